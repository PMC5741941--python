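"""Enriched-gene-set overlap network and ORA membership table.

The network summarizes how the recurrently enriched gene sets share genes:
nodes are sets enriched in at least one dataset (sized by how often), and
edges connect sets whose shared-gene fraction reaches a threshold (the
fraction is relative to the smaller set by default).  The membership table
is the binary gene x significant-set matrix behind the ORA heatmap, plus
the count of query genes covered by no significant set.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from qsig.types import GeneSetCollection, ValidationError

SHARED_FRACTION_MODES = ("min", "union", "either")


def _shared_fraction(a: set, b: set, mode: str) -> float:
    inter = len(a & b)
    if mode == "min":
        denom = min(len(a), len(b))
    elif mode == "union":
        denom = len(a | b)
    elif mode == "either":
        denom = max(len(a), len(b))
    else:
        raise ValidationError(f"unknown shared-fraction mode {mode!r}")
    return inter / denom if denom else 0.0


def build_overlap_network(
    matrix: pd.DataFrame,
    collection: GeneSetCollection,
    min_shared_frac: float = 0.10,
    top_k: int | None = None,
    frac_mode: str = "min",
) -> nx.Graph:
    """Build the overlap network of enriched gene sets.

    ``matrix`` is the direction-coded enrichment matrix (sets x datasets,
    entries in {-1, 0, +1}).  Nodes are sets enriched in >= 1 dataset, with
    attributes ``enrichment_count``, ``dominant_direction`` (sign of the
    summed codes; ties -> "Mixed"), ``set_size`` and ``anchor`` (True for
    the ``top_k`` most frequently enriched sets per direction, when
    requested).  Undirected edges carry ``shared_gene_count`` and
    ``shared_fraction`` and exist iff the fraction reaches
    ``min_shared_frac``; the denominator convention (``frac_mode``) is
    recorded on the graph.
    """
    unknown = set(matrix.index) - set(collection.sets)
    if unknown:
        raise ValidationError(f"matrix rows missing from collection: {sorted(unknown)[:5]}")
    if frac_mode not in SHARED_FRACTION_MODES:
        raise ValidationError(f"unknown shared-fraction mode {frac_mode!r}")
    counts = (matrix != 0).sum(axis=1)
    sums = matrix.sum(axis=1)
    enriched = sorted(counts.index[counts >= 1])
    anchors: set = set()
    if top_k is not None:
        for direction in (1, -1):
            dir_counts = (matrix == direction).sum(axis=1)
            dir_counts = dir_counts[dir_counts > 0].sort_values(
                ascending=False, kind="mergesort"
            )
            anchors |= set(dir_counts.index[:top_k])
    graph = nx.Graph(min_shared_frac=min_shared_frac, frac_mode=frac_mode)
    for name in enriched:
        total = int(sums.loc[name])
        direction = "Up" if total > 0 else ("Down" if total < 0 else "Mixed")
        graph.add_node(
            name,
            enrichment_count=int(counts.loc[name]),
            dominant_direction=direction,
            set_size=len(collection.sets[name]),
            anchor=bool(name in anchors),
        )
    for i, a in enumerate(enriched):
        for b in enriched[i + 1:]:
            frac = _shared_fraction(collection.sets[a], collection.sets[b], frac_mode)
            if frac >= min_shared_frac:
                graph.add_edge(
                    a,
                    b,
                    shared_gene_count=len(collection.sets[a] & collection.sets[b]),
                    shared_fraction=frac,
                )
    return graph


def ora_membership_table(
    ora: pd.DataFrame,
    fdr_max: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Binary gene x set membership matrix of the significant ORA sets.

    Rows are query genes appearing in at least one significant set
    (``adj_p <= fdr_max``), columns the significant sets; returns the matrix
    together with the count of query genes covered by no significant set.
    """
    sig = ora[ora["adj_p"] <= fdr_max]
    query_size = int(ora["K"].iloc[0]) if len(ora) else 0
    if sig.empty:
        return pd.DataFrame(dtype=int), query_size
    membership: dict[str, set] = {
        set_name: set(filter(None, str(row["overlap_genes"]).split(",")))
        for set_name, row in sig.iterrows()
    }
    covered = sorted(set().union(*membership.values()))
    table = pd.DataFrame(
        {s: [1 if g in membership[s] else 0 for g in covered] for s in sorted(membership)},
        index=pd.Index(covered, name="gene"),
        dtype=int,
    )
    return table, query_size - len(covered)
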