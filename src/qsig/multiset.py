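"""Multi-set analysis: intersection landscape, similarity, ranking, consensus.

Given per-dataset up/down DEG sets, this module quantifies agreement between
datasets (Jaccard similarity with hierarchical clustering), explores the
combinatorial landscape of dataset intersections with an exact significance
test on overlap sizes, ranks datasets by significance criteria to select an
ensemble, and assembles the consensus signature — the genes up- (or down-)
regulated in every ensemble member.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from qsig.types import ConsensusSignature, DegSets, ValidationError

logger = logging.getLogger(__name__)

MAX_DATASETS_FOR_ENUMERATION = 20


# ---------------------------------------------------------------------------
# Similarity


def jaccard(a: set, b: set) -> float:
    """Jaccard index |a & b| / |a | b|; 0 for two empty sets (logged)."""
    union = len(a | b)
    if union == 0:
        logger.warning("jaccard: both sets empty; returning 0 by convention")
        return 0.0
    return len(a & b) / union


@dataclass
class JaccardMatrix:
    """Pairwise Jaccard-index matrix for one DEG direction plus its
    hierarchical clustering (complete linkage)."""

    direction: str
    matrix: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str] = field(default_factory=list)

    def mean_offdiag(self, dataset_id: str) -> float:
        others = [d for d in self.matrix.index if d != dataset_id]
        return float(self.matrix.loc[dataset_id, others].mean())


def jaccard_matrix(
    degs: DegSets,
    direction: str,
    cluster_on: str = "rows",
) -> JaccardMatrix:
    """Symmetric Jaccard matrix of one direction's DEG sets, with clustering.

    Clustering is complete-linkage.  ``cluster_on="rows"`` (default) uses
    Euclidean distances between the similarity matrix's rows;
    ``cluster_on="one_minus_ji"`` clusters on ``1 - JI`` directly.  Dataset
    ids are sorted so ties resolve deterministically.
    """
    ids = degs.dataset_ids
    if len(ids) < 2:
        raise ValidationError("jaccard_matrix needs >= 2 datasets")
    sets = degs.direction(direction)
    n = len(ids)
    mat = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ji = jaccard(sets[ids[i]], sets[ids[j]])
        mat[i, j] = mat[j, i] = ji
    frame = pd.DataFrame(mat, index=ids, columns=ids)
    if cluster_on == "rows":
        if n == 2:
            dist = np.array([float(np.linalg.norm(mat[0] - mat[1]))])
        else:
            from scipy.spatial.distance import pdist

            dist = pdist(mat, metric="euclidean")
    elif cluster_on == "one_minus_ji":
        dist = squareform(1.0 - mat, checks=False)
    else:
        raise ValidationError(f"unknown cluster_on mode {cluster_on!r}")
    linkage = hierarchy.linkage(dist, method="complete")
    order = [ids[i] for i in hierarchy.leaves_list(linkage)]
    return JaccardMatrix(direction=direction, matrix=frame, linkage=linkage, leaf_order=order)


# ---------------------------------------------------------------------------
# Exact intersection statistics


def exact_intersection_test(
    sizes: list[int], N: int, observed: int
) -> tuple[float, float]:
    """Expected size and upper-tail p-value of a multi-set intersection.

    Under independent uniform draws of fixed-size sets from a background of
    ``N`` elements, each element belongs to all ``m`` sets with probability
    ``prod(n_i / N)``, so the expected intersection is ``N * prod(n_i / N)``.
    For ``m = 2`` the intersection size is exactly hypergeometric and the
    tail is computed in closed form; for ``m > 2`` the binomial tail with
    the joint membership probability is used (elements are exchangeable
    with that marginal probability; the binomial form neglects the weak
    negative dependence induced by the fixed set sizes and is validated
    against Monte Carlo).
    """
    sizes = [int(s) for s in sizes]
    if len(sizes) < 2:
        raise ValidationError("exact_intersection_test needs >= 2 set sizes")
    if any(s < 0 or s > N for s in sizes):
        raise ValidationError(f"set sizes must lie in [0, N={N}]")
    if observed > min(sizes):
        raise ValidationError(
            f"observed intersection {observed} exceeds smallest set {min(sizes)}"
        )
    prob = float(np.prod([s / N for s in sizes]))
    expected = N * prob
    if observed <= 0:
        return expected, 1.0
    if len(sizes) == 2:
        n1, n2 = sizes
        p = float(stats.hypergeom.sf(observed - 1, N, n1, n2))
    else:
        p = float(stats.binom.sf(observed - 1, N, prob))
    return expected, min(p, 1.0)


@dataclass
class IntersectionRecord:
    """Best dataset combination at one intersection degree."""

    combination: tuple[str, ...]
    degree: int
    up_overlap: set
    down_overlap: set
    up_size: int
    down_size: int
    up_expected: float
    down_expected: float
    up_p: float
    down_p: float


def _overlap(sets: dict[str, set], combo: tuple[str, ...]) -> set:
    out = set(sets[combo[0]])
    for ds in combo[1:]:
        out &= sets[ds]
    return out


def intersection_landscape(
    degs: DegSets,
    degrees: range | list[int] | None = None,
    objective: str = "both",
) -> list[IntersectionRecord]:
    """Best dataset combination per intersection degree, with exact tests.

    For each degree ``k`` all ``C(K, k)`` dataset subsets are enumerated and
    the best is the one maximizing the summed up+down overlap size
    (``objective`` may instead be ``"up"`` or ``"down"`` to optimize one
    direction).  Ties break toward the lexicographically smallest dataset-id
    tuple.  Enumeration is exhaustive and refuses more than
    20 datasets.
    """
    ids = degs.dataset_ids
    K = len(ids)
    if K > MAX_DATASETS_FOR_ENUMERATION:
        raise ValidationError(
            f"exhaustive enumeration capped at {MAX_DATASETS_FOR_ENUMERATION} datasets; got {K}"
        )
    if degrees is None:
        degrees = range(2, K + 1)
    degrees = sorted(set(int(k) for k in degrees))
    if any(k < 2 or k > K for k in degrees):
        raise ValidationError(f"degrees must lie in [2, {K}]")
    if objective not in ("both", "up", "down"):
        raise ValidationError(f"unknown objective {objective!r}")
    records = []
    for k in degrees:
        best_combo: tuple[str, ...] | None = None
        best_score = -1
        for combo in itertools.combinations(ids, k):  # lexicographic order
            up = len(_overlap(degs.up, combo))
            down = len(_overlap(degs.down, combo))
            score = {"both": up + down, "up": up, "down": down}[objective]
            if score > best_score:
                best_score, best_combo = score, combo
        assert best_combo is not None
        up_set = _overlap(degs.up, best_combo)
        down_set = _overlap(degs.down, best_combo)
        N = min(degs.background[ds] for ds in best_combo)
        up_sizes = [min(len(degs.up[ds]), N) for ds in best_combo]
        down_sizes = [min(len(degs.down[ds]), N) for ds in best_combo]
        up_exp, up_p = exact_intersection_test(up_sizes, N, min(len(up_set), min(up_sizes, default=0)))
        down_exp, down_p = exact_intersection_test(down_sizes, N, min(len(down_set), min(down_sizes, default=0)))
        records.append(
            IntersectionRecord(
                combination=best_combo,
                degree=k,
                up_overlap=up_set,
                down_overlap=down_set,
                up_size=len(up_set),
                down_size=len(down_set),
                up_expected=up_exp,
                down_expected=down_exp,
                up_p=up_p,
                down_p=down_p,
            )
        )
    return records


def landscape_table(records: list[IntersectionRecord]) -> pd.DataFrame:
    """Tabular view of an intersection landscape (one row per degree)."""
    return pd.DataFrame(
        {
            "degree": [r.degree for r in records],
            "combination": ["+".join(r.combination) for r in records],
            "up_overlap": [r.up_size for r in records],
            "down_overlap": [r.down_size for r in records],
            "up_expected": [r.up_expected for r in records],
            "down_expected": [r.down_expected for r in records],
            "up_p": [r.up_p for r in records],
            "down_p": [r.down_p for r in records],
        }
    ).set_index("degree")


# ---------------------------------------------------------------------------
# Dataset significance ranking and consensus


def rank_datasets(
    degs: DegSets,
    markers: list[str] | None = None,
    min_deg: int = 300,
    min_marker_frac: float = 0.5,
    min_mean_ji: float | None = None,
    criteria: tuple[str, ...] = ("n_deg", "markers", "similarity"),
) -> pd.DataFrame:
    """Pass/fail significance report deciding each dataset's ensemble membership.

    Three independent criteria, each disableable via ``criteria``:

    - ``n_deg``: total DEG count (up+down) >= ``min_deg``;
    - ``markers``: fraction of the known-marker list present among the
      dataset's up-DEGs >= ``min_marker_frac``;
    - ``similarity``: mean off-diagonal Jaccard index to the other datasets
      (up and down averaged) >= ``min_mean_ji``.  When ``min_mean_ji`` is
      None it defaults to half the grand mean off-diagonal JI, an adaptive
      cut separating datasets that agree with the bulk from stragglers.

    ``include`` is the conjunction of all enabled criteria.
    """
    ids = degs.dataset_ids
    if "markers" in criteria and not markers:
        raise ValidationError("marker criterion enabled but marker list empty")
    markers = list(markers or [])
    ji_up = jaccard_matrix(degs, "up")
    ji_down = jaccard_matrix(degs, "down")
    mean_ji = {
        ds: 0.5 * (ji_up.mean_offdiag(ds) + ji_down.mean_offdiag(ds)) for ds in ids
    }
    if min_mean_ji is None:
        grand = float(np.mean([mean_ji[ds] for ds in ids]))
        min_mean_ji = 0.5 * grand
    rows = []
    for ds in ids:
        n_up, n_down = len(degs.up[ds]), len(degs.down[ds])
        found = sorted(set(markers) & degs.up[ds])
        marker_frac = len(found) / len(markers) if markers else float("nan")
        checks = {
            "n_deg": (n_up + n_down) >= min_deg,
            "markers": marker_frac >= min_marker_frac if markers else True,
            "similarity": mean_ji[ds] >= min_mean_ji,
        }
        enabled = {c: checks[c] for c in criteria}
        rows.append(
            {
                "dataset": ds,
                "n_up": n_up,
                "n_down": n_down,
                "n_deg_total": n_up + n_down,
                "markers_found": ",".join(found),
                "markers_missing": ",".join(sorted(set(markers) - set(found))),
                "marker_frac": marker_frac,
                "mean_ji": mean_ji[ds],
                "pass_n_deg": checks["n_deg"] if "n_deg" in criteria else None,
                "pass_markers": checks["markers"] if "markers" in criteria else None,
                "pass_similarity": checks["similarity"] if "similarity" in criteria else None,
                "include": all(enabled.values()),
            }
        )
    report = pd.DataFrame(rows).set_index("dataset")
    report.attrs["params"] = {
        "min_deg": min_deg,
        "min_marker_frac": min_marker_frac,
        "min_mean_ji": min_mean_ji,
        "criteria": list(criteria),
        "markers": markers,
    }
    return report


def consensus_signature(
    degs: DegSets,
    report: pd.DataFrame | None = None,
    ensemble: list[str] | None = None,
    suspects: list[str] | None = None,
    thresholds: dict | None = None,
) -> ConsensusSignature:
    """Intersect the ensemble datasets' DEG sets into the consensus signature.

    The ensemble is taken from ``report`` (rows with ``include``) unless
    given explicitly.  Signature genes present in the ``suspects`` list
    (e.g. isolation-stress immediate-early genes) are flagged, never
    silently kept or removed.
    """
    if ensemble is None:
        if report is None:
            raise ValidationError("consensus_signature needs a report or an ensemble")
        ensemble = sorted(report.index[report["include"]])
    else:
        ensemble = sorted(ensemble)
    if len(ensemble) < 2:
        raise ValidationError(
            f"ensemble has {len(ensemble)} dataset(s); >= 2 required "
            f"(see the significance report)"
        )
    missing = set(ensemble) - set(degs.dataset_ids)
    if missing:
        raise ValidationError(f"ensemble datasets without DEG sets: {sorted(missing)}")
    up = sorted(_overlap(degs.up, tuple(ensemble)))
    down = sorted(_overlap(degs.down, tuple(ensemble)))
    suspects_set = set(suspects or [])
    flagged_up = sorted(set(up) & suspects_set)
    flagged_down = sorted(set(down) & suspects_set)
    if flagged_up or flagged_down:
        logger.warning(
            "consensus signature contains %d suspect gene(s): %s",
            len(flagged_up) + len(flagged_down),
            ",".join(flagged_up + flagged_down),
        )
    return ConsensusSignature(
        ensemble=list(ensemble),
        up=up,
        down=down,
        thresholds=dict(thresholds or {}),
        flagged_up=flagged_up,
        flagged_down=flagged_down,
    )


def flag_suspect_genes(signature: ConsensusSignature, suspects: list[str]) -> list[str]:
    """Signature genes matching a user-supplied suspect/immediate-early list."""
    suspects_set = set(suspects)
    return sorted((set(signature.up) | set(signature.down)) & suspects_set)
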