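"""Gene-set collections and enrichment tests.

Two complementary tests are provided.  The competitive test asks, per
dataset, whether the genes of a set are more differentially expressed than
the genes outside it; because co-regulated genes are correlated, the
variance of the set mean is inflated by the factor ``VIF = 1 + (m-1)*rho``
with ``rho`` the mean pairwise inter-gene correlation, estimated from the
residual matrix.  The over-representation analysis (ORA) asks whether a
fixed query gene list (here, a consensus signature) overlaps a set more
than expected under hypergeometric sampling from the background universe —
a one-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from qsig.diffexpr import benjamini_hochberg
from qsig.types import GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SET_SIZE = 5


# ---------------------------------------------------------------------------
# GMT i/o


def read_gmt(path: str | Path, name: str | None = None,
             universe: set | None = None) -> GeneSetCollection:
    """Read a GMT file (set_name TAB description TAB gene...).

    Duplicate genes within a set are de-duplicated with a warning.  The
    universe defaults to the union of all sets unless given explicitly.
    """
    path = Path(path)
    sets: dict[str, set] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            set_name, genes = fields[0], [g for g in fields[2:] if g]
            unique = set(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "%s:%d: set %r lists %d duplicate gene(s); de-duplicated",
                    path, lineno, set_name, len(genes) - len(unique),
                )
            sets[set_name] = unique
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(name=name or path.stem, sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT, one line per set, genes sorted for
    reproducible output."""
    path = Path(path)
    with path.open("w") as fh:
        for set_name in sorted(collection.sets):
            genes = sorted(collection.sets[set_name])
            fh.write("\t".join([set_name, collection.name] + genes) + "\n")


# ---------------------------------------------------------------------------
# Competitive enrichment (CAMERA-style)


def _gene_scores(t_mod: np.ndarray, df_total: np.ndarray) -> np.ndarray:
    """Probability-integral transform of moderated t to standard-normal scores.

    Computed tail-first on the side of the observed sign so extreme
    statistics map to finite large z-scores rather than overflowing the CDF.
    """
    t_mod = np.asarray(t_mod, dtype=float)
    df_total = np.asarray(df_total, dtype=float)
    z = np.empty_like(t_mod)
    pos = t_mod >= 0
    finite = np.isfinite(df_total)
    df_pos = np.where(finite, df_total, 1.0)
    upper = np.where(finite, stats.t.sf(np.abs(t_mod), df=df_pos),
                     stats.norm.sf(np.abs(t_mod)))
    upper = np.clip(upper, 1e-300, 1.0)
    z[pos] = stats.norm.isf(upper[pos])
    z[~pos] = -stats.norm.isf(upper[~pos])
    return z


def variance_inflation(m: int, rho_bar: float) -> float:
    """VIF of a size-``m`` set mean under mean pairwise correlation ``rho_bar``,
    floored at 1 (negative average correlation must not anti-inflate)."""
    return max(1.0, 1.0 + (m - 1) * rho_bar)


def camera_test(
    de: pd.DataFrame,
    residual_matrix: pd.DataFrame | None,
    collection: GeneSetCollection,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    use_vif: bool = True,
) -> pd.DataFrame:
    """Competitive gene-set test with inter-gene-correlation correction.

    Per-gene scores are ``z_g = Phi^-1(F_t(t_mod; df_total))``.  For each
    set of size ``m`` within the ``G`` tested genes:

        z_set = (mean z in - mean z out) / (sd(z) * sqrt(VIF/m + 1/(G-m)))

    with ``VIF = max(1, 1 + (m-1)*rho_bar)`` and ``rho_bar`` the mean
    pairwise Pearson correlation of the member genes' residual rows
    (``rho_bar = 0`` if the residual matrix is absent, with a warning, or if
    ``m = 1``).  Two-sided normal p-values, BH-corrected across the sets
    tested.  ``use_vif=False`` forces ``VIF = 1`` (uncorrected variant, for
    calibration comparisons).
    """
    genes = de.index
    restricted = collection.restrict(genes, min_size=min_set_size)
    z = _gene_scores(de["t_mod"].to_numpy(), de["df_total"].to_numpy())
    z_series = pd.Series(z, index=genes)
    G = len(genes)
    sd_all = float(np.std(z, ddof=1))
    if residual_matrix is None and use_vif:
        logger.warning("camera_test: no residual matrix; rho_bar = 0 for all sets")
    rows = []
    for set_name in sorted(restricted.sets):
        members = restricted.sets[set_name]
        m = len(members)
        if G - m < 2:
            logger.warning(
                "camera_test: set %r leaves %d genes outside; skipped", set_name, G - m
            )
            continue
        member_idx = z_series.index.isin(members)
        mean_in = float(z_series[member_idx].mean())
        mean_out = float(z_series[~member_idx].mean())
        if use_vif and residual_matrix is not None and m > 1:
            rho_bar = _mean_pairwise_correlation(residual_matrix.loc[sorted(members)])
        else:
            rho_bar = 0.0
        vif = variance_inflation(m, rho_bar) if use_vif else 1.0
        se = sd_all * np.sqrt(vif / m + 1.0 / (G - m))
        z_set = (mean_in - mean_out) / se
        p = 2.0 * stats.norm.sf(abs(z_set))
        rows.append(
            {
                "set": set_name,
                "m": m,
                "rho_bar": rho_bar,
                "vif": vif,
                "z_set": z_set,
                "direction": "Up" if mean_in > mean_out else "Down",
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "m", "rho_bar", "vif", "z_set", "direction", "p"]
    ).set_index("set")
    if len(table):
        table["adj_p"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        table["adj_p"] = pd.Series(dtype=float)
    table.attrs["collection"] = collection.name
    return table


def _mean_pairwise_correlation(rows: pd.DataFrame) -> float:
    """Mean off-diagonal Pearson correlation of the given residual rows.

    Rows with zero variance contribute correlation 0 to their pairs.
    """
    values = rows.to_numpy(dtype=float)
    m = values.shape[0]
    if m < 2:
        return 0.0
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    k = int(keep.sum())
    if k < 2:
        return 0.0
    corr = np.corrcoef(values[keep])
    total = float(corr.sum() - k)  # off-diagonal sum among usable rows
    return total / (m * (m - 1))


# ---------------------------------------------------------------------------
# Over-representation analysis (one-sided Fisher)


def fisher_ora(
    query: set,
    collection: GeneSetCollection,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation test of a query gene list.

    For each set (size ``n`` within the universe of size ``N``) and a query
    of size ``K``, the p-value is the hypergeometric upper tail
    ``P(X >= k)`` of the observed overlap ``k``.  Genes outside the universe
    are dropped from the query with a logged count.  BH across sets.
    """
    dropped = len(query) - len(set(query) & collection.universe)
    if dropped:
        logger.warning("fisher_ora: %d query gene(s) outside the universe dropped", dropped)
    query = set(query) & collection.universe
    if not query:
        raise ValidationError("fisher_ora: query empty after universe restriction")
    N = len(collection.universe)
    K = len(query)
    rows = []
    for set_name in sorted(collection.sets):
        members = collection.sets[set_name] & collection.universe
        n = len(members)
        if n < min_set_size:
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, n, K))
        rows.append(
            {
                "set": set_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p", "overlap_genes"]
    ).set_index("set")
    if len(table):
        table["adj_p"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        table["adj_p"] = pd.Series(dtype=float)
    table.attrs["collection"] = collection.name
    return table


# ---------------------------------------------------------------------------
# Cross-dataset enrichment summary


def enrichment_matrix(
    results: dict[str, pd.DataFrame],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Direction-coded gene-set x dataset matrix of significant enrichments.

    Entries are +1 (enriched Up at ``adj_p <= fdr_max``), -1 (Down) or 0.
    All per-dataset tables must come from the same collection.
    """
    collections = {t.attrs.get("collection") for t in results.values()}
    if len(collections) > 1:
        raise ValidationError(f"enrichment_matrix: mixed collections {collections}")
    all_sets = sorted(set().union(*[set(t.index) for t in results.values()]))
    matrix = pd.DataFrame(
        0, index=pd.Index(all_sets, name="set"), columns=sorted(results), dtype=int
    )
    for ds in sorted(results):
        t = results[ds]
        sig = t[t["adj_p"] <= fdr_max]
        for set_name, row in sig.iterrows():
            matrix.loc[set_name, ds] = 1 if row["direction"] == "Up" else -1
    return matrix
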