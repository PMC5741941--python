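"""Two-group differential expression with empirical-Bayes moderated t-statistics.

Per gene, the two-group model compares quiescent (QSC) against activated
(ASC) samples: ``logFC = mean(QSC) - mean(ASC)`` on the log2 scale, with the
pooled residual variance ``s_g^2`` on ``d_g = n1 + n2 - 2`` degrees of
freedom.  An inverse-chi-square prior with hyperparameters ``(d0, s0^2)``,
fitted across genes by moment matching on log variances, shrinks each gene's
variance to the posterior

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t-statistic ``t = logFC / sqrt(s~^2 (1/n1 + 1/n2))`` is
referred to a t distribution on ``d0 + d_g`` degrees of freedom.  Multiple
testing is controlled per dataset with the Benjamini-Hochberg step-up
procedure.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import special, stats

from qsig.types import ExpressionDataset, PriorEstimate, ValidationError

MIN_GENES_FOR_PRIOR = 10


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def _trigamma_inverse(y: float, rel_tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection.

    trigamma is strictly decreasing on (0, inf) with range (0, inf), so the
    root is unique.  Bisection on a bracket grown geometrically around the
    asymptotic guess x ~ 1/y converges to the stated relative tolerance.
    """
    if y <= 0:
        raise ValidationError("trigamma inverse requires y > 0")
    lo, hi = 1e-12, max(2.0, 2.0 / y)
    while _trigamma(hi) > y:
        hi *= 2.0
        if hi > 1e12:
            return hi
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if _trigamma(mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_prior(s_g_sq: np.ndarray, d_g: np.ndarray | int) -> PriorEstimate:
    """Fit the variance-prior hyperparameters (d0, s0^2) across genes.

    Moment matching on ``log(s_g^2)``: under the hierarchical model the
    centred log variance ``e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2)``
    has mean ``log(s0^2) - digamma(d0/2) + log(d0/2)`` and variance
    ``trigamma(d_g/2) + trigamma(d0/2)``.  The excess of the empirical
    variance of ``e`` over the mean sampling term identifies
    ``trigamma(d0/2)``, inverted numerically.  A non-positive excess means
    the gene variances are consistent with a single common value: ``d0`` is
    flagged infinite and ``s0^2`` is the (geometric-mean based) common value.

    Genes with non-positive variance or ``d_g < 1`` are excluded from the
    fit; fewer than 10 usable genes is an error.
    """
    s_g_sq = np.asarray(s_g_sq, dtype=float)
    d_g = np.broadcast_to(np.asarray(d_g, dtype=float), s_g_sq.shape)
    usable = (s_g_sq > 0) & (d_g >= 1)
    n_used = int(usable.sum())
    if n_used < MIN_GENES_FOR_PRIOR:
        raise ValidationError(
            f"estimate_prior needs >= {MIN_GENES_FOR_PRIOR} genes with positive "
            f"variance and d_g >= 1; got {n_used}"
        )
    s2 = s_g_sq[usable]
    df = d_g[usable]
    if np.ptp(s2) == 0:
        # zero dispersion: the common variance is observed directly
        return PriorEstimate(d0=math.inf, s0_sq=float(s2[0]), n_genes_used=n_used)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(e.mean())
    excess = float(e.var(ddof=1) - _trigamma(df / 2.0).mean())
    if excess <= 0:
        return PriorEstimate(d0=math.inf, s0_sq=float(np.exp(e_bar)), n_genes_used=n_used)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return PriorEstimate(d0=d0, s0_sq=s0_sq, n_genes_used=n_used)


def _two_group_stats(dataset: ExpressionDataset):
    qsc = dataset.samples("QSC")
    asc = dataset.samples("ASC")
    if len(qsc) < 2 or len(asc) < 2:
        raise ValidationError(
            f"{dataset.dataset_id}: need >= 2 samples per condition "
            f"(QSC={len(qsc)}, ASC={len(asc)})"
        )
    x1 = dataset.matrix[qsc].to_numpy(dtype=float)
    x2 = dataset.matrix[asc].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    d_g = n1 + n2 - 2
    s_g_sq = ss / d_g
    logfc = m1 - m2
    avg = (x1.sum(axis=1) + x2.sum(axis=1)) / (n1 + n2)
    return logfc, avg, s_g_sq, d_g, n1, n2


def moderated_t_test(
    dataset: ExpressionDataset,
    prior: PriorEstimate | None = None,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    use_lfc: bool = True,
) -> pd.DataFrame:
    """Moderated t-test of QSC vs ASC for every gene of one dataset.

    Returns a DataFrame indexed by gene with columns ``logFC``, ``avg_expr``,
    ``s2``, ``df_resid``, ``s2_post``, ``t_mod``, ``df_total``, ``p``,
    ``adj_p`` and ``call`` (the call uses the thresholds given here; see
    :func:`call_degs` for re-thresholding).  If no prior is supplied it is
    estimated from this dataset's gene variances.  ``d0 = 0`` recovers the
    ordinary pooled two-sample t-test exactly.
    """
    logfc, avg, s_g_sq, d_g, n1, n2 = _two_group_stats(dataset)
    if prior is None:
        prior = estimate_prior(s_g_sq, d_g)
    scale = 1.0 / n1 + 1.0 / n2
    if prior.is_infinite:
        s2_post = np.full_like(s_g_sq, prior.s0_sq)
        df_total = np.full_like(s_g_sq, math.inf)
    else:
        s2_post = (prior.d0 * prior.s0_sq + d_g * s_g_sq) / (prior.d0 + d_g)
        df_total = np.full_like(s_g_sq, prior.d0 + d_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = logfc / np.sqrt(s2_post * scale)
    # degenerate genes: zero posterior variance (possible only when d0 == 0)
    zero_var = s2_post == 0
    t_mod[zero_var & (logfc == 0)] = 0.0
    t_mod[zero_var & (logfc > 0)] = math.inf
    t_mod[zero_var & (logfc < 0)] = -math.inf
    if prior.is_infinite:
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=prior.d0 + d_g)
    p[np.abs(t_mod) == math.inf] = 0.0
    p[t_mod == 0.0] = 1.0
    adj_p = benjamini_hochberg(p)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "avg_expr": avg,
            "s2": s_g_sq,
            "df_resid": float(d_g),
            "s2_post": s2_post,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "adj_p": adj_p,
        },
        index=pd.Index(dataset.matrix.index, name="gene"),
    )
    up = (table["adj_p"] <= fdr_max) & (
        table["logFC"] >= lfc_min if use_lfc else table["logFC"] > 0
    )
    down = (table["adj_p"] <= fdr_max) & (
        table["logFC"] <= -lfc_min if use_lfc else table["logFC"] < 0
    )
    table["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    table.attrs["prior"] = prior
    table.attrs["dataset_id"] = dataset.dataset_id
    table.attrs["thresholds"] = {
        "lfc_min": lfc_min,
        "fdr_max": fdr_max,
        "use_lfc": use_lfc,
    }
    return table


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min_{j >= i} m * p_(j) / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("benjamini_hochberg expects a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def call_degs(
    de: pd.DataFrame,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    use_lfc: bool = True,
) -> tuple[set, set]:
    """Extract (up, down) DEG sets from a differential-expression table.

    ``up`` requires ``adj_p <= fdr_max`` and, when ``use_lfc`` is set,
    ``logFC >= lfc_min`` (signature mode drops the fold-change threshold and
    keeps only the sign); ``down`` is symmetric.
    """
    if lfc_min <= 0 or not (0 < fdr_max < 1):
        raise ValidationError("thresholds must satisfy lfc_min > 0, 0 < fdr_max < 1")
    sig = de["adj_p"] <= fdr_max
    if use_lfc:
        up = set(de.index[sig & (de["logFC"] >= lfc_min)])
        down = set(de.index[sig & (de["logFC"] <= -lfc_min)])
    else:
        up = set(de.index[sig & (de["logFC"] > 0)])
        down = set(de.index[sig & (de["logFC"] < 0)])
    return up, down


def group_residuals(dataset: ExpressionDataset) -> pd.DataFrame:
    """Residual matrix after removing per-gene group means (for correlation
    estimation in the competitive gene-set test)."""
    out = dataset.matrix.copy().astype(float)
    for cond in ("QSC", "ASC"):
        cols = dataset.samples(cond)
        out[cols] = out[cols].sub(out[cols].mean(axis=1), axis=0)
    return out
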