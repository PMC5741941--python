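"""Per-dataset quality control, normalization and probeset aggregation.

The pipeline starts from normalized, probeset- or gene-level log2 matrices
(public microarray data arrive that way); an optional quantile normalization
is provided for synthetic raw matrices.  Quality control follows the
relative-log-expression (RLE) convention: per sample, the median over genes
of the deviation from the gene-wise median across samples.  Good arrays have
RLE medians near zero; a globally shifted sample stands out.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from qsig.types import ExpressionDataset, QCReport, ValidationError, condition_counts

# |RLE median| beyond this flags a sample as an outlier.  Clean arrays sit
# well inside; a +1 log2 global shift lands far outside.
DEFAULT_RLE_THRESHOLD = 0.15


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of mean order statistics.

    Each column is replaced by the row-wise mean of the sorted columns at its
    own ranks, so all columns share the identical sorted value multiset.
    Ties within a column receive the average of the tied target values.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("quantile_normalize needs at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("quantile_normalize: non-finite values in matrix")
    order_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_vals = col[order]
        # runs of tied values all receive the mean of their target values
        group = np.concatenate([[0], np.cumsum(sorted_vals[1:] != sorted_vals[:-1])])
        targets = (np.bincount(group, weights=order_means) / np.bincount(group))[group]
        out[order, j] = targets
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def rle_stats(
    matrix: pd.DataFrame,
    threshold: float = DEFAULT_RLE_THRESHOLD,
    dataset_id: str = "",
) -> QCReport:
    """Relative log expression per sample, with outlier flags.

    For sample ``j``, RLE values are ``x[g, j] - median_over_samples(x[g, :])``;
    the per-sample median and IQR summarize them.  Samples with
    ``|median| > threshold`` are flagged.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("rle_stats needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("rle_stats: non-finite values in matrix")
    rle = values - np.median(values, axis=1, keepdims=True)
    med = np.median(rle, axis=0)
    q75, q25 = np.percentile(rle, [75, 25], axis=0)
    table = pd.DataFrame(
        {
            "rle_median": med,
            "rle_iqr": q75 - q25,
            "flagged": np.abs(med) > threshold,
        },
        index=pd.Index(matrix.columns, name="sample_id"),
    )
    return QCReport(dataset_id=dataset_id, table=table, params={"threshold": threshold})


def drop_outliers(dataset: ExpressionDataset, qc: QCReport) -> ExpressionDataset:
    """Remove QC-flagged samples; refuse if a condition loses replication."""
    if set(qc.table.index) != set(dataset.matrix.columns):
        raise ValidationError(
            f"{dataset.dataset_id}: QC report samples do not match dataset samples"
        )
    flagged = set(qc.flagged)
    if not flagged:
        return dataset
    keep = [s for s in dataset.matrix.columns if s not in flagged]
    remaining = condition_counts({s: dataset.conditions[s] for s in keep})
    for cond, n in remaining.items():
        if n < 2:
            raise ValidationError(
                f"{dataset.dataset_id}: dropping outliers leaves {n} {cond} "
                f"sample(s); at least 2 are required"
            )
    return dataset.subset_samples(keep)


def aggregate_probesets(dataset: ExpressionDataset) -> ExpressionDataset:
    """Collapse probesets to genes, keeping the most variable probeset per gene.

    Variability is the sample variance of the probeset row across all samples
    (both conditions).  Unannotated probesets are dropped.  Exact variance
    ties are broken toward the lexicographically smallest probeset id.  The
    chosen probeset per gene is recorded in the returned dataset's
    annotation (column ``probeset``).
    """
    ann = dataset.annotation
    if ann is None or ann.empty:
        raise ValidationError(f"{dataset.dataset_id}: no probeset annotation")
    mapped = ann["gene_symbol"].dropna()
    mapped = mapped[mapped.astype(str).str.len() > 0]
    mapped = mapped[mapped.index.isin(dataset.matrix.index)]
    if mapped.empty:
        raise ValidationError(f"{dataset.dataset_id}: annotation maps no probeset")
    variances = dataset.matrix.loc[mapped.index].var(axis=1, ddof=1)
    choice = (
        pd.DataFrame({"gene_symbol": mapped, "variance": variances})
        .rename_axis("probeset")
        .reset_index()
        # descending variance, ascending probeset id: first row per gene wins ties
        .sort_values(["variance", "probeset"], ascending=[False, True], kind="mergesort")
        .drop_duplicates("gene_symbol", keep="first")
        .sort_values("gene_symbol")
    )
    matrix = dataset.matrix.loc[choice["probeset"]].copy()
    matrix.index = pd.Index(choice["gene_symbol"].to_numpy(), name="gene")
    provenance = choice.set_index("gene_symbol")[["probeset"]]
    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        matrix=matrix,
        conditions=dict(dataset.conditions),
        annotation=provenance,
    )
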