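"""Readers/writers for the pipeline's plain-text exchange formats.

Expression matrices and result tables travel as TSV, sample metadata as a
two-column TSV (sample_id, condition), gene sets as GMT, ground truth and
manifests as JSON.  All writers are deterministic (fixed column order and
float formatting) so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from qsig.types import DegSets, ExpressionDataset, QCReport, ValidationError

FLOAT_FORMAT = "%.10g"


def write_expression_tsv(dataset: ExpressionDataset, matrix_path: str | Path,
                         metadata_path: str | Path) -> None:
    dataset.matrix.to_csv(matrix_path, sep="\t", float_format=FLOAT_FORMAT,
                          index_label="gene")
    meta = pd.DataFrame(
        {"sample_id": list(dataset.matrix.columns),
         "condition": [dataset.conditions[s] for s in dataset.matrix.columns]}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_expression_tsv(dataset_id: str, matrix_path: str | Path,
                        metadata_path: str | Path,
                        annotation_path: str | Path | None = None) -> ExpressionDataset:
    if not Path(matrix_path).exists():
        raise ValidationError(f"expression matrix not found: {matrix_path}")
    if not Path(metadata_path).exists():
        raise ValidationError(f"sample metadata not found: {metadata_path}")
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    conditions = dict(zip(meta["sample_id"].astype(str), meta["condition"].astype(str)))
    annotation = None
    if annotation_path is not None:
        annotation = pd.read_csv(annotation_path, sep="\t", index_col=0)
    return ExpressionDataset(dataset_id=dataset_id, matrix=matrix,
                             conditions=conditions, annotation=annotation)


def write_qc_report(qc: QCReport, table_path: str | Path, params_path: str | Path) -> None:
    qc.table.to_csv(table_path, sep="\t", float_format=FLOAT_FORMAT)
    Path(params_path).write_text(json.dumps(
        {"dataset_id": qc.dataset_id, **qc.params}, indent=1, sort_keys=True))


DE_COLUMNS = ["logFC", "avg_expr", "t_mod", "p", "adj_p", "call"]


def write_de_table(de: pd.DataFrame, path: str | Path,
                   sidecar_path: str | Path | None = None) -> None:
    de[DE_COLUMNS].to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene")
    if sidecar_path is not None:
        prior = de.attrs.get("prior")
        payload = {
            "dataset_id": de.attrs.get("dataset_id"),
            "thresholds": de.attrs.get("thresholds", {}),
            "prior": None if prior is None else {
                "d0": "inf" if prior.is_infinite else prior.d0,
                "s0_sq": prior.s0_sq,
                "n_genes_used": prior.n_genes_used,
            },
        }
        Path(sidecar_path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_deg_sets(degs: DegSets, directory: str | Path) -> None:
    """One two-column TSV (gene, direction) per dataset plus a background JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ds in degs.dataset_ids:
        rows = [(g, "up") for g in sorted(degs.up[ds])]
        rows += [(g, "down") for g in sorted(degs.down[ds])]
        pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(
            directory / f"{ds}.degs.tsv", sep="\t", index=False)
    (directory / "background.json").write_text(
        json.dumps(degs.background, indent=1, sort_keys=True))


def read_deg_sets(directory: str | Path) -> DegSets:
    directory = Path(directory)
    background = json.loads((directory / "background.json").read_text())
    up, down = {}, {}
    for ds in background:
        table = pd.read_csv(directory / f"{ds}.degs.tsv", sep="\t")
        up[ds] = set(table.loc[table["direction"] == "up", "gene"])
        down[ds] = set(table.loc[table["direction"] == "down", "gene"])
    return DegSets(up=up, down=down, background=background)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, inputs: dict, params: dict,
                   outputs: list[str | Path], version: str) -> None:
    """Record every output file with a content hash, plus inputs/parameters."""
    payload = {
        "version": version,
        "inputs": inputs,
        "params": params,
        "outputs": {str(Path(p).name): sha256_file(p) for p in sorted(map(str, outputs))},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
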