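"""Pipeline configuration: a single human-readable YAML file.

The config registers datasets (paths + ids), thresholds for the two DEG
modes (per-dataset mode uses |logFC| and FDR; signature mode uses FDR
only), the known-marker and suspect gene lists, the multi-set criteria
parameters, gene-set collection paths, the RNG seed and the output
directory.  Every run writes the resolved config beside its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from qsig.types import ValidationError

# Known quiescence markers reported across prior satellite-cell studies.
DEFAULT_MARKERS = ["Calcr", "Notch1", "Chrdl2", "Lama3", "Pax7", "Bmp6"]


@dataclass
class DatasetEntry:
    dataset_id: str
    matrix: str
    metadata: str
    annotation: str | None = None


@dataclass
class PipelineConfig:
    datasets: list[DatasetEntry] = field(default_factory=list)
    collection: str | None = None
    output_dir: str = "qsig_output"
    seed: int = 0
    # per-dataset DEG mode
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    use_lfc: bool = True
    # enrichment
    min_set_size: int = 5
    enrichment_fdr_max: float = 0.05
    # QC
    rle_threshold: float = 0.15
    quantile_normalize: bool = False
    # multi-set criteria
    markers: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    suspects: list[str] = field(default_factory=list)
    min_deg: int = 300
    min_marker_frac: float = 0.5
    min_mean_ji: float | None = None
    criteria: list[str] = field(default_factory=lambda: ["n_deg", "markers", "similarity"])
    # network
    min_shared_frac: float = 0.10
    top_k: int | None = 3

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max < 1) or not (0 < self.enrichment_fdr_max < 1):
            raise ValidationError("FDR thresholds must lie in (0, 1)")
        if self.lfc_min <= 0:
            raise ValidationError("lfc_min must be positive")
        ids = [d.dataset_id for d in self.datasets]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate dataset ids in config")

    def dataset(self, dataset_id: str) -> DatasetEntry:
        for entry in self.datasets:
            if entry.dataset_id == dataset_id:
                return entry
        raise ValidationError(f"dataset {dataset_id!r} not registered in config")

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        payload = yaml.safe_load(path.read_text()) or {}
        datasets = [DatasetEntry(**d) for d in payload.pop("datasets", [])]
        return cls(datasets=datasets, **payload)
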