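"""Shared domain containers for the pipeline.

Expression data live in pandas objects throughout: an expression matrix is a
DataFrame with features (probesets or gene symbols) as rows and samples as
columns, on the log2 scale.  Conditions are the two compared cell states,
``QSC`` (quiescent) and ``ASC`` (activated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("QSC", "ASC")


class ValidationError(ValueError):
    """An input violated a documented invariant; the message names it."""


@dataclass
class ExpressionDataset:
    """One study's log2 expression matrix plus sample labels and annotation.

    Parameters
    ----------
    dataset_id:
        Short identifier for the study (e.g. a GEO accession).
    matrix:
        Features x samples DataFrame of log2 intensities.
    conditions:
        Mapping sample id -> condition, each in ``{"QSC", "ASC"}``.
    annotation:
        Optional probeset -> gene mapping with columns ``gene_symbol`` and
        (optionally) ``gene_id``, indexed by probeset id.  Absent for
        matrices already at gene level.
    """

    dataset_id: str
    matrix: pd.DataFrame
    conditions: dict[str, str]
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.conditions = dict(self.conditions)
        self.matrix = self.matrix.rename_axis("gene")
        missing = [s for s in self.matrix.columns if s not in self.conditions]
        if missing:
            raise ValidationError(
                f"{self.dataset_id}: samples without condition labels: {missing}"
            )
        bad = {s: c for s, c in self.conditions.items() if c not in CONDITIONS}
        if bad:
            raise ValidationError(
                f"{self.dataset_id}: conditions must be QSC or ASC, got {bad}"
            )
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise ValidationError(f"{self.dataset_id}: non-finite intensities")

    def samples(self, condition: str) -> list[str]:
        """Sample ids of the matrix belonging to one condition, in column order."""
        return [s for s in self.matrix.columns if self.conditions[s] == condition]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionDataset":
        keep = [s for s in self.matrix.columns if s in set(keep)]
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            matrix=self.matrix[keep].copy(),
            conditions={s: self.conditions[s] for s in keep},
            annotation=self.annotation,
        )


@dataclass
class QCReport:
    """Per-sample relative log expression (RLE) summary with outlier flags.

    ``table`` has one row per sample with columns ``rle_median``, ``rle_iqr``
    and boolean ``flagged``; ``params`` records the threshold used.
    """

    dataset_id: str
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


@dataclass
class PriorEstimate:
    """Empirical-Bayes variance prior shared across genes.

    ``d0`` is the prior degrees of freedom (``math.inf`` when the observed
    log-variance dispersion is entirely explained by sampling, in which case
    every posterior variance equals ``s0_sq``); ``s0_sq`` is the prior
    variance on the log2 scale.
    """

    d0: float
    s0_sq: float
    n_genes_used: int

    @property
    def is_infinite(self) -> bool:
        return np.isinf(self.d0)


@dataclass
class GeneSetCollection:
    """Named gene sets with a declared background universe (GMT-backed)."""

    name: str
    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError(f"collection {self.name!r}: empty universe")
        if any(not n for n in self.sets):
            raise ValidationError(f"collection {self.name!r}: empty set name")

    def restrict(self, universe: Iterable[str], min_size: int = 0) -> "GeneSetCollection":
        """Restrict all sets to a new universe, dropping sets below ``min_size``."""
        universe = set(universe)
        sets = {
            name: genes & universe
            for name, genes in self.sets.items()
        }
        sets = {n: g for n, g in sets.items() if len(g) >= max(min_size, 1)}
        return GeneSetCollection(name=self.name, sets=sets, universe=universe)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class DegSets:
    """Per-dataset up/down DEG sets with the per-dataset tested background size."""

    up: dict[str, set]
    down: dict[str, set]
    background: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.up) != set(self.down) or set(self.up) != set(self.background):
            raise ValidationError("DegSets: dataset ids differ between fields")
        for ds in self.up:
            both = self.up[ds] & self.down[ds]
            if both:
                raise ValidationError(
                    f"DegSets: {ds} has genes both up and down: {sorted(both)[:5]}"
                )

    @property
    def dataset_ids(self) -> list[str]:
        return sorted(self.up)

    def direction(self, direction: str) -> dict[str, set]:
        if direction not in ("up", "down"):
            raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
        return self.up if direction == "up" else self.down


@dataclass
class ConsensusSignature:
    """Genes up/down-regulated in every dataset of the selected ensemble.

    ``flagged_up`` lists signature genes that match a user-supplied suspect
    list (e.g. isolation-stress immediate-early genes) and therefore need
    scrutiny before being interpreted as quiescence markers.
    """

    ensemble: list[str]
    up: list[str]
    down: list[str]
    thresholds: dict = field(default_factory=dict)
    flagged_up: list[str] = field(default_factory=list)
    flagged_down: list[str] = field(default_factory=list)


def condition_counts(conditions: Mapping[str, str]) -> dict[str, int]:
    out = {c: 0 for c in CONDITIONS}
    for c in conditions.values():
        out[c] = out.get(c, 0) + 1
    return out
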