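"""Synthetic multi-dataset compendia with known ground truth.

The generator emulates the statistical structure of a compendium of
microarray studies comparing quiescent (QSC) and activated (ASC) muscle
stem cells: a shared planted up/down signature, dataset-private DEGs,
heterogeneous per-dataset effect scales and replicate counts (3-6 per
group), within-gene-set correlation induced by a shared per-set latent
factor, and "isolation-stress" contaminant genes up-shifted in the QSC
group of every dataset — the immediate-early-gene artifact of conventional
cell-isolation protocols.

Noise is additive Gaussian on the log2 scale; correlation comes from a
per-block latent factor, the simplest mechanism matching the assumptions of
the competitive gene-set test.  Gene identifiers are synthetic symbols
("G000001"...), with the reserved prefix "MKR" for designated quiescence
markers so downstream tests are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from qsig.types import ExpressionDataset, GeneSetCollection, ValidationError

MARKER_PREFIX = "MKR"


@dataclass(frozen=True)
class CompendiumSpec:
    """Parameters of a simulated compendium.

    Defaults describe a realistic eight-study compendium: ~6000 measured
    genes, a planted consensus signature of 200 up / 500 down genes, 150
    dataset-private DEGs per study, 3-6 replicates per group, planted
    |log2 fold changes| around 2 (modest gene-to-gene spread: consensus genes
    are by construction strongly differential everywhere) with per-dataset
    scale heterogeneity,
    residual SD 0.5 on the log2 scale, mild within-set correlation (0.1)
    and 20 isolation-stress contaminants.
    """

    n_datasets: int = 8
    n_genes: int = 6000
    n_up_shared: int = 200
    n_down_shared: int = 500
    n_specific: int = 150
    reps_per_group: tuple[tuple[int, int], ...] | None = None  # (n_qsc, n_asc) per dataset
    effect_mean: float = 2.0
    effect_sd: float = 0.25
    scale_factors: tuple[float, ...] | None = None
    noise_sd: float = 0.5
    rho_within_set: float = 0.1
    n_contaminant: int = 20
    n_markers: int = 6
    block_size: int = 50
    seed: int = 0

    def validate(self) -> None:
        planted = (
            self.n_up_shared
            + self.n_down_shared
            + self.n_datasets * self.n_specific
            + self.n_contaminant
        )
        if planted > self.n_genes:
            raise ValidationError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.noise_sd <= 0 or self.effect_sd <= 0:
            raise ValidationError("noise_sd and effect_sd must be positive")
        if not (0 <= self.rho_within_set < 1):
            raise ValidationError("rho_within_set must lie in [0, 1)")
        if self.n_markers > self.n_up_shared:
            raise ValidationError("n_markers cannot exceed n_up_shared")
        if self.scale_factors is not None:
            if len(self.scale_factors) != self.n_datasets:
                raise ValidationError("scale_factors length must equal n_datasets")
            if any(s <= 0 for s in self.scale_factors):
                raise ValidationError("scale_factors must be positive")
        if self.reps_per_group is not None:
            if len(self.reps_per_group) != self.n_datasets:
                raise ValidationError("reps_per_group length must equal n_datasets")
            for nq, na in self.reps_per_group:
                if not (2 <= nq <= 8 and 2 <= na <= 8):
                    raise ValidationError("replicate counts must lie in [2, 8]")
        if self.n_datasets < 1 or self.n_genes < 1:
            raise ValidationError("n_datasets and n_genes must be positive")


@dataclass
class CompendiumTruth:
    """Ground truth of a simulated compendium.

    Truth sets are disjoint except ``marker_genes``, which are a subset of
    ``up_shared``.  ``correlation_blocks`` records the latent-factor block
    of every gene (the "synthetic gene sets" whose members are correlated).
    """

    genes: list[str]
    up_shared: set
    down_shared: set
    contaminant: set
    marker_genes: set
    specific: dict[str, set] = field(default_factory=dict)
    realized_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    correlation_blocks: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes,
            "up_shared": sorted(self.up_shared),
            "down_shared": sorted(self.down_shared),
            "contaminant": sorted(self.contaminant),
            "marker_genes": sorted(self.marker_genes),
            "specific": {k: sorted(v) for k, v in self.specific.items()},
            "realized_effects": self.realized_effects,
            "correlation_blocks": self.correlation_blocks,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CompendiumTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            genes=list(payload["genes"]),
            up_shared=set(payload["up_shared"]),
            down_shared=set(payload["down_shared"]),
            contaminant=set(payload["contaminant"]),
            marker_genes=set(payload["marker_genes"]),
            specific={k: set(v) for k, v in payload["specific"].items()},
            realized_effects=payload["realized_effects"],
            correlation_blocks={k: list(v) for k, v in payload["correlation_blocks"].items()},
        )


def _effect_magnitudes(rng: np.random.Generator, n: int, spec: CompendiumSpec) -> np.ndarray:
    """Planted |log2FC| values: folded normal around effect_mean."""
    return np.abs(rng.normal(spec.effect_mean, spec.effect_sd, size=n))


def simulate_compendium(
    spec: CompendiumSpec,
) -> tuple[list[ExpressionDataset], CompendiumTruth]:
    """Simulate a compendium of K datasets sharing one gene namespace.

    Every dataset carries the shared planted signature scaled by its
    per-dataset factor, its own private DEGs, and the contaminant genes
    up-shifted in QSC samples.  Identical spec (including seed) gives
    identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    genes = [f"G{i + 1:06d}" for i in range(spec.n_genes)]
    for i in range(spec.n_markers):
        genes[i] = f"{MARKER_PREFIX}{i + 1:03d}"
    cursor = 0
    up_shared = genes[cursor:cursor + spec.n_up_shared]
    cursor += spec.n_up_shared
    down_shared = genes[cursor:cursor + spec.n_down_shared]
    cursor += spec.n_down_shared
    contaminant = genes[cursor:cursor + spec.n_contaminant]
    cursor += spec.n_contaminant
    dataset_ids = [f"DS{i + 1:02d}" for i in range(spec.n_datasets)]
    specific: dict[str, list[str]] = {}
    for ds in dataset_ids:
        specific[ds] = genes[cursor:cursor + spec.n_specific]
        cursor += spec.n_specific

    blocks: dict[str, list[str]] = {}
    for b in range(0, spec.n_genes, spec.block_size):
        blocks[f"BLOCK{b // spec.block_size + 1:04d}"] = genes[b:b + spec.block_size]
    block_of = np.repeat(
        np.arange((spec.n_genes + spec.block_size - 1) // spec.block_size),
        spec.block_size,
    )[: spec.n_genes]

    if spec.scale_factors is None:
        scale_factors = tuple(rng.uniform(0.9, 1.4, size=spec.n_datasets).round(3))
    else:
        scale_factors = spec.scale_factors
    if spec.reps_per_group is None:
        reps = tuple(
            (int(rng.integers(3, 7)), int(rng.integers(3, 7)))
            for _ in range(spec.n_datasets)
        )
    else:
        reps = spec.reps_per_group

    # shared effect magnitudes, realized once and re-scaled per dataset
    up_eff = _effect_magnitudes(rng, spec.n_up_shared, spec)
    down_eff = _effect_magnitudes(rng, spec.n_down_shared, spec)
    cont_eff = _effect_magnitudes(rng, spec.n_contaminant, spec)

    gene_pos = {g: i for i, g in enumerate(genes)}
    rho = spec.rho_within_set
    n_blocks = int(block_of.max()) + 1 if spec.n_genes else 0

    datasets = []
    realized: dict[str, dict[str, float]] = {}
    truth_specific: dict[str, set] = {}
    for d, ds in enumerate(dataset_ids):
        n_q, n_a = reps[d]
        n_samples = n_q + n_a
        scale = float(scale_factors[d])
        baseline = rng.uniform(6.0, 12.0, size=spec.n_genes)

        effect = np.zeros(spec.n_genes)
        for gene_list, eff, sign in (
            (up_shared, up_eff, +1.0),
            (down_shared, down_eff, -1.0),
            (contaminant, cont_eff, +1.0),
        ):
            idx = [gene_pos[g] for g in gene_list]
            effect[idx] = sign * eff * scale
        spec_eff = _effect_magnitudes(rng, spec.n_specific, spec)
        spec_sign = rng.choice([-1.0, 1.0], size=spec.n_specific)
        idx = [gene_pos[g] for g in specific[ds]]
        effect[idx] = spec_sign * spec_eff * scale
        truth_specific[ds] = set(specific[ds])

        factors = rng.standard_normal((n_blocks, n_samples))
        eps = rng.standard_normal((spec.n_genes, n_samples))
        residual = spec.noise_sd * (
            np.sqrt(rho) * factors[block_of] + np.sqrt(1.0 - rho) * eps
        )
        is_qsc = np.zeros(n_samples)
        is_qsc[:n_q] = 1.0
        matrix = baseline[:, None] + effect[:, None] * is_qsc[None, :] + residual

        sample_ids = [f"{ds}_QSC{i + 1}" for i in range(n_q)] + [
            f"{ds}_ASC{i + 1}" for i in range(n_a)
        ]
        conditions = {s: ("QSC" if i < n_q else "ASC") for i, s in enumerate(sample_ids)}
        datasets.append(
            ExpressionDataset(
                dataset_id=ds,
                matrix=pd.DataFrame(
                    matrix, index=pd.Index(genes, name="gene"), columns=sample_ids
                ),
                conditions=conditions,
            )
        )
        planted = {g: float(effect[gene_pos[g]]) for g in
                   (*up_shared, *down_shared, *contaminant, *specific[ds])}
        realized[ds] = planted

    truth = CompendiumTruth(
        genes=genes,
        up_shared=set(up_shared),
        down_shared=set(down_shared),
        contaminant=set(contaminant),
        marker_genes=set(genes[: spec.n_markers]),
        specific=truth_specific,
        realized_effects=realized,
        correlation_blocks=blocks,
    )
    return datasets, truth


def simulate_geneset_collection(
    n_sets: int,
    set_sizes: int | list[int],
    overlap_frac: float,
    truth: CompendiumTruth,
    seed: int = 0,
    n_signal_up: int = 0,
    n_signal_down: int = 0,
    signal_purity: float = 0.8,
    align_to_blocks: bool = False,
    name: str = "synthetic_collection",
) -> GeneSetCollection:
    """Gene-set collection over the compendium namespace.

    Background ("null") sets share a common core so each pair's shared-gene
    fraction is near ``overlap_frac`` (exactly disjoint at 0).  Optional
    "signal" sets are built mostly (``signal_purity``) from the planted
    up/down truth genes, the remainder filler, so enrichment tests have
    known positives.  ``align_to_blocks`` instead samples each null set
    from within one latent correlation block, giving within-set correlation
    equal to the compendium's ``rho_within_set`` — the configuration used
    for calibration studies of the competitive test.
    """
    if not (0 <= overlap_frac < 1):
        raise ValidationError("overlap_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    universe = list(truth.genes)
    if isinstance(set_sizes, int):
        set_sizes = [set_sizes] * n_sets
    if len(set_sizes) != n_sets:
        raise ValidationError("set_sizes length must equal n_sets")
    if any(s > len(universe) for s in set_sizes):
        raise ValidationError("set sizes cannot exceed the universe size")

    sets: dict[str, set] = {}
    if align_to_blocks:
        block_names = sorted(truth.correlation_blocks)
        if n_sets > len(block_names):
            raise ValidationError(
                f"align_to_blocks: only {len(block_names)} blocks for {n_sets} sets"
            )
        chosen = rng.choice(len(block_names), size=n_sets, replace=False)
        for i, (bi, size) in enumerate(zip(sorted(chosen), set_sizes)):
            block = truth.correlation_blocks[block_names[bi]]
            if size > len(block):
                raise ValidationError(
                    f"set size {size} exceeds block size {len(block)}"
                )
            picked = rng.choice(len(block), size=size, replace=False)
            sets[f"SET{i + 1:04d}"] = {block[j] for j in sorted(picked)}
    elif n_sets > 0:
        core_size = int(round(overlap_frac * min(set_sizes)))
        pool = rng.permutation(len(universe))
        core = {universe[j] for j in pool[:core_size]}
        offset = core_size
        for i, size in enumerate(set_sizes):
            rest_n = size - core_size
            if offset + rest_n > len(universe):
                raise ValidationError("universe too small for disjoint set remainders")
            rest = {universe[j] for j in pool[offset:offset + rest_n]}
            offset += rest_n
            sets[f"SET{i + 1:04d}"] = core | rest

    for prefix, source, count in (
        ("SIG_UP", sorted(truth.up_shared), n_signal_up),
        ("SIG_DOWN", sorted(truth.down_shared), n_signal_down),
    ):
        size = set_sizes[0] if set_sizes else 50
        for i in range(count):
            n_signal = min(int(round(signal_purity * size)), len(source))
            picked = rng.choice(len(source), size=n_signal, replace=False)
            members = {source[j] for j in sorted(picked)}
            filler_pool = sorted(set(universe) - set(source))
            n_fill = size - n_signal
            fill_idx = rng.choice(len(filler_pool), size=n_fill, replace=False)
            members |= {filler_pool[j] for j in sorted(fill_idx)}
            sets[f"{prefix}{i + 1:02d}"] = members

    return GeneSetCollection(name=name, sets=sets, universe=set(universe))


def benchmark_spec(seed: int = 0, n_bad: int = 2) -> CompendiumSpec:
    """The standard benchmark compendium: 8 datasets, 200 up / 500 down
    planted signature genes, 20 contaminants, and ``n_bad`` low-quality
    datasets whose effect scale is too small to yield DEGs or markers.
    """
    n_datasets = 8
    good_scales = [1.0, 1.2, 0.95, 1.1, 1.3, 1.05, 1.15, 0.9][: n_datasets - n_bad]
    scales = tuple(good_scales + [0.12] * n_bad)
    reps = tuple(
        [(3, 3), (3, 3), (4, 4), (3, 4), (6, 5), (4, 3), (3, 3), (5, 4)][:n_datasets]
    )
    return CompendiumSpec(
        n_datasets=n_datasets,
        scale_factors=scales,
        reps_per_group=reps,
        seed=seed,
    )
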