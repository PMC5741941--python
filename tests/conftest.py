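"""Shared fixtures: small synthetic datasets and the expensive study runs.

Session-scoped fixtures cache the benchmark-compendium analysis and the
null-calibration compendia so the statistical and end-to-end tests reuse
one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qsig import (
    benchmark_spec,
    call_degs,
    consensus_signature,
    moderated_t_test,
    rank_datasets,
    simulate_compendium,
)
from qsig.synthetic import CompendiumSpec
from qsig.types import DegSets, ExpressionDataset


def make_dataset(
    n_genes: int = 60,
    n_qsc: int = 3,
    n_asc: int = 3,
    effect_genes: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    dataset_id: str = "TEST",
) -> ExpressionDataset:
    """Small two-group dataset with optional planted mean shifts in QSC."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"Q{i}" for i in range(n_qsc)] + [f"A{i}" for i in range(n_asc)]
    conditions = {s: ("QSC" if s.startswith("Q") else "ASC") for s in samples}
    matrix = rng.normal(8.0, noise_sd, size=(n_genes, n_qsc + n_asc))
    frame = pd.DataFrame(matrix, index=genes, columns=samples)
    for gene, effect in (effect_genes or {}).items():
        frame.loc[gene, frame.columns[:n_qsc]] += effect
    return ExpressionDataset(dataset_id=dataset_id, matrix=frame, conditions=conditions)


@pytest.fixture(scope="session")
def benchmark_run():
    """Full analysis of the standard benchmark compendium (seed 1)."""
    spec = benchmark_spec(seed=1)
    datasets, truth = simulate_compendium(spec)
    up, down, background = {}, {}, {}
    de_tables = {}
    for ds in datasets:
        de = moderated_t_test(ds)
        de_tables[ds.dataset_id] = de
        up[ds.dataset_id], down[ds.dataset_id] = call_degs(de, use_lfc=False)
        background[ds.dataset_id] = len(de)
    degs = DegSets(up=up, down=down, background=background)
    report = rank_datasets(degs, markers=sorted(truth.marker_genes))
    signature = consensus_signature(
        degs, report=report, suspects=sorted(truth.contaminant)
    )
    return {
        "spec": spec,
        "datasets": datasets,
        "truth": truth,
        "de_tables": de_tables,
        "degs": degs,
        "report": report,
        "signature": signature,
    }


@pytest.fixture(scope="session")
def null_dataset():
    """One null dataset (2000 genes, no planted effects, no correlation)."""
    spec = CompendiumSpec(
        n_datasets=1, n_genes=2000, n_up_shared=0, n_down_shared=0,
        n_specific=0, n_contaminant=0, n_markers=0, rho_within_set=0.0, seed=3,
    )
    (dataset,), _ = simulate_compendium(spec)
    return dataset
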