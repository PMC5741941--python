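#!/usr/bin/env python
"""Simulate the benchmark compendium and write it to disk.

Eight datasets sharing a 6000-gene namespace: a planted consensus signature
(200 up / 500 down in the quiescent state), 150 dataset-private DEGs each,
20 isolation-stress contaminants up-shifted in QSC everywhere, six known
quiescence markers, and two deliberately under-powered "bad" datasets that
the significance ranking should later exclude.  Matrices, metadata, ground
truth, a gene-set collection and a ready-to-run config go to
``scratch/compendium`` (large, regenerable); a summary table goes to
``results``.
"""

from pathlib import Path

import pandas as pd

from qsig import io, simulate_compendium, simulate_geneset_collection
from qsig.config import DatasetEntry, PipelineConfig
from qsig.genesets import write_gmt
from qsig.synthetic import benchmark_spec

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "compendium"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    spec = benchmark_spec(seed=SEED)
    datasets, truth = simulate_compendium(spec)

    entries, rows = [], []
    for ds, scale in zip(datasets, spec.scale_factors):
        matrix = SCRATCH / f"{ds.dataset_id}.expr.tsv"
        meta = SCRATCH / f"{ds.dataset_id}.meta.tsv"
        io.write_expression_tsv(ds, matrix, meta)
        entries.append(DatasetEntry(ds.dataset_id, str(matrix), str(meta)))
        rows.append({
            "dataset": ds.dataset_id,
            "n_qsc": len(ds.samples("QSC")),
            "n_asc": len(ds.samples("ASC")),
            "effect_scale": scale,
        })
    truth.to_json(SCRATCH / "truth.json")

    collection = simulate_geneset_collection(
        n_sets=30, set_sizes=50, overlap_frac=0.1, truth=truth, seed=SEED + 1,
        n_signal_up=2, n_signal_down=2,
    )
    write_gmt(collection, SCRATCH / "collection.gmt")

    config = PipelineConfig(
        datasets=entries,
        collection=str(SCRATCH / "collection.gmt"),
        output_dir=str(SCRATCH / "analysis"),
        seed=SEED,
        markers=sorted(truth.marker_genes),
        suspects=sorted(truth.contaminant),
    )
    config.to_yaml(SCRATCH / "config.yaml")

    summary = pd.DataFrame(rows).set_index("dataset")
    summary.to_csv(RESULTS / "simulation_summary.tsv", sep="\t")
    print(f"wrote {len(datasets)} datasets under {SCRATCH}")
    print(summary.to_string())
    print(f"planted: {len(truth.up_shared)} up, {len(truth.down_shared)} down, "
          f"{len(truth.contaminant)} contaminants, {len(truth.marker_genes)} markers")


if __name__ == "__main__":
    main()
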