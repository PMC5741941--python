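#!/usr/bin/env python
"""Per-dataset analysis: QC, differential expression, gene-set enrichment.

Runs the standardized individual-dataset pipeline (RLE outlier screen,
moderated-t differential expression with BH correction, VIF-corrected
competitive gene-set test) on every dataset of the simulated compendium and
tabulates the DEG counts — the per-study numbers whose heterogeneity
motivates the multi-set analysis.
"""

from pathlib import Path

import pandas as pd

from qsig.config import PipelineConfig
from qsig.genesets import read_gmt
from qsig.pipeline import run_individual

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "compendium"
RESULTS = ROOT / "results"


def main() -> None:
    config = PipelineConfig.from_yaml(SCRATCH / "config.yaml")
    collection = read_gmt(config.collection)
    rows = []
    for entry in config.datasets:
        artifacts = run_individual(config, entry.dataset_id, collection=collection)
        de = artifacts["de"]
        enr = artifacts["enrichment"]
        rows.append({
            "dataset": entry.dataset_id,
            "genes_tested": len(de),
            "samples_flagged": len(artifacts["qc"].flagged),
            "up_strict": int((de["call"] == "up").sum()),
            "down_strict": int((de["call"] == "down").sum()),
            "sets_enriched": int((enr["adj_p"] <= config.enrichment_fdr_max).sum()),
        })
    table = pd.DataFrame(rows).set_index("dataset")
    table.to_csv(RESULTS / "deg_counts.tsv", sep="\t")
    print("per-dataset DEG counts (|logFC| >= 1, FDR <= 0.05) and enriched sets:")
    print(table.to_string())
    print("note the two under-powered datasets with ~no DEGs — candidates for "
          "exclusion by the significance ranking.")


if __name__ == "__main__":
    main()
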