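#!/usr/bin/env python
"""Multi-set analysis: similarity, landscape, ranking, consensus signature.

Consumes the per-dataset runs, computes pairwise Jaccard similarity of the
DEG lists, the best dataset combination per intersection degree with exact
overlap tests, the three-criterion significance ranking, and intersects the
selected ensemble's DEG calls into the consensus quiescence signature
(flagging any gene on the suspect/immediate-early list).  Small result
tables are copied into ``results``.
"""

import shutil
from pathlib import Path

from qsig.config import PipelineConfig
from qsig.multiset import landscape_table
from qsig.pipeline import run_multiset

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "compendium"
RESULTS = ROOT / "results"

COPY = [
    "jaccard_up.tsv", "jaccard_down.tsv", "landscape.tsv",
    "significance_report.tsv", "signature.json",
    "enrichment_matrix.tsv", "network_nodes.tsv", "network_edges.tsv",
    "ora_up.tsv", "ora_membership.tsv",
]


def main() -> None:
    config = PipelineConfig.from_yaml(SCRATCH / "config.yaml")
    results = run_multiset(config)
    report = results["report"]
    signature = results["signature"]
    print("significance ranking:")
    print(report[["n_up", "n_down", "marker_frac", "mean_ji", "include"]].to_string())
    print(f"\nensemble: {'+'.join(signature.ensemble)}")
    print(f"consensus signature: {len(signature.up)} up / {len(signature.down)} down")
    print(f"suspect (immediate-early-like) genes flagged in the signature: "
          f"{len(signature.flagged_up) + len(signature.flagged_down)}")
    print("\nintersection landscape (best combination per degree):")
    print(landscape_table(results["landscape"])
          [["combination", "up_overlap", "down_overlap"]].to_string())

    out = Path(config.output_dir) / "multiset"
    for name in COPY:
        src = out / name
        if src.exists():
            shutil.copy(src, RESULTS / name)
    print(f"\ncopied multi-set tables to {RESULTS}")


if __name__ == "__main__":
    main()
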