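"""Stage orchestration: individual-dataset runs and the multi-set analysis.

``run_individual`` executes preprocess -> differential expression ->
competitive enrichment for one registered dataset and writes every artifact
with a manifest.  ``run_multiset`` consumes the per-dataset outputs and
runs the full multi-set chain (signature-mode DEG sets, Jaccard matrices,
intersection landscape, significance ranking, consensus signature, ORA and
the overlap network), again with a manifest.  Reruns with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import networkx as nx
import pandas as pd

import qsig
from qsig import io
from qsig.config import PipelineConfig
from qsig.diffexpr import call_degs, group_residuals, moderated_t_test
from qsig.genesets import camera_test, enrichment_matrix, fisher_ora, read_gmt
from qsig.multiset import (
    consensus_signature,
    intersection_landscape,
    jaccard_matrix,
    landscape_table,
    rank_datasets,
)
from qsig.network import build_overlap_network, ora_membership_table
from qsig.preprocess import aggregate_probesets, drop_outliers, quantile_normalize, rle_stats
from qsig.types import (
    DegSets,
    ExpressionDataset,
    GeneSetCollection,
    ValidationError,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = io.FLOAT_FORMAT


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and dataset id."""

    def __init__(self, stage: str, dataset_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for dataset {dataset_id!r}: {cause}")
        self.stage = stage
        self.dataset_id = dataset_id
        self.__cause__ = cause


def _load_dataset(config: PipelineConfig, dataset_id: str) -> ExpressionDataset:
    entry = config.dataset(dataset_id)
    return io.read_expression_tsv(
        dataset_id, entry.matrix, entry.metadata, entry.annotation
    )


def run_individual(
    config: PipelineConfig,
    dataset_id: str,
    collection: GeneSetCollection | None = None,
) -> dict:
    """QC -> differential expression -> enrichment for one dataset.

    Writes ``<out>/<dataset_id>/{qc.tsv, qc_params.json, de.tsv, de_params.json,
    enrichment.tsv, manifest.json}`` and returns the in-memory artifacts.
    """
    out = Path(config.output_dir) / dataset_id
    out.mkdir(parents=True, exist_ok=True)
    try:
        dataset = _load_dataset(config, dataset_id)
    except ValidationError as exc:
        raise StageError("load", dataset_id, exc) from exc

    try:
        if config.quantile_normalize:
            dataset = ExpressionDataset(
                dataset_id=dataset.dataset_id,
                matrix=quantile_normalize(dataset.matrix),
                conditions=dataset.conditions,
                annotation=dataset.annotation,
            )
        qc = rle_stats(dataset.matrix, threshold=config.rle_threshold,
                       dataset_id=dataset_id)
        dataset = drop_outliers(dataset, qc)
        if dataset.annotation is not None and "gene_symbol" in dataset.annotation.columns:
            dataset = aggregate_probesets(dataset)
        logger.info("%s: %d genes x %d samples after preprocessing (%d flagged)",
                    dataset_id, *dataset.matrix.shape, len(qc.flagged))
    except ValidationError as exc:
        raise StageError("preprocess", dataset_id, exc) from exc

    try:
        de = moderated_t_test(dataset, lfc_min=config.lfc_min,
                              fdr_max=config.fdr_max, use_lfc=config.use_lfc)
    except ValidationError as exc:
        raise StageError("diffexpr", dataset_id, exc) from exc

    enrichment = None
    if collection is None and config.collection:
        collection = read_gmt(config.collection)
    if collection is not None:
        try:
            residuals = group_residuals(dataset)
            enrichment = camera_test(de, residuals, collection,
                                     min_set_size=config.min_set_size)
        except ValidationError as exc:
            raise StageError("enrichment", dataset_id, exc) from exc

    io.write_qc_report(qc, out / "qc.tsv", out / "qc_params.json")
    io.write_de_table(de, out / "de.tsv", out / "de_params.json")
    outputs = [out / "qc.tsv", out / "qc_params.json", out / "de.tsv",
               out / "de_params.json"]
    if enrichment is not None:
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", float_format=FLOAT_FORMAT)
        outputs.append(out / "enrichment.tsv")
    entry = config.dataset(dataset_id)
    io.write_manifest(
        out / "manifest.json",
        inputs=asdict(entry),
        params={"lfc_min": config.lfc_min, "fdr_max": config.fdr_max,
                "use_lfc": config.use_lfc, "rle_threshold": config.rle_threshold,
                "quantile_normalize": config.quantile_normalize,
                "min_set_size": config.min_set_size, "seed": config.seed},
        outputs=outputs,
        version=qsig.__version__,
    )
    return {"qc": qc, "de": de, "enrichment": enrichment, "dataset": dataset}


def run_multiset(
    config: PipelineConfig,
    individual: dict[str, dict] | None = None,
) -> dict:
    """Full multi-set chain over all registered datasets.

    Signature-mode DEG sets (adjusted p only) feed the Jaccard matrices,
    intersection landscape, significance ranking and consensus signature;
    the consensus up and down lists are then tested by ORA against the
    collection restricted to the genes measured in every ensemble dataset,
    and the per-dataset enrichment tables are summarized into the
    direction-coded matrix and the overlap network.
    """
    if individual is None:
        individual = {}
        collection = read_gmt(config.collection) if config.collection else None
        for entry in config.datasets:
            individual[entry.dataset_id] = run_individual(
                config, entry.dataset_id, collection=collection
            )
    if len(individual) < 2:
        raise ValidationError("run_multiset needs >= 2 completed datasets")
    out = Path(config.output_dir) / "multiset"
    out.mkdir(parents=True, exist_ok=True)

    up, down, background = {}, {}, {}
    tested: dict[str, set] = {}
    for ds, artifacts in individual.items():
        de = artifacts["de"]
        up[ds], down[ds] = call_degs(de, lfc_min=config.lfc_min,
                                     fdr_max=config.fdr_max, use_lfc=False)
        background[ds] = len(de)
        tested[ds] = set(de.index)
    degs = DegSets(up=up, down=down, background=background)
    io.write_deg_sets(degs, out / "degs")

    ji_up = jaccard_matrix(degs, "up")
    ji_down = jaccard_matrix(degs, "down")
    records = intersection_landscape(degs)
    report = rank_datasets(
        degs,
        markers=config.markers,
        min_deg=config.min_deg,
        min_marker_frac=config.min_marker_frac,
        min_mean_ji=config.min_mean_ji,
        criteria=tuple(config.criteria),
    )
    included = sorted(report.index[report["include"]])
    if len(included) < 2:
        raise ValidationError(
            f"only {len(included)} dataset(s) pass the significance criteria; "
            f"see the significance report at {out / 'significance_report.tsv'}"
        )
    signature = consensus_signature(
        degs, report=report, suspects=config.suspects,
        thresholds={"fdr_max": config.fdr_max, "use_lfc": False},
    )

    # ORA universe: genes measured in every ensemble dataset
    universe = set.intersection(*[tested[ds] for ds in signature.ensemble])
    ora_up = ora_down = membership = None
    network = None
    collection = read_gmt(config.collection) if config.collection else None
    if collection is not None:
        restricted = GeneSetCollection(
            name=collection.name,
            sets={n: s & universe for n, s in collection.sets.items()},
            universe=universe,
        )
        if set(signature.up) & universe:
            ora_up = fisher_ora(set(signature.up), restricted)
            membership, uncovered = ora_membership_table(
                ora_up, fdr_max=config.enrichment_fdr_max
            )
        if set(signature.down) & universe:
            ora_down = fisher_ora(set(signature.down), restricted)
        enr = {ds: a["enrichment"] for ds, a in individual.items()
               if a.get("enrichment") is not None}
        if enr:
            matrix = enrichment_matrix(enr, fdr_max=config.enrichment_fdr_max)
            matrix.to_csv(out / "enrichment_matrix.tsv", sep="\t")
            network = build_overlap_network(
                matrix, collection, min_shared_frac=config.min_shared_frac,
                top_k=config.top_k,
            )

    # serialize
    outputs = []
    ji_up.matrix.to_csv(out / "jaccard_up.tsv", sep="\t", float_format=FLOAT_FORMAT)
    ji_down.matrix.to_csv(out / "jaccard_down.tsv", sep="\t", float_format=FLOAT_FORMAT)
    landscape_table(records).to_csv(out / "landscape.tsv", sep="\t",
                                    float_format=FLOAT_FORMAT)
    report.to_csv(out / "significance_report.tsv", sep="\t", float_format=FLOAT_FORMAT)
    (out / "signature.json").write_text(json.dumps(
        {"ensemble": signature.ensemble, "up": signature.up, "down": signature.down,
         "flagged_up": signature.flagged_up, "flagged_down": signature.flagged_down,
         "thresholds": signature.thresholds}, indent=1, sort_keys=True))
    (out / "signature_up.txt").write_text("\n".join(signature.up) + "\n")
    (out / "signature_down.txt").write_text("\n".join(signature.down) + "\n")
    outputs += [out / "jaccard_up.tsv", out / "jaccard_down.tsv", out / "landscape.tsv",
                out / "significance_report.tsv", out / "signature.json",
                out / "signature_up.txt", out / "signature_down.txt"]
    if ora_up is not None:
        ora_up.to_csv(out / "ora_up.tsv", sep="\t", float_format=FLOAT_FORMAT)
        outputs.append(out / "ora_up.tsv")
    if ora_down is not None:
        ora_down.to_csv(out / "ora_down.tsv", sep="\t", float_format=FLOAT_FORMAT)
        outputs.append(out / "ora_down.tsv")
    if membership is not None and len(membership):
        membership.to_csv(out / "ora_membership.tsv", sep="\t")
        outputs.append(out / "ora_membership.tsv")
    if network is not None:
        _write_network(network, out)
        outputs += [out / "network.graphml", out / "network_edges.tsv",
                    out / "network_nodes.tsv"]
    if (out / "enrichment_matrix.tsv").exists():
        outputs.append(out / "enrichment_matrix.tsv")
    config.to_yaml(out / "resolved_config.yaml")
    outputs.append(out / "resolved_config.yaml")
    io.write_manifest(
        out / "manifest.json",
        inputs={"datasets": sorted(individual)},
        params={"fdr_max": config.fdr_max, "min_deg": config.min_deg,
                "min_marker_frac": config.min_marker_frac,
                "min_mean_ji": config.min_mean_ji, "criteria": list(config.criteria),
                "markers": list(config.markers), "suspects": list(config.suspects),
                "seed": config.seed},
        outputs=outputs,
        version=qsig.__version__,
    )
    return {
        "degs": degs,
        "jaccard_up": ji_up,
        "jaccard_down": ji_down,
        "landscape": records,
        "report": report,
        "signature": signature,
        "ora_up": ora_up,
        "ora_down": ora_down,
        "membership": membership,
        "network": network,
    }


def _write_network(network: nx.Graph, out: Path) -> None:
    nx.write_graphml(network, out / "network.graphml")
    nodes = pd.DataFrame(
        [{"set": n, **d} for n, d in sorted(network.nodes(data=True))]
    )
    nodes.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [{"set_a": min(a, b), "set_b": max(a, b), **d}
         for a, b, d in network.edges(data=True)]
    )
    if len(edges):
        edges = edges.sort_values(["set_a", "set_b"])
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False,
                 float_format=FLOAT_FORMAT)
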