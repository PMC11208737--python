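"""End-to-end orchestration: simulate -> enrich -> strictness -> caf ->
networks -> metrics/compare, with a structured config and a manifest.

Stage defaults mirror the analysis constants used throughout the package:
10,000 enrichment bootstraps, 500,000 strictness bootstraps, FDR 0.05,
detection threshold 0.1, allele-frequency cutoff 0.05, and central-gene
thresholds (degree > 5, score > 180) with the relaxed (4, 50) variant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import caf as caf_mod
from . import enrichment as enr_mod
from . import io as io_mod
from . import metrics as met_mod
from . import simulate as sim_mod
from . import strictness as str_mod
from .containers import GeneSet, ValidationError
from .ggm import GGMConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Typed, defaulted configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "strictnet_run"
    # simulation
    n_genes: int = 600
    n_cells_per_stratum: int = 1500
    n_cell_types: int = 4
    n_specific_per_type: int = 25
    specificity_fold: float = 20.0
    network_genes: int = 30
    network_topology: str = "hub"        # chain | hub | cluster
    network_partial_corr: float = 0.3
    broken_fraction: float = 0.8
    network_cells: int = 3000
    n_variants_per_gene: int = 10
    lof_fraction: float = 0.3
    n_decoy_interactions: int = 200
    interaction_universe: int = 2000
    # stage parameters (defaults = the analysis constants)
    enrichment_n_boot: int = 10_000
    strictness_n_boot: int = 500_000
    fdr_threshold: float = 0.05
    detection_threshold: float = 0.1
    af_cutoff: float = 0.05
    central_degree_min: int = 5
    central_score_min: float = 180.0
    relaxed_degree_min: int = 4
    relaxed_score_min: float = 50.0
    ggm_method: str = "mb"
    ggm_criterion: str = "ric"
    min_cells: int = 50
    n_perm: int = 0                       # density permutation test; 0 = skip

    def validate(self) -> None:
        positive = ["n_genes", "n_cells_per_stratum", "n_cell_types",
                    "n_specific_per_type", "network_genes", "network_cells",
                    "enrichment_n_boot", "strictness_n_boot",
                    "n_variants_per_gene", "interaction_universe"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ["fdr_threshold", "detection_threshold", "af_cutoff",
                     "broken_fraction", "lof_fraction"]:
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0,1]")
        if self.specificity_fold < 1:
            raise ValidationError("specificity_fold must be >= 1")
        if self.network_topology not in ("chain", "hub", "cluster"):
            raise ValidationError(f"unknown topology {self.network_topology!r}")


def validate_config(path) -> RunConfig:
    """Load a YAML config, reject unknown keys, fill defaults, range-check."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys: {sorted(unknown)}")
    config = RunConfig(**raw)
    config.validate()
    return config


def dump_config(config: RunConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _planted_network(config: RunConfig) -> sim_mod.PlantedNetwork:
    makers = {"chain": sim_mod.chain_precision, "hub": sim_mod.hub_precision,
              "cluster": sim_mod.cluster_precision}
    planted = makers[config.network_topology](
        config.network_genes, partial_corr=config.network_partial_corr)
    planted.broken_fraction = config.broken_fraction
    planted.break_seed = config.seed
    return planted


def run_all(config: RunConfig) -> dict:
    """Run every stage on synthetic data; returns the manifest dict.

    Outputs land under ``config.outdir``; the manifest records the seed,
    all stage parameters and a sha256 per emitted file, so a fixed seed
    reproduces the manifest bit for bit.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "parameters": dataclasses.asdict(config), "stages": {}}
    files: dict[str, Path] = {}

    # --- simulate ---------------------------------------------------------
    type_names = ["monocyte", "t_helper", "epithelial", "ilc3",
                  "b_cell", "ilc2", "fibroblast", "neuron"][: config.n_cell_types]
    sim_config = sim_mod.SimulationConfig(
        n_genes=config.n_genes,
        cell_type_proportions={t: 1 / len(type_names) for t in type_names},
        n_specific_per_type=config.n_specific_per_type,
        specificity_fold=config.specificity_fold,
        strata=[sim_mod.Stratum(condition="control", age_group="pediatric",
                                n_cells=config.n_cells_per_stratum),
                sim_mod.Stratum(condition="case", age_group="pediatric",
                                n_cells=config.n_cells_per_stratum)],
        seed=config.seed,
    )
    dataset, truth = sim_mod.simulate_celltype_counts(sim_config)
    files["expression"] = io_mod.write_expression(dataset, outdir / "celltype")["matrix"]

    planted = _planted_network(config)
    net_control, net_truth_c = sim_mod.simulate_network_counts(
        config.network_cells, planted, condition="control", seed=config.seed)
    net_case, net_truth_k = sim_mod.simulate_network_counts(
        config.network_cells, planted, condition="case", seed=config.seed + 1)
    truth.true_edges.update(net_truth_c.true_edges)
    truth.true_edges.update(net_truth_k.true_edges)

    target_type = type_names[0]
    targets = GeneSet(name=f"{target_type}_planted",
                      genes=frozenset(truth.specific_genes[target_type]))
    variants = sim_mod.simulate_variants(
        targets, n_variants_per_gene=config.n_variants_per_gene,
        lof_fraction=config.lof_fraction, seed=config.seed)
    files["variants"] = io_mod.write_variant_table(variants, outdir / "variants.tsv")

    interactions = sim_mod.simulate_interactions(
        truth.true_edges["control"], n_decoys=config.n_decoy_interactions,
        universe_size=config.interaction_universe, seed=config.seed)
    files["interactions"] = io_mod.write_interactions(interactions,
                                                      outdir / "interactions.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)
    files["truth"] = outdir / "truth.json"
    manifest["stages"]["simulate"] = {"n_cells": dataset.n_cells,
                                      "n_genes": dataset.n_genes}

    # --- enrichment -------------------------------------------------------
    spec = enr_mod.compute_specificity(dataset, type_field="cell_type")
    results = enr_mod.bootstrap_enrichment(spec, targets,
                                           n_boot=config.enrichment_n_boot,
                                           seed=config.seed)
    frame = enr_mod.enrichment_frame(results)
    frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                 float_format=io_mod.FLOAT_FORMAT)
    files["enrichment"] = outdir / "enrichment.tsv"
    flagged = frame.loc[frame["q"] < config.fdr_threshold, "cell_type"].tolist()
    proportions = enr_mod.compare_proportions(dataset, target_type)
    manifest["stages"]["enrichment"] = {
        "flagged_cell_types": flagged,
        "proportion_test_p": proportions.p,
    }

    # --- strictness -------------------------------------------------------
    mask = dataset.cell_mask(cell_type=target_type)
    table = str_mod.compute_strictness(dataset, mask)
    table.table.to_csv(outdir / "strictness.tsv", sep="\t",
                       float_format=io_mod.FLOAT_FORMAT)
    files["strictness"] = outdir / "strictness.tsv"
    significance = str_mod.strictness_significance(
        table, targets, n_boot=config.strictness_n_boot, seed=config.seed)
    manifest["stages"]["strictness"] = {
        "observed_mean": significance.observed_mean,
        "null_mean": significance.null_mean,
        "null_sd": significance.null_sd,
        "p": significance.p,
    }

    # --- caf --------------------------------------------------------------
    caf_result = caf_mod.cumulative_allele_frequency(variants, targets,
                                                     af_cutoff=config.af_cutoff)
    manifest["stages"]["caf"] = {
        "aggregate_caf": caf_result.aggregate_caf,
        "n_lof_variants": caf_result.n_lof_variants,
    }

    # --- networks ---------------------------------------------------------
    ggm_config = GGMConfig(method=config.ggm_method, criterion=config.ggm_criterion,
                           detection_threshold=config.detection_threshold,
                           min_cells=config.min_cells)
    nets = {}
    for label, net_data in [("control", net_control), ("case", net_case)]:
        net = met_mod._network_from_cells(net_data, ggm_config, config.seed)
        net.stratum["condition"] = label
        nets[label] = net
        files[f"network_{label}"] = io_mod.write_network(
            net, outdir / f"network_{label}.tsv")
        metrics = met_mod.compute_metrics(net)
        metrics.to_frame().to_csv(outdir / f"metrics_{label}.tsv", sep="\t",
                                  index=False, float_format=io_mod.FLOAT_FORMAT)
        files[f"metrics_{label}"] = outdir / f"metrics_{label}.tsv"
        calls = met_mod.call_central_genes(metrics, config.central_degree_min,
                                           config.central_score_min)
        manifest["stages"][f"network_{label}"] = {
            **metrics.summary(),
            "central_genes": [c.gene for c in calls if c.called],
        }

    _, degree_p = met_mod.compare_degrees(nets["case"], nets["control"],
                                          alternative="less")
    overlap = met_mod.overlap_test(
        met_mod.union_edges(nets.values()), interactions)
    manifest["stages"]["compare"] = {
        "degree_ranksum_p": degree_p,
        "overlap": {"n": overlap.n_edges, "k": overlap.k_overlap,
                    "p0": overlap.background_p, "p": overlap.p},
    }

    manifest["files"] = {k: _sha256(Path(v)) for k, v in sorted(files.items())}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", outdir / "manifest.json")
    return manifest
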