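"""End-to-end orchestration: QC -> both DE tracks -> consensus -> composition
-> robustness -> enrichment, for both outcome contrasts with role-swapped
covariates, writing TSV tables and a JSON manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import anndata as ad
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    DEFAULT_CANDIDATE_FACTORS,
    CohortTable,
    build_contrast,
    crosstab_outcomes,
    eligible_confounders,
    load_cohort,
)
from .composition import composition_track, subject_proportions
from .consensus import call_consensus, consensus_matrix
from .enrichment import enrich_calls, read_gmt
from .io import read_dataset
from .mixedmodel import mixed_track
from .pseudobulk import aggregate, test_pseudobulk
from .qc import qc_filter
from .robustness import robustness_scan

log = logging.getLogger("marrowde")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, loadable from YAML."""

    cohort_path: str | None = None  # None -> packaged study table
    dataset_path: str | None = None  # dataset directory (matrix.mtx + sidecars)
    gmt_path: str | None = None
    out_dir: str = "results/pipeline"
    contrasts: tuple[str, ...] = ("cgvhd", "relapse")
    modalities: tuple[str, ...] = ("rna", "protein")
    qc: dict = field(default_factory=lambda: {
        "min_umi": 50, "min_genes": 35, "min_novelty": 0.55})
    nbmm: dict = field(default_factory=lambda: {
        "n_quad": 10, "min_cells": 20, "min_expressing": 3})
    pseudobulk_min_cells: int = 3
    alpha: float = 0.05
    composition_eps: float = 0.5
    min_minority: int = 4
    candidate_factors: tuple[str, ...] | None = None  # None -> auto-detect
    robustness_modalities: tuple[str, ...] = ("rna", "protein")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _write(df: pd.DataFrame, path: Path, manifest: dict, key: str) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"][key] = {"path": path.name, "n_rows": int(len(df))}


def run_pipeline(
    config: PipelineConfig,
    cohort: CohortTable | None = None,
    adata: ad.AnnData | None = None,
) -> Path:
    """Run every stage on the given (or configured) inputs; returns the output dir.

    Deterministic given the inputs and config; the manifest records the
    config hash, package version and per-stage record counts.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest: dict = {
        "package": "marrowde",
        "version": __version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {},
        "outputs": {},
    }

    if cohort is None:
        cohort = load_cohort(config.cohort_path)
    if adata is None:
        if config.dataset_path is None:
            raise ValueError("no dataset: pass adata or set dataset_path")
        adata = read_dataset(config.dataset_path)
    log.info("cohort: %d subjects; dataset: %d cells x %d features",
             len(cohort), adata.n_obs, adata.n_vars)

    contrasts = [build_contrast(cohort, v) for v in config.contrasts]
    manifest["stages"]["cohort"] = {
        "n_subjects": len(cohort),
        "crosstab": crosstab_outcomes(cohort).to_numpy().tolist(),
        "contrasts": {
            c.variable: {"n_positive": c.n_positive, "n_negative": c.n_negative,
                         "covariates": list(c.covariates)}
            for c in contrasts
        },
    }

    filtered, qc_report = qc_filter(adata, **config.qc)
    qc_report.metrics.to_csv(out / "qc_metrics.tsv", sep="\t")
    (out / "qc_summary.json").write_text(json.dumps(qc_report.summary(), indent=2))
    manifest["stages"]["qc"] = qc_report.summary()
    log.info("qc: %d/%d cells survive", filtered.n_obs, adata.n_obs)

    props = subject_proportions(filtered)
    props.to_csv(out / "cell_type_proportions.tsv", sep="\t")
    comp = composition_track(filtered, cohort, contrasts, eps=config.composition_eps)
    _write(comp, out / "composition_results.tsv", manifest, "composition")
    manifest["stages"]["composition"] = {
        "n_tests": int(len(comp)),
        "n_significant": int((comp["q"] < config.alpha).sum()),
    }

    pb = aggregate(filtered, min_cells=config.pseudobulk_min_cells)
    pb.normalized.to_csv(out / "pseudobulk_normalized.tsv", sep="\t")
    manifest["stages"]["pseudobulk"] = {
        "n_units": int(len(pb.units)), "n_excluded_units": int(len(pb.excluded)),
    }

    all_calls, mixed_all = [], []
    for modality in config.modalities:
        mixed = mixed_track(filtered, cohort, contrasts, modality=modality,
                            **config.nbmm)
        pbres = pd.concat(
            [test_pseudobulk(pb, cohort, c, modality=modality) for c in contrasts],
            ignore_index=True,
        )
        calls = call_consensus(mixed, pbres, alpha=config.alpha)
        _write(mixed, out / f"de_mixed_{modality}.tsv", manifest, f"mixed_{modality}")
        _write(pbres, out / f"de_pseudobulk_{modality}.tsv", manifest,
               f"pseudobulk_{modality}")
        _write(calls, out / f"consensus_{modality}.tsv", manifest,
               f"consensus_{modality}")
        for c in contrasts:
            consensus_matrix(calls, c.variable, modality).to_csv(
                out / f"heatmap_{modality}_{c.variable}.tsv", sep="\t")
        manifest["stages"][f"de_{modality}"] = {
            "n_tests": int(mixed["p"].notna().sum()),
            "n_untestable": int(mixed["p"].isna().sum()),
            "n_fdr_pass": int((mixed["q"] < config.alpha).sum()),
            "n_called": int(calls["called"].sum()),
        }
        all_calls.append(calls)
        mixed_all.append(mixed)
        log.info("%s: %d consensus calls", modality, int(calls["called"].sum()))
    calls = pd.concat(all_calls, ignore_index=True)
    mixed = pd.concat(mixed_all, ignore_index=True)

    candidates = config.candidate_factors
    if candidates is None:
        candidates = [
            f for f in DEFAULT_CANDIDATE_FACTORS if f in cohort.data.columns
        ] + [c for c in cohort.data.columns if c.startswith("null_factor")]
    factors = eligible_confounders(
        cohort, candidates, min_minority=config.min_minority
    )
    manifest["stages"]["robustness"] = {"eligible_factors": factors}
    rob_parts = []
    for c in contrasts:
        for modality in config.robustness_modalities:
            base = mixed[(mixed["modality"] == modality)
                         & (mixed["contrast"] == c.variable)]
            corr, scatter = robustness_scan(
                filtered, cohort, c, factors, modality=modality,
                base_results=base, **config.nbmm,
            )
            rob_parts.append(corr)
            for factor, df in scatter.items():
                df.to_csv(
                    out / f"robustness_scatter_{modality}_{c.variable}_{factor}.tsv",
                    sep="\t", index=False)
    if rob_parts:
        rob = pd.concat(rob_parts, ignore_index=True)
        _write(rob, out / "robustness_correlations.tsv", manifest, "robustness")

    if config.gmt_path is not None:
        panel = set(adata.var.index[adata.var["modality"] == "rna"])
        genesets = read_gmt(config.gmt_path, panel)
        enr = enrich_calls(calls, genesets, panel, modality="rna")
        _write(enr, out / "enrichment.tsv", manifest, "enrichment")
        manifest["stages"]["enrichment"] = {
            "n_sets": len(genesets),
            "n_highlighted": int(enr["highlighted"].sum()) if len(enr) else 0,
        }

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
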