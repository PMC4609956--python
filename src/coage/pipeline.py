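"""Stage orchestration: simulate -> aging-genes -> coaging / predict-age / enrich.

Each stage reads the previous stage's files from the output directory, so a
later stage can be rerun alone as long as its upstream outputs exist.  A run
manifest (config echo, seed, stage timings, input digests, output paths,
warnings) is written last.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
import zlib

from . import aging, coaging, enrich, io, predict, simulate
from .containers import AnalysisConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "aging-genes", "coaging", "predict-age", "enrich")


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_timings: Dict[str, float] = field(default_factory=dict)
    input_digests: Dict[str, str] = field(default_factory=dict)
    output_paths: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "stage_timings": self.stage_timings,
            "input_digests": self.input_digests,
            "output_paths": self.output_paths,
            "warnings": self.warnings,
        }


def _stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_cohort_spec(cfg: dict, seed: int) -> simulate.CohortSpec:
    cohort = dict(cfg)
    tissues = [simulate.TissueSpec(**t) for t in cohort.pop("tissues")]
    coaging_corr = cohort.pop("coaging_corr", None)
    if coaging_corr is not None:
        coaging_corr = np.asarray(coaging_corr, dtype=float)
    if "age_range" in cohort:
        cohort["age_range"] = tuple(cohort["age_range"])
    return simulate.CohortSpec(
        tissues=tissues, coaging_corr=coaging_corr, seed=seed, **cohort
    )


def run_pipeline(
    config_path: str | dict,
    stages: Sequence[str] = STAGES,
    outdir: Optional[str] = None,
    seed: Optional[int] = None,
) -> RunManifest:
    """Run the requested stages in dependency order and write a manifest."""
    if isinstance(config_path, dict):
        cfg = dict(config_path)
    else:
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid stages: {STAGES}")
    stages = [s for s in STAGES if s in stages]

    global_seed = int(seed if seed is not None else cfg.get("seed", 0))
    out = Path(outdir or cfg.get("outdir", "coage_output"))
    out.mkdir(parents=True, exist_ok=True)
    analysis_cfg = AnalysisConfig.from_dict({**cfg.get("analysis", {}), "seed": global_seed})
    manifest = RunManifest(config=cfg, seed=global_seed)

    for stage in stages:
        t0 = time.perf_counter()
        logger.info("stage %s starting", stage)
        if stage == "simulate":
            _stage_simulate(cfg, out, _stage_seed(global_seed, stage), manifest)
        elif stage == "aging-genes":
            _stage_aging(cfg, out, analysis_cfg, manifest)
        elif stage == "coaging":
            _stage_coaging(cfg, out, analysis_cfg, manifest)
        elif stage == "predict-age":
            _stage_predict(cfg, out, analysis_cfg, _stage_seed(global_seed, stage), manifest)
        elif stage == "enrich":
            _stage_enrich(cfg, out, analysis_cfg, manifest)
        manifest.stage_timings[stage] = round(time.perf_counter() - t0, 4)

    io.write_run_summary(str(out / "run_summary.json"), analysis_cfg)
    manifest.output_paths.append(str(out / "run_summary.json"))
    manifest_path = out / "run_manifest.json"
    manifest.output_paths.append(str(manifest_path))
    with open(manifest_path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True, default=str)
    for p in manifest.output_paths:
        if not Path(p).exists():
            raise RuntimeError(f"manifest lists missing output: {p}")
    return manifest


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {needed_by!r} requires {path.name}, produced by stage {stage!r}; "
            f"run that stage first or provide the file"
        )
    return path


def _load_inputs(cfg: dict, out: Path, needed_by: str):
    expr_path = cfg.get("expression_path") or str(_require(out / "expression.tsv", "simulate", needed_by))
    meta_path = cfg.get("metadata_path") or str(_require(out / "metadata.tsv", "simulate", needed_by))
    return io.load_dataset(expr_path, meta_path)


def _stage_simulate(cfg: dict, out: Path, seed: int, manifest: RunManifest) -> None:
    if "cohort" not in cfg:
        raise ValueError("config missing 'cohort' section for simulate stage")
    spec = _build_cohort_spec(cfg["cohort"], seed)
    mats, donors, smap, truth = simulate.generate_cohort(spec)
    ecfg = cfg.get("enrichment", {})
    gene_ids = next(iter(mats.values())).gene_ids
    sets = simulate.generate_reference_and_disease_sets(
        truth,
        n_sets=int(ecfg.get("n_sets", 10)),
        planted_enrichment=float(ecfg.get("planted_enrichment", 5.0)),
        seed=seed + 1,
        universe=gene_ids,
    )
    combined = pd.concat([m.data for m in mats.values()], axis=1)
    from .containers import ExpressionMatrix

    io.write_expression_tsv(ExpressionMatrix("all", combined), str(out / "expression.tsv"))
    io.write_metadata(donors, smap, str(out / "metadata.tsv"))
    io.write_gene_sets(sets, str(out / "disease_sets.gmt"))
    with open(out / "truth.json", "w") as fh:
        json.dump(simulate.truth_to_json_dict(truth), fh, indent=2, sort_keys=True)
    for name in ("expression.tsv", "metadata.tsv", "disease_sets.gmt", "truth.json"):
        manifest.output_paths.append(str(out / name))
        manifest.input_digests[name] = _digest(out / name)


def _stage_aging(cfg: dict, out: Path, acfg: AnalysisConfig, manifest: RunManifest) -> None:
    mats, donors, smap, = _load_inputs(cfg, out, "aging-genes")
    use_bootstrap = bool(cfg.get("bootstrap", False))
    for tissue, expr in mats.items():
        if use_bootstrap:
            gene_set, results = aging.bootstrap_consensus(expr, donors, smap, acfg)
        else:
            gene_set, results = aging.call_aging_genes(expr, donors, smap, acfg)
            results = results.copy()
            results["bootstrap_support"] = np.nan
        path = out / f"aging_genes_{tissue}.tsv"
        results.to_csv(path, sep="\t", float_format="%.17g")
        manifest.output_paths.append(str(path))
        logger.info("tissue %s: %d aging genes", tissue, len(gene_set))


def _read_signature(out: Path, tissue: str, needed_by: str) -> pd.DataFrame:
    path = _require(out / f"aging_genes_{tissue}.tsv", "aging-genes", needed_by)
    return pd.read_csv(path, sep="\t", index_col=0)


def _apparent_tables(cfg: dict, out: Path, needed_by: str):
    mats, donors, smap = _load_inputs(cfg, out, needed_by)
    tables = {}
    for tissue, expr in mats.items():
        res = _read_signature(out, tissue, needed_by)
        genes = res.index[res["in_final_set"].astype(bool)].tolist()
        if len(genes) < 2:
            logger.warning("tissue %s: <2 aging genes, skipped in co-aging", tissue)
            continue
        from .containers import aligned_covariates

        ages, _, _, _ = aligned_covariates(expr, donors, smap)
        tables[tissue] = coaging.apparent_age_pc1(expr.subset_genes(genes), ages)
    return mats, donors, smap, tables


def _stage_coaging(cfg: dict, out: Path, acfg: AnalysisConfig, manifest: RunManifest) -> None:
    mats, donors, smap, tables = _apparent_tables(cfg, out, "coaging")
    rows = []
    for tissue, tab in tables.items():
        for s, c, r in zip(tab.sample_ids, tab.pc1_coordinate, tab.rank):
            rows.append(
                {
                    "tissue": tissue,
                    "sample_id": s,
                    "donor_id": smap.data.at[s, "donor_id"],
                    "pc1": c,
                    "rank": r,
                    "age": donors.data.at[smap.data.at[s, "donor_id"], "age"],
                }
            )
    pd.DataFrame(rows).to_csv(out / "apparent_age.tsv", sep="\t", index=False, float_format="%.17g")
    manifest.output_paths.append(str(out / "apparent_age.tsv"))
    if len(tables) >= 2:
        cm = coaging.coaging_matrix(tables, smap)
        cm.coefficients.to_csv(out / "coaging_matrix.tsv", sep="\t", float_format="%.17g")
        manifest.output_paths.append(str(out / "coaging_matrix.tsv"))
        try:
            devs = coaging.rank_deviation(tables, donors, smap, acfg.outlier_alpha)
        except ValueError as exc:
            manifest.warnings.append(f"rank deviation skipped: {exc}")
        else:
            recs = [
                {
                    "donor_id": r.donor_id,
                    **{f"rank_{t}": rv for t, rv in zip(tables, r.rank_vector)},
                    "chrono_rank": r.chrono_rank,
                    "d": r.d,
                    "p_value": r.p_value,
                    "outlier": r.is_outlier,
                }
                for r in devs
            ]
            pd.DataFrame(recs).to_csv(
                out / "rank_deviation.tsv", sep="\t", index=False, float_format="%.17g"
            )
            manifest.output_paths.append(str(out / "rank_deviation.tsv"))


def _stage_predict(
    cfg: dict, out: Path, acfg: AnalysisConfig, seed: int, manifest: RunManifest
) -> None:
    mats, donors, smap = _load_inputs(cfg, out, "predict-age")
    pcfg = cfg.get("prediction", {})
    folds = int(pcfg.get("folds", acfg.en_folds))
    repeats = int(pcfg.get("repeats", acfg.en_repeats))
    features = pcfg.get("features", "all")
    results = {}
    rows = []
    from .containers import aligned_covariates

    for tissue, expr in mats.items():
        if features == "aging":
            res = _read_signature(out, tissue, "predict-age")
            genes = res.index[res["in_final_set"].astype(bool)].tolist()
            if len(genes) < 2:
                logger.warning("tissue %s: <2 aging genes, prediction skipped", tissue)
                continue
            expr = expr.subset_genes(genes)
        ages, _, _, donor_ids = aligned_covariates(expr, donors, smap)
        pres = predict.repeated_cv_predict(expr, ages, folds=folds, repeats=repeats, seed=seed)
        results[tissue] = pres
        for s, d, a, pa in zip(pres.sample_ids, donor_ids, ages, pres.predicted_age):
            rows.append(
                {
                    "tissue": tissue,
                    "sample_id": s,
                    "donor_id": d,
                    "age": a,
                    "predicted_age": pa,
                    "n_repeats": repeats,
                }
            )
    pd.DataFrame(rows).to_csv(out / "predicted_age.tsv", sep="\t", index=False, float_format="%.17g")
    manifest.output_paths.append(str(out / "predicted_age.tsv"))
    if len(results) >= 2:
        cm = predict.predicted_age_coaging(results, smap)
        cm.coefficients.to_csv(out / "en_coaging_matrix.tsv", sep="\t", float_format="%.17g")
        manifest.output_paths.append(str(out / "en_coaging_matrix.tsv"))


def _stage_enrich(cfg: dict, out: Path, acfg: AnalysisConfig, manifest: RunManifest) -> None:
    mats, donors, smap = _load_inputs(cfg, out, "enrich")
    ecfg = cfg.get("enrichment", {})
    sets_path = ecfg.get("sets_path") or str(
        _require(out / "disease_sets.gmt", "simulate", "enrich")
    )
    sets = io.read_gene_sets(sets_path, min_size=acfg.min_set_size)
    signatures = {}
    universe = {}
    for tissue, expr in mats.items():
        res = _read_signature(out, tissue, "enrich")
        # disease scan uses the stricter signature FDR
        sig = res[(res["fdr"] <= acfg.disease_fdr) & res["passed_low_expression_filter"].astype(bool)]
        up = sig.index[sig["direction"] == "up"].tolist()
        down = sig.index[sig["direction"] == "down"].tolist()
        signatures[tissue] = aging.AgingGeneSet(tissue, up, down)
        universe[tissue] = res.index.tolist()
    table = enrich.disease_enrichment_scan(
        signatures, sets, universe, top_k=int(ecfg.get("top_k", 10))
    )
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.17g")
    manifest.output_paths.append(str(out / "enrichment.tsv"))
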