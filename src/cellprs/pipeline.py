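"""Stage orchestration: simulate → gene sets → partition → score →
associate → mediate → SEM, driven by one structured config.

Each stage reads its inputs from the output directory, writes its results
as TSV/BED/JSON, and appends a manifest entry (counts at every filter,
seed, parameter values) so any table can be reproduced. Rerunning a stage
with the same config and seed produces byte-identical outputs: every
source of randomness derives from the single config seed, keyed by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .association import association_scan, bh_fdr
from .intervals import build_intervals, assign_variants
from .mediation import fit_mediation, fit_mediation_with_upstream
from .scoring import reconcile_alleles, score_partitions
from .sem import PathModel, fit_path_model, residualize
from .simulate import SimulationConfig, simulate_study
from .specificity import APOE_REGION, build_gene_sets

logger = logging.getLogger(__name__)

STAGES = ("simulate", "genesets", "partition", "score", "associate",
          "mediate", "sem")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "results",
    "margin_bp": 30_000,
    "decile_fraction": 0.10,
    "min_expressed_fraction": 0.01,
    "excluded_region": list(APOE_REGION),
    "fdr_level": 0.025,
    "interaction_alpha": 0.017,
    "B_delta_r2": 1000,
    "B_mediation": 10_000,
    "B_sem": 10_000,
    "simulation": {},          # overrides for SimulationConfig fields
    "model_specs": {
        "Abeta":   {"family": "linear", "covariates": ["e4", "e2", "age", "sex", "batch", "PC1", "PC2", "PC3"]},
        "DP":      {"family": "linear", "covariates": ["e4", "e2", "age", "sex", "batch", "PC1", "PC2", "PC3"]},
        "NP":      {"family": "linear", "covariates": ["e4", "e2", "age", "sex", "batch", "PC1", "PC2", "PC3"]},
        "PHFtau":  {"family": "linear", "covariates": ["e4", "e2", "age", "sex", "batch", "PC1", "PC2", "PC3"]},
        "NFT":     {"family": "linear", "covariates": ["e4", "e2", "age", "sex", "batch", "PC1", "PC2", "PC3"]},
        "CogDec":  {"family": "linear", "covariates": ["e4", "e2", "batch", "PC1", "PC2", "PC3"]},
        "dementia": {"family": "logistic", "covariates": ["e4", "e2", "age", "sex", "education", "batch", "PC1", "PC2", "PC3"]},
    },
    "mediation_triplets": [
        {"treatment": "Ast", "mediator": "DP", "outcome": "NP"},
        {"treatment": "Ast", "mediator": "NP", "outcome": "NFT"},
        {"treatment": "Mic", "mediator": "NP", "outcome": "PHFtau"},
        {"treatment": "Mic", "mediator": "NFT", "outcome": "CogDec",
         "upstream": "NP"},
    ],
    "mediation_covariates": ["age", "sex", "e4", "e2", "batch", "PC1", "PC2", "PC3"],
    "sem_model": None,          # text block; None = default graph
    "sem_covariates": ["e4", "e2", "age", "sex", "batch", "PC1", "PC2", "PC3"],
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    cfg.update(overrides)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if cfg["margin_bp"] < 0:
        raise ValueError("config field margin_bp: must be >= 0")
    if not 0 < cfg["decile_fraction"] <= 1:
        raise ValueError("config field decile_fraction: must be in (0, 1]")
    if not 0 < cfg["fdr_level"] < 1:
        raise ValueError("config field fdr_level: must be in (0, 1)")
    for key in ("B_delta_r2", "B_mediation", "B_sem"):
        if cfg[key] < 100:
            raise ValueError(f"config field {key}: must be >= 100")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, info: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    info = dict(info)
    info["elapsed_s"] = round(info.get("elapsed_s", 0.0), 3)
    files = info.get("files", [])
    info["hashes"] = {f: _sha256(outdir / f) for f in files if (outdir / f).exists()}
    manifest[stage] = info
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _sim_config(cfg: dict) -> SimulationConfig:
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    overrides = dict(cfg.get("simulation") or {})
    unknown = set(overrides) - fields
    if unknown:
        raise ValueError(f"config field simulation: unknown key(s) {sorted(unknown)}")
    if "maf_range" in overrides:
        overrides["maf_range"] = tuple(overrides["maf_range"])
    overrides.setdefault("seed", cfg["seed"])
    return SimulationConfig(**overrides)


def run_stage(stage: str, cfg: dict) -> Path:
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    fn = {
        "simulate": _stage_simulate,
        "genesets": _stage_genesets,
        "partition": _stage_partition,
        "score": _stage_score,
        "associate": _stage_associate,
        "mediate": _stage_mediate,
        "sem": _stage_sem,
    }.get(stage)
    if fn is None:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    info = fn(cfg, outdir)
    info["elapsed_s"] = time.time() - t0
    info["seed"] = cfg["seed"]
    _write_manifest(outdir, stage, info)
    return outdir


def run_all(cfg: dict) -> Path:
    for stage in STAGES:
        run_stage(stage, cfg)
    return Path(cfg["outdir"])


# ------------------------------------------------------------------ stages

def _stage_simulate(cfg: dict, outdir: Path) -> dict:
    sim = _sim_config(cfg)
    study = simulate_study(sim, margin_bp=cfg["margin_bp"],
                           fraction=cfg["decile_fraction"])
    cio.write_expression_mtx(study.expression, outdir / "expression")
    cio.write_annotation_bed(study.annotation, outdir / "annotation.bed")
    cio.write_weights(study.weights, outdir / "weights.tsv")
    cio.write_genotypes(study.genotypes, outdir / "genotypes")
    cio.write_table(study.phenotypes.rename_axis("IID"), outdir / "phenotypes.tsv", index=True)
    cio.write_json(
        {
            "marker_genes": study.truth.marker_genes,
            "true_path_coefficients": study.truth.true_path_coefficients,
        },
        outdir / "ground_truth.json",
    )
    return {
        "n_cells": int(study.expression.counts.shape[0]),
        "n_genes": int(study.expression.counts.shape[1]),
        "n_individuals": len(study.genotypes.individual_ids),
        "n_variants": len(study.genotypes.variant_meta),
        "files": ["expression.mtx", "annotation.bed", "weights.tsv",
                  "genotypes.dosage.tsv", "phenotypes.tsv", "ground_truth.json"],
    }


def _stage_genesets(cfg: dict, outdir: Path) -> dict:
    expr = cio.read_expression_mtx(outdir / "expression")
    ann = cio.read_annotation_bed(outdir / "annotation.bed")
    region = tuple(cfg["excluded_region"])
    sets, spec = build_gene_sets(
        expr, ann,
        min_fraction=cfg["min_expressed_fraction"],
        fraction=cfg["decile_fraction"],
        region=region,
    )
    spec.Sg.rename_axis("gene_id").to_csv(outdir / "specificity.tsv", sep="\t")
    files = ["specificity.tsv"]
    for ct, df in sets.sets.items():
        track = ann.subset(df["gene_id"])
        cio.write_annotation_bed(track, outdir / f"geneset_{ct}.bed")
        files.append(f"geneset_{ct}.bed")
    logger.info("retained %d genes; per-type set size %d",
                sets.n_retained, len(next(iter(sets.sets.values()))))
    return {
        "n_retained_genes": sets.n_retained,
        "set_size": len(next(iter(sets.sets.values()))),
        "files": files,
    }


def _stage_partition(cfg: dict, outdir: Path) -> dict:
    ann = cio.read_annotation_bed(outdir / "annotation.bed")
    geno = cio.read_genotypes(outdir / "genotypes")
    sets = {
        p.stem.removeprefix("geneset_"): cio.read_annotation_bed(p)
        for p in sorted(outdir.glob("geneset_*.bed"))
    }
    interval_sets = {
        ct: build_intervals(track, cfg["margin_bp"], source=ct)
        for ct, track in sets.items()
    }
    membership = assign_variants(
        geno.variant_meta, interval_sets, apoe_region=tuple(cfg["excluded_region"])
    )
    files = []
    for ct, iset in interval_sets.items():
        cio.write_intervals_bed(iset, outdir / f"intervals_{ct}.bed")
        files.append(f"intervals_{ct}.bed")
        members = membership.table[membership.table[ct]]
        members[["CHR", "BP"]].rename_axis("SNP").to_csv(
            outdir / f"variants_{ct}.tsv", sep="\t"
        )
        files.append(f"variants_{ct}.tsv")
    membership.table.to_csv(outdir / "membership.tsv", sep="\t")
    files.append("membership.tsv")
    counts = membership.counts()
    logger.info("per-partition variant counts: %s", counts)
    return {"variant_counts": counts, "margin_bp": cfg["margin_bp"], "files": files}


def _stage_score(cfg: dict, outdir: Path) -> dict:
    geno = cio.read_genotypes(outdir / "genotypes")
    weights = cio.read_weights(outdir / "weights.tsv")
    membership_df = pd.read_csv(outdir / "membership.tsv", sep="\t", index_col="SNP")
    from .intervals import VariantMembership

    membership = VariantMembership(table=membership_df, margin_bp=cfg["margin_bp"])
    aligned = reconcile_alleles(
        weights, geno.variant_meta[["SNP", "counted_allele", "other_allele"]]
    )
    scores = score_partitions(geno, aligned, membership, strict=False)
    cio.write_scores(scores, outdir / "scores")
    from .scoring import score_correlation

    corr = score_correlation(scores.standardized)
    corr.to_csv(outdir / "score_correlation.tsv", sep="\t")
    return {
        "partitions": list(scores.standardized.columns),
        "variant_counts": dict(scores.variant_counts),
        "n_dropped_palindromic": aligned.n_dropped_palindromic,
        "n_dropped_mismatch": aligned.n_dropped_mismatch,
        "files": ["scores.raw.tsv", "scores.std.tsv", "score_correlation.tsv"],
    }


def _load_scores_phenotypes(outdir: Path):
    scores = pd.read_csv(outdir / "scores.std.tsv", sep="\t", index_col="IID")
    pheno = pd.read_csv(outdir / "phenotypes.tsv", sep="\t", index_col="IID")
    return scores.loc[pheno.index], pheno


def _stage_associate(cfg: dict, outdir: Path) -> dict:
    scores, pheno = _load_scores_phenotypes(outdir)
    results = association_scan(pheno, scores, cfg["model_specs"])
    fdr = bh_fdr(results["p"], level=cfg["fdr_level"])
    results["q"] = fdr["q"].to_numpy()
    results["significant"] = fdr["significant"].to_numpy()
    cio.write_table(results, outdir / "associations.tsv")
    return {
        "n_analyses": len(results),
        "n_significant": int(results["significant"].sum()),
        "fdr_level": cfg["fdr_level"],
        "files": ["associations.tsv"],
    }


def _stage_mediate(cfg: dict, outdir: Path) -> dict:
    scores, pheno = _load_scores_phenotypes(outdir)
    covs = pheno[cfg["mediation_covariates"]].to_numpy(float)
    rows = []
    for i, trip in enumerate(cfg["mediation_triplets"]):
        T = scores[trip["treatment"]].to_numpy(float)
        M = pheno[trip["mediator"]].to_numpy(float)
        Y = pheno[trip["outcome"]].to_numpy(float)
        seed = int(cfg["seed"]) * 100 + i
        if trip.get("upstream"):
            res = fit_mediation_with_upstream(
                T, M, Y, pheno[trip["upstream"]].to_numpy(float), covs,
                B=cfg["B_mediation"], seed=seed,
            )
        else:
            res = fit_mediation(T, M, Y, covs, B=cfg["B_mediation"], seed=seed)
        rows.append({
            "treatment": trip["treatment"], "mediator": trip["mediator"],
            "outcome": trip["outcome"], "upstream": trip.get("upstream", ""),
            "acme": res.acme.point, "acme_lo": res.acme.ci[0], "acme_hi": res.acme.ci[1],
            "acme_p": res.acme.p,
            "ade": res.ade.point, "ade_p": res.ade.p,
            "total": res.total.point, "total_p": res.total.p,
            "prop_mediated": res.prop_mediated.point,
            "n": res.n, "B": res.B,
        })
    df = pd.DataFrame(rows)
    cio.write_table(df, outdir / "mediation.tsv")
    cio.write_json({"B": cfg["B_mediation"], "seed": cfg["seed"]},
                   outdir / "mediation_meta.json")
    return {"n_triplets": len(rows),
            "files": ["mediation.tsv", "mediation_meta.json"]}


def _stage_sem(cfg: dict, outdir: Path) -> dict:
    scores, pheno = _load_scores_phenotypes(outdir)
    model = (PathModel.from_text(cfg["sem_model"]) if cfg.get("sem_model")
             else PathModel.default())
    data = pd.DataFrame({
        "AstScore": scores["Ast"], "MicScore": scores["Mic"],
        "DP": pheno["DP"], "NP": pheno["NP"], "NFT": pheno["NFT"],
        "CogDec": pheno["CogDec"],
    })
    resid = residualize(data, pheno[cfg["sem_covariates"]])
    fit = fit_path_model(model, resid, B=cfg["B_sem"], seed=int(cfg["seed"]) + 7)
    cio.write_table(fit.edges, outdir / "sem_edges.tsv")
    cio.write_json(
        {
            "chi2": fit.chi2, "df": fit.df, "cfi": fit.cfi, "tli": fit.tli,
            "rmsea": fit.rmsea, "srmr": fit.srmr, "n": fit.n, "B": fit.B,
        },
        outdir / "sem_fit.json",
    )
    return {"n": fit.n, "df": fit.df,
            "files": ["sem_edges.tsv", "sem_fit.json"]}
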