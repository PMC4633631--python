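"""End-to-end orchestration: simulate -> QC -> structure -> association ->
GRM -> REML -> bivariate -> GPS -> prediction, from a single config.

A run operates on one simulated pair study (two disease cohorts sharing a
pooled control set, the design the bivariate estimator assumes); every
stage writes its outputs and an audit log under the configured output
directory, and all randomness derives deterministically from one root
seed, so reruns are byte-identical.
"""
from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import bivar as bivar_mod
from . import gps as gps_mod
from . import predict as predict_mod
from . import qc as qc_mod
from . import reml as reml_mod
from . import structure as structure_mod
from .datatypes import GenotypeData
from .errors import ConfigError
from .grm import RegionSpec, build_grm, build_grm_x, partition_snps, prune_related
from .plink_io import write_plink
from .synthdata import SimParams, StudyData, simulate_pair_study

log = logging.getLogger(__name__)


@dataclass
class DiseaseSpec:
    name: str
    prevalence: float
    h2: float
    n_cases: int


@dataclass
class RunConfig:
    seed: int = 1
    output_dir: str = "coherit_out"
    diseases: list = field(default_factory=list)
    n_controls: int = 2000
    rg_true: float = 0.0
    n_snps: int = 2000
    n_causal: int = 200
    maf_range: tuple = (0.05, 0.5)
    mhc_n_snps: int = 0
    mhc_variance_share: float = 0.0
    n_snps_x: int = 0
    qc: qc_mod.QcThresholds = field(default_factory=qc_mod.QcThresholds)
    region: RegionSpec = field(default_factory=RegionSpec)
    n_pcs_assoc: int = 10
    n_pcs_reml: int = 20
    relatedness_threshold: float = 0.05
    bonferroni_relaxed: int = 9
    bonferroni_strict: int = 45
    predict: predict_mod.PredictionConfig = field(
        default_factory=predict_mod.PredictionConfig)

    def validate(self) -> None:
        if not self.diseases:
            raise ConfigError("no diseases configured")
        for d in self.diseases:
            if d.prevalence is None or not (0 < d.prevalence < 1):
                raise ConfigError(
                    f"disease {d.name!r} needs a prevalence in (0, 1)")


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration; raises ConfigError on problems."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        diseases = [DiseaseSpec(name=d["name"], prevalence=d.get("prevalence"),
                                h2=d.get("h2", 0.5), n_cases=d.get("n_cases", 500))
                    for d in raw.pop("diseases", [])]
        qc_t = qc_mod.QcThresholds(**raw.pop("qc", {}))
        # YAML 1.1 reads bare scientific notation like 1e-5 as a string
        pred = predict_mod.PredictionConfig(**{
            k: (tuple(float(x) for x in v) if k == "thresholds" else v)
            for k, v in raw.pop("predict", {}).items()})
        cfg = RunConfig(diseases=diseases, qc=qc_t, predict=pred, **{
            k: (tuple(float(x) for x in v) if k == "maf_range" else v)
            for k, v in raw.items()})
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    cfg.validate()
    return cfg


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(f"{root_seed}:{stage}".encode()) & 0x7FFFFFFF)


def _sim_params(cfg: RunConfig) -> SimParams:
    d1, d2 = cfg.diseases[0], cfg.diseases[1]
    mhc_block = (0, cfg.mhc_n_snps)
    return SimParams(
        n_individuals=1, n_snps=cfg.n_snps, maf_range=cfg.maf_range,
        n_causal=cfg.n_causal, h2_trait1=d1.h2, h2_trait2=d2.h2,
        rg_true=cfg.rg_true, prevalence1=d1.prevalence, prevalence2=d2.prevalence,
        mhc_block=mhc_block, mhc_variance_share=cfg.mhc_variance_share,
        n_snps_x=cfg.n_snps_x, seed=derive_seed(cfg.seed, "simulate"))


def simulate_stage(cfg: RunConfig, outdir: Path) -> StudyData:
    cfg.validate()
    if len(cfg.diseases) < 2:
        raise ConfigError("the pair pipeline needs two configured diseases")
    outdir.mkdir(parents=True, exist_ok=True)
    d1, d2 = cfg.diseases[0], cfg.diseases[1]
    study = simulate_pair_study(_sim_params(cfg), d1.n_cases, d2.n_cases,
                                cfg.n_controls)
    write_plink(study.geno, outdir / "simulated")
    pd.DataFrame({"iid": study.geno.sample_ids, "role": study.roles,
                  "y1": study.y1, "y2": study.y2}).to_csv(
        outdir / "roles.tsv", sep="\t", index=False)
    log.info("simulated %d samples x %d SNPs (population %d)",
             study.geno.n_samples, study.geno.n_snps, study.population_size)
    return study


def qc_stage(cfg: RunConfig, study: StudyData, outdir: Path):
    any_case = study.roles != "control"
    samp_report, geno = qc_mod.filter_samples(study.geno, cfg.qc)
    keep_rows = np.isin(study.geno.sample_ids, samp_report.retained_ids)
    snp_report, geno = qc_mod.filter_snps(geno, any_case[keep_rows], cfg.qc)
    snp_report.to_tsv(outdir / "qc_snps.tsv")
    samp_report.to_tsv(outdir / "qc_samples.tsv")
    return geno, keep_rows, snp_report, samp_report


def structure_stage(cfg: RunConfig, geno: GenotypeData, outdir: Path):
    """PCA with ancestry-outlier and relatedness removal; returns the
    analysis-ready cohort plus its PC scores."""
    pruned = structure_mod.ld_prune(geno)
    k = max(cfg.n_pcs_reml, cfg.n_pcs_assoc)
    pca = structure_mod.compute_pca(geno, pruned, k=min(k, geno.n_samples - 2))
    outliers = structure_mod.remove_pca_outliers(pca)
    keep = ~np.isin(geno.sample_ids, outliers)
    geno = geno.subset(samples=keep)
    masks = partition_snps(geno.snp_map, cfg.region)
    grm_auto = build_grm(geno, masks["auto"], region="auto")
    retained = prune_related(grm_auto, cfg.relatedness_threshold)
    keep2 = np.isin(geno.sample_ids, retained)
    geno = geno.subset(samples=keep2)
    pca = structure_mod.compute_pca(
        geno, np.intersect1d(pruned, geno.snp_ids),
        k=min(k, geno.n_samples - 2))
    pca.to_frame().to_csv(outdir / "pcs.tsv", sep="\t", index=False)
    log.info("structure stage: %d ancestry outliers, %d related removed",
             int(len(outliers)), int((~keep2).sum()))
    return geno, pca


def _disease_masks(study: StudyData, geno: GenotypeData):
    """Row masks of the current cohort for each disease and the controls."""
    pos = pd.Index(study.geno.sample_ids).get_indexer(geno.sample_ids)
    roles = study.roles[pos]
    return roles


def run_univariate(cfg: RunConfig, study: StudyData | None = None) -> pd.DataFrame:
    """QC -> structure -> GRM -> REML -> liability transform, per disease."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if study is None:
        study = simulate_stage(cfg, outdir)
    geno, _, _, _ = qc_stage(cfg, study, outdir)
    geno, pca = structure_stage(cfg, geno, outdir)
    roles = _disease_masks(study, geno)
    masks = partition_snps(geno.snp_map, cfg.region)
    rows = []
    for i, disease in enumerate(cfg.diseases[:2]):
        case_mask = roles == f"case{i + 1}"
        cohort = case_mask | (roles == "control")
        sub = geno.subset(samples=cohort)
        y = case_mask[cohort].astype(float)
        pcs = pca.scores[cohort]
        lam = assoc_mod.gwas_logistic(
            sub, y, pcs[:, :cfg.n_pcs_assoc]).lambda_gc
        row = {"disease": disease.name, "lambda_gc": lam}
        fits = {}
        for region_name in ("auto", "auto_exMHC"):
            mask = masks[region_name]
            if not mask.any():
                continue
            grm = build_grm(sub, mask, region=region_name)
            fit = reml_mod.reml_fit(y, grm, pcs[:, :cfg.n_pcs_reml])
            K = disease.prevalence
            P = float(y.mean())
            liab = reml_mod.observed_to_liability(
                fit.h2_obs, reml_mod.LiabilityScaleParams(K=K, P=P),
                se=fit.h2_obs_se)
            fits[region_name] = (fit, liab)
        if "auto" in fits:
            fit, liab = fits["auto"]
            row.update(h2_auto=liab.h2, se_auto=liab.se, p_auto=fit.lrt_p)
        if "auto_exMHC" in fits:
            fit, liab = fits["auto_exMHC"]
            row.update(h2_exMHC=liab.h2, se_exMHC=liab.se, p_exMHC=fit.lrt_p)
        if "auto" in fits and "auto_exMHC" in fits:
            row["pct_mhc"] = reml_mod.partition_report(
                fits["auto"][1].h2, fits["auto_exMHC"][1].h2)["pct_mhc"]
        if masks["X"].any():
            try:
                grm_x = build_grm_x(sub.subset(snps=masks["X"]))
                fit_x = reml_mod.reml_fit(y, grm_x, pcs[:, :cfg.n_pcs_reml])
                liab_x = reml_mod.observed_to_liability(
                    fit_x.h2_obs,
                    reml_mod.LiabilityScaleParams(K=disease.prevalence,
                                                  P=float(y.mean())),
                    se=fit_x.h2_obs_se)
                row.update(h2_X=liab_x.h2, se_X=liab_x.se, p_X=fit_x.lrt_p)
            except Exception as exc:  # noqa: BLE001 - ChrX fit is best-effort
                log.warning("ChrX REML unavailable for %s: %s", disease.name, exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "univariate.tsv", sep="\t", index=False,
                 float_format="%.6g")
    return table


def run_pairwise(cfg: RunConfig, study: StudyData | None = None) -> dict:
    """Control split -> bivariate REML (auto and exMHC) -> GPS -> SVM."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(cfg.diseases) < 2:
        log.info("single disease configured; pairwise stage skipped")
        return {"skipped": "single disease"}
    if study is None:
        study = simulate_stage(cfg, outdir)
    geno, _, _, _ = qc_stage(cfg, study, outdir)
    geno, pca = structure_stage(cfg, geno, outdir)
    roles = _disease_masks(study, geno)
    masks = partition_snps(geno.snp_map, cfg.region)
    d1, d2 = cfg.diseases[0], cfg.diseases[1]

    control_ids = geno.sample_ids[roles == "control"]
    design = bivar_mod.split_controls(control_ids,
                                      derive_seed(cfg.seed, "split_controls"))
    side1 = (roles == "case1") | np.isin(geno.sample_ids, design.controls_side1)
    side2 = (roles == "case2") | np.isin(geno.sample_ids, design.controls_side2)
    pair_rows = side1 | side2
    sub = geno.subset(samples=pair_rows)
    y1 = np.where(side1[pair_rows], (roles[pair_rows] == "case1").astype(float),
                  np.nan)
    y2 = np.where(side2[pair_rows], (roles[pair_rows] == "case2").astype(float),
                  np.nan)
    pcs = pca.scores[pair_rows][:, :cfg.n_pcs_reml]
    results = {}
    bivar_rows = {}
    for region_name in ("auto", "auto_exMHC"):
        grm = build_grm(sub, masks[region_name], region=region_name)
        fit = bivar_mod.bivar_reml(y1, y2, grm, pcs)
        bivar_rows[region_name] = fit
    p_nom = bivar_rows["auto_exMHC"].lrt_p
    pair_table = pd.DataFrame([{
        "pair": f"{d1.name}-{d2.name}",
        "rG_auto": bivar_rows["auto"].rg, "se_auto": bivar_rows["auto"].rg_se,
        "p_auto": bivar_rows["auto"].lrt_p,
        "rG_exMHC": bivar_rows["auto_exMHC"].rg,
        "se_exMHC": bivar_rows["auto_exMHC"].rg_se,
        "p_nominal": p_nom,
        "p_adj": bivar_mod.bonferroni_adjust(p_nom, cfg.bonferroni_relaxed),
        "p_strict": bivar_mod.bonferroni_adjust(p_nom, cfg.bonferroni_strict),
    }])
    pair_table.to_csv(outdir / "pairwise.tsv", sep="\t", index=False,
                      float_format="%.6g")
    results["pairwise"] = pair_table

    # GPS on per-disease association scans (cases vs their control half)
    tables = {}
    for name, side, case_label in ((d1.name, side1, "case1"),
                                   (d2.name, side2, "case2")):
        cohort = geno.subset(samples=side)
        yy = (roles[side] == case_label).astype(float)
        res = assoc_mod.gwas_logistic(cohort, yy,
                                      pca.scores[side][:, :cfg.n_pcs_assoc])
        tables[name] = res.pvalues().dropna()
    common = tables[d1.name].index.intersection(tables[d2.name].index)
    tables = {k: v.loc[common] for k, v in tables.items()}
    gps_table = gps_mod.gps_all_pairs(tables, snp_map=geno.snp_map,
                                      exclude_mhc=bool(masks["MHC"].any()),
                                      region=cfg.region)
    gps_table.to_csv(outdir / "gps.tsv", sep="\t", index=False,
                     float_format="%.6g")
    results["gps"] = gps_table

    svm_rows = []
    for i, disease in enumerate((d1, d2)):
        case_mask = roles == f"case{i + 1}"
        cohort = case_mask | (roles == "control")
        subg = geno.subset(samples=cohort)
        yv = case_mask[cohort].astype(int)
        pred = predict_mod.cv_svm_predict(
            subg, yv, covariates=pca.scores[cohort][:, :cfg.n_pcs_assoc],
            config=cfg.predict)
        svm_rows.append({"disease": disease.name, "auc_mean": pred.auc_mean,
                         "auc_max": pred.auc_max})
    svm_table = pd.DataFrame(svm_rows)
    svm_table.to_csv(outdir / "svm.tsv", sep="\t", index=False,
                     float_format="%.6g")
    results["svm"] = svm_table
    with open(outdir / "pairwise_summary.json", "w") as fh:
        json.dump({
            "rg_auto": bivar_rows["auto"].rg,
            "rg_exMHC": bivar_rows["auto_exMHC"].rg,
            "p_nominal": p_nom,
            "gps_p": float(gps_table["p"].iloc[0]),
        }, fh, indent=2)
    return results
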