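"""End-to-end orchestration: discovery (QC -> per-cohort MLM GWAS -> meta ->
COJO -> heritability/power) and downstream causal inference (SMR/HEIDI grid,
GSMR, mediation), driven by one config with reproducible seeds.

Every multiple-testing denominator is derived from the dimensions of the
tables actually analysed, never hard-coded.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gwas, heritability, meta, proteome, simulate, smr
from . import io as pio


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, each with its published default."""

    seed: int = 0
    outdir: str = "pqtl_out"
    # proteome QC
    sample_id_fraction: float = 0.8
    feature_max_missing: float = 0.8
    replicate_min_r: float = 0.8
    # genotype QC
    hwe_p: float = 1e-5
    geno_max_missing: float = 0.05
    min_maf: float = 0.05
    min_rsq: float = 0.3
    prune_r2: float = 0.2
    relatedness: float = 0.05
    n_pcs: int = 5
    # association / meta
    alpha: float = 5e-8
    cohort_p: float = 0.05
    cis_window: float = 1e6
    cojo_collinearity_r2: float = 0.9
    cojo_window_bp: float = 10e6
    # heritability / power
    exclusion_mb: float = 10.0
    ld_score_window_bp: float = 1e6
    # causal inference
    smr_instrument_p: float = 5e-8
    clump_r2: float = 0.05
    heidi_outlier_p: float = 0.01

    def to_yaml(self, path) -> None:
        pio.write_yaml(dataclasses.asdict(self), path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**pio.read_yaml(path))


@dataclass
class DiscoveryResult:
    pqtl_table: pd.DataFrame
    meta_tables: dict
    heritability_table: pd.DataFrame
    secondary_table: pd.DataFrame
    log: list = field(default_factory=list)


def _cohort_scan(genotypes, y_by_sample: pd.Series, cfg: PipelineConfig):
    """GRM, PCs and MLM scan for one sub-cohort."""
    grm = gwas.compute_grm(genotypes, prune_r2=cfg.prune_r2)
    k = min(cfg.n_pcs, len(genotypes.samples) - 2)
    pcs = gwas.pca_covariates(grm, k=k)
    y = y_by_sample.loc[genotypes.samples].to_numpy()
    return gwas.mlma_scan(y, pcs, genotypes, grm)


def run_discovery(
    cfg: PipelineConfig,
    genotypes: simulate.GenotypeMatrix,
    run_matrix: pd.DataFrame,
    replicate_map: dict,
    subcohort: pd.Series,
    tss: pd.DataFrame,
) -> DiscoveryResult:
    """Proteome QC, per-sub-cohort MLM GWAS, random-effects meta-analysis,
    three-criterion significance calling, lead extraction with cis/trans
    labels, stepwise conditional signals, and the heritability/power columns.
    """
    log: list = []
    qc = proteome.run_qc(
        run_matrix, replicate_map,
        sample_fraction=cfg.sample_id_fraction,
        feature_max_missing=cfg.feature_max_missing,
        min_r=cfg.replicate_min_r,
    )
    log.extend(qc.log)

    geno = gwas.qc_variants(
        genotypes, hwe_p=cfg.hwe_p, max_missing=cfg.geno_max_missing,
        min_maf=cfg.min_maf, min_rsq=cfg.min_rsq,
    )
    log.append({"step": "qc_variants", "kept": geno.n_variants, "of": genotypes.n_variants})

    samples = [s for s in qc.samples if s in set(geno.samples)]
    n_features = len(qc.features)
    threshold = cfg.alpha / n_features
    log.append({"step": "significance_threshold", "alpha": cfg.alpha,
                "n_features": n_features, "threshold": threshold})

    cohorts = sorted(subcohort.loc[samples].unique())
    meta_tables, lead_rows, secondary_rows = {}, [], []
    tss_idx = tss.set_index("feature")
    cohort_geno = {
        c: geno.subset_samples([s for s in samples if subcohort[s] == c]) for c in cohorts
    }
    # drop relatives within each sub-cohort before association; a GRM entry has
    # sampling sd ~ 1/sqrt(M), so calling relatedness at the threshold needs
    # M large enough that noise cannot cross it (else every pair is suspect)
    for c in cohorts:
        g = cohort_geno[c]
        grm = gwas.compute_grm(g, prune_r2=cfg.prune_r2)
        if grm.n_snps ** -0.5 > cfg.relatedness / 2:
            log.append({"step": "prune_related", "cohort": c, "skipped":
                        f"GRM from {grm.n_snps} SNPs cannot resolve relatedness at {cfg.relatedness}"})
            continue
        keep = gwas.prune_related(grm, threshold=cfg.relatedness)
        if len(keep) < len(g.samples):
            cohort_geno[c] = g.subset_samples(keep)
            log.append({"step": "prune_related", "cohort": c,
                        "removed": len(g.samples) - len(keep)})

    for feat in qc.features:
        stats_per_cohort = [
            _cohort_scan(cohort_geno[c], qc.values[feat], cfg) for c in cohorts
        ]
        pooled = meta.meta_analyze(stats_per_cohort)
        pooled = meta.call_significant(pooled, n_features, alpha=cfg.alpha)
        meta_tables[feat] = pooled
        lead = meta.extract_lead(pooled)
        if lead is None:
            continue
        if feat in tss_idx.index:
            label, dist = meta.classify_cis_trans(
                lead["chrom"], lead["pos"], tss_idx.loc[feat, "chrom"],
                tss_idx.loc[feat, "tss"], window=cfg.cis_window,
            )
        else:
            label, dist = "unassigned", float("nan")
        maf = min(lead["freq"], 1 - lead["freq"])
        q2 = heritability.variance_explained(lead["b"], maf) if 0 < maf <= 0.5 else np.nan
        pw = heritability.power(lead["freq"], lead["b"], lead["n"], threshold)
        lead_rows.append({
            "feature": feat, "snp": lead["snp"], "chrom": lead["chrom"],
            "pos": lead["pos"], "a1": lead["a1"], "a2": lead["a2"],
            "freq": lead["freq"], "b": lead["b"], "se": lead["se"], "p": lead["p"],
            "cis_trans": label, "dist_tss": dist, "var_explained": q2, "power": pw,
        })
        cojo = meta.cojo_stepwise(
            pooled, geno, p_threshold=threshold,
            collinearity_r2=cfg.cojo_collinearity_r2, window_bp=cfg.cojo_window_bp,
        )
        for _, r in cojo.iterrows():
            if r["snp"] == lead["snp"]:
                continue
            secondary_rows.append({
                "feature": feat, "snp": r["snp"], "b": r["b"], "se": r["se"],
                "p": r["p"], "b_joint": r["b_joint"], "se_joint": r["se_joint"],
                "p_joint": r["p_joint"],
            })

    pqtl = pd.DataFrame(lead_rows)
    secondary = pd.DataFrame(secondary_rows)

    # heritability partition per feature with a lead
    herit_rows, poly_fits = [], {}
    ld_scores = heritability.compute_ld_scores(geno, window_bp=cfg.ld_score_window_bp)
    for _, r in pqtl.iterrows():
        feat = r["feature"]
        leads = [(r["chrom"], r["pos"])]
        maf = min(r["freq"], 1 - r["freq"])
        q2 = heritability.variance_explained(r["b"], maf)
        q2_joint = 0.0
        sec = secondary[secondary["feature"] == feat] if len(secondary) else secondary
        if len(sec):
            pooled = meta_tables[feat].set_index("snp")
            for _, s in sec.iterrows():
                fr = pooled.loc[s["snp"], "freq"]
                mafj = min(fr, 1 - fr)
                q2_joint += heritability.joint_variance_explained(s["b"], s["b_joint"], mafj)
        try:
            fit = heritability.ldsc_polygenic(
                meta_tables[feat], ld_scores, n=float(meta_tables[feat]["n"].median()),
                m_total=geno.n_variants, lead_pqtls=leads, exclusion_mb=cfg.exclusion_mb,
            )
        except ValueError:
            fit = None
        poly_fits[feat] = fit
        herit_rows.append({
            "feature": feat, "h2_lead": q2 + q2_joint,
            "h2_poly": fit.h2_poly if fit else np.nan,
            "intercept": fit.intercept if fit else np.nan,
            "m_snps": fit.m_snps if fit else 0,
            "n_leads": 1 + (len(sec) if len(secondary) else 0),
        })
    herit = pd.DataFrame(herit_rows)
    return DiscoveryResult(pqtl, meta_tables, herit, secondary, log)


def run_causal(
    cfg: PipelineConfig,
    exposure_stats: dict,
    outcome_stats: dict,
    ld_ref: simulate.GenotypeMatrix,
    tss: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """SMR + HEIDI colocalization over an exposures x outcomes grid.

    ``exposure_stats`` maps feature -> cis-region AssocStats; ``outcome_stats``
    maps outcome name -> AssocStats over the same variants. MHC variants are
    excluded first; the Bonferroni threshold is alpha / (rows x cols of the
    grid actually tested).
    """
    rows = []
    for feat, cis in exposure_stats.items():
        keep = smr.exclude_mhc(cis[["snp", "chrom", "pos"]].rename(columns={"snp": "id"}))
        cis = cis[cis["snp"].isin(keep["id"])].reset_index(drop=True)
        if len(cis) == 0 or cis["p"].min() >= cfg.smr_instrument_p:
            continue
        top = int(np.argmin(cis["p"].to_numpy()))
        ld = smr.ld_r_matrix(ld_ref, list(cis["snp"]))
        for out_name, out_stats in outcome_stats.items():
            out_aligned = out_stats.set_index("snp").reindex(cis["snp"]).reset_index()
            if out_aligned["b"].isna().any():
                continue
            b_xy, se_xy, p_smr = smr.smr_single(
                cis["b"].iloc[top], cis["se"].iloc[top],
                out_aligned["b"].iloc[top], out_aligned["se"].iloc[top],
            )
            sel = smr.select_heidi_snps(cis, ld, top)
            p_heidi = smr.heidi(cis, out_aligned, ld, top, sel) if sel else np.nan
            try:
                _, p_multi, inst = smr.smr_multi(cis, out_aligned, ld, cfg.smr_instrument_p)
            except ValueError:
                p_multi, inst = np.nan, []
            rows.append({
                "exposure": feat, "outcome": out_name, "b_xy": b_xy, "se": se_xy,
                "p_smr": p_smr, "p_multi": p_multi, "p_heidi": p_heidi,
                "n_snps": len(inst),
            })
    res = pd.DataFrame(rows)
    if len(res) == 0:
        return res
    n_exp = res["exposure"].nunique()
    n_out = res["outcome"].nunique()
    return smr.colocalization_grid(res, n_exp, n_out)


def save_discovery(result: DiscoveryResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    result.pqtl_table.to_csv(os.path.join(outdir, "pqtl_table.tsv"), sep="\t", index=False)
    result.heritability_table.to_csv(os.path.join(outdir, "heritability.tsv"), sep="\t", index=False)
    result.secondary_table.to_csv(os.path.join(outdir, "secondary_signals.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "log.json"), "w") as fh:
        json.dump(result.log, fh, indent=2, default=str)
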