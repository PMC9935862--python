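"""Synthetic cohorts with known genetic architecture.

Generates genotype matrices with block-wise LD, multi-sub-cohort proteome
run matrices with replicate pairs and missing-not-at-random censoring, and a
BMI -> protein -> binary-disease mediation cohort. Every generator is seeded
and returns the ground truth it used, so each downstream analysis stage can
be tested for parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    ``variants`` is a DataFrame with columns
    ``id, chrom, pos, a1, a2, maf, rsq`` (a1 = effect/counted allele,
    pos is 1-based bp). ``dosage`` holds a1-allele counts in [0, 2].
    """

    samples: list
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError("dosage dimensions inconsistent with id lists")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def freq(self) -> np.ndarray:
        """Observed a1-allele frequency per variant."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")
        return int(idx[0])

    def subset_samples(self, keep) -> "GenotypeMatrix":
        keep = list(keep)
        pos = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(keep, self.variants.copy(), self.dosage[pos])

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            list(self.samples),
            self.variants.loc[mask].reset_index(drop=True),
            self.dosage[:, mask],
        )


@dataclass
class ProteinArchitecture:
    """Ground-truth genetic architecture of one protein."""

    name: str
    cis_variant: str | None = None
    beta_cis: float = 0.0
    trans_variant: str | None = None
    beta_trans: float = 0.0
    h2_poly: float = 0.0
    var_e: float | None = None  # residual variance; default fills to total 1
    tss_chrom: str = "1"
    tss_pos: int = 1


@dataclass
class MediationTruth:
    """True path coefficients of the BMI -> protein -> disease model."""

    alpha: float  # BMI -> protein, per BMI unit
    beta: float  # protein -> disease liability (log-odds per protein unit)
    direct: float  # BMI -> liability not through the protein
    prevalence: float
    bmi_h2: float = 0.3
    protein_var_e: float = 1.0

    @property
    def indirect(self) -> float:
        return self.alpha * self.beta


@dataclass
class ArchitectureTruth:
    proteins: list = field(default_factory=list)
    mediation: MediationTruth | None = None


# ---------------------------------------------------------------------------
# genotypes


def _binary_corr_from_latent(rho: float, t1: float, t2: float, p1: float, p2: float) -> float:
    """Correlation of two threshold-Bernoulli variables with latent normal corr rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf(
        [t1, t2]
    )
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


from functools import lru_cache


@lru_cache(maxsize=100_000)
def _latent_rho(r_target: float, maf1: float, maf2: float) -> float:
    """Latent-normal correlation giving allele correlation r_target (Gaussian copula)."""
    if r_target == 0.0:
        return 0.0
    t1, t2 = stats.norm.ppf(maf1), stats.norm.ppf(maf2)
    if r_target >= 1.0 and abs(maf1 - maf2) < 1e-12:
        return 1.0
    hi = 1.0 - 1e-9
    f = lambda rho: _binary_corr_from_latent(rho, t1, t2, maf1, maf2) - r_target
    if f(hi) <= 0:  # target not attainable with these MAFs: cap
        return hi
    return optimize.brentq(f, 0.0, hi, xtol=1e-6)


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    ld_block_sizes=None,
    maf_range=(0.05, 0.5),
    r_adj: float = 0.0,
    seed: int = 0,
    chrom: str = "1",
    pos_start: int = 1,
    pos_spacing: int = 10_000,
    chrom_assign=None,
    structure_seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate hard-call dosages as sums of two Bernoulli haplotypes.

    Within an LD block, adjacent variants follow an AR(1) Gaussian copula on
    the haplotypes calibrated so the *allele* (hence dosage) correlation of
    adjacent variants equals ``r_adj``; variants in different blocks are
    independent. Deterministic under fixed ``seed``.

    ``ld_block_sizes`` must sum to ``n_variants`` (default: one block).
    ``chrom_assign`` optionally gives a chromosome label per variant.
    ``structure_seed`` controls the MAF draw separately from the haplotype
    draw, so two cohorts can share one variant structure (same MAFs and LD)
    while holding different individuals; it defaults to ``seed``.
    """
    if n_samples < 1 or n_variants < 1:
        raise ValueError("n_samples and n_variants must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    if ld_block_sizes is None:
        ld_block_sizes = [n_variants]
    ld_block_sizes = list(ld_block_sizes)
    if len(ld_block_sizes) == 0 or any(b < 1 for b in ld_block_sizes):
        raise ValueError("ld_block_sizes must be a non-empty list of positive sizes")
    if sum(ld_block_sizes) != n_variants:
        raise ValueError("ld_block_sizes must sum to n_variants")

    # purpose-tagged seed sequences keep generators for genotypes, proteomes
    # and phenotypes statistically independent even under one shared seed
    rng = np.random.default_rng([seed, 101])
    rng_struct = np.random.default_rng(
        [seed if structure_seed is None else structure_seed, 102]
    )
    mafs = np.round(rng_struct.uniform(lo, hi, size=n_variants), 4)
    thresholds = stats.norm.ppf(mafs)

    # adjacent-pair latent correlations, zero across block boundaries
    rho = np.zeros(n_variants)  # rho[j] links variant j-1 and j
    edges = np.cumsum([0] + ld_block_sizes)
    for b0, b1 in zip(edges[:-1], edges[1:]):
        for j in range(b0 + 1, b1):
            rho[j] = _latent_rho(r_adj, mafs[j - 1], mafs[j])

    def haplotype() -> np.ndarray:
        z = np.empty((n_samples, n_variants))
        z[:, 0] = rng.standard_normal(n_samples)
        for j in range(1, n_variants):
            e = rng.standard_normal(n_samples)
            z[:, j] = rho[j] * z[:, j - 1] + np.sqrt(1 - rho[j] ** 2) * e
        return (z < thresholds).astype(np.float64)

    dosage = haplotype() + haplotype()

    chroms = list(chrom_assign) if chrom_assign is not None else [chrom] * n_variants
    variants = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(n_variants)],
            "chrom": chroms,
            "pos": pos_start + pos_spacing * np.arange(n_variants),
            "a1": "A",
            "a2": "G",
            "maf": mafs,
            "rsq": 1.0,
        }
    )
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, variants, dosage)


# ---------------------------------------------------------------------------
# proteome


@dataclass
class MissingRule:
    """Censoring: per-feature low-abundance quantile plus uniform dropout."""

    nmar_quantile: float = 0.05
    random_rate: float = 0.02


def _variance_shares(geno: GenotypeMatrix, arch: ProteinArchitecture) -> tuple:
    share = 0.0
    cis_var = trans_var = 0.0
    if arch.cis_variant is not None and arch.beta_cis != 0.0:
        f = geno.freq()[geno.index_of(arch.cis_variant)]
        cis_var = arch.beta_cis**2 * 2 * f * (1 - f)
    if arch.trans_variant is not None and arch.beta_trans != 0.0:
        f = geno.freq()[geno.index_of(arch.trans_variant)]
        trans_var = arch.beta_trans**2 * 2 * f * (1 - f)
    share = cis_var + trans_var + arch.h2_poly
    return share, cis_var, trans_var


def simulate_proteome(
    genotypes: GenotypeMatrix,
    truth: ArchitectureTruth,
    n_subcohorts: int = 4,
    replicate_fraction: float = 0.3,
    missing_rule: MissingRule | None = None,
    technical_sd: float = 0.05,
    seed: int = 0,
):
    """Simulate run-level protein abundances for a multi-batch cohort.

    Each protein value is ``beta_cis*x_cis + beta_trans*x_trans + polygenic +
    N(0, var_e)``; the polygenic term sums standardized background-SNP effects
    drawn ``N(0, h2_poly/M_bg)``. A fraction of specimens is measured twice;
    replicate runs share the biological value plus independent technical
    noise. Missingness censors the lowest-abundance quantile per feature
    (missing-not-at-random) plus uniform dropout.

    Returns ``(run_values, replicate_map, subcohort)`` where ``run_values``
    is a DataFrame (rows = runs, cols = features, NaN = missing),
    ``replicate_map`` maps final sample id -> list of run ids and
    ``subcohort`` is a Series mapping sample id -> sub-cohort label.
    """
    if n_subcohorts < 1:
        raise ValueError("n_subcohorts must be >= 1")
    if missing_rule is None:
        missing_rule = MissingRule()
    rng = np.random.default_rng([seed, 103])
    n = genotypes.n_samples

    used = {a.cis_variant for a in truth.proteins} | {
        a.trans_variant for a in truth.proteins
    }
    bg_mask = ~genotypes.variants["id"].isin(used).to_numpy()
    bg = genotypes.dosage[:, bg_mask]
    bg_sd = bg.std(axis=0)
    ok = bg_sd > 0
    bg_std = (bg[:, ok] - bg[:, ok].mean(axis=0)) / bg_sd[ok]
    m_bg = bg_std.shape[1]

    bio = {}
    for arch in truth.proteins:
        share, _, _ = _variance_shares(genotypes, arch)
        if share > 1.0:
            raise ValueError(
                f"{arch.name}: requested variance shares sum to {share:.3f} > 1"
            )
        var_e = arch.var_e if arch.var_e is not None else 1.0 - share
        y = np.zeros(n)
        if arch.cis_variant is not None:
            y += arch.beta_cis * genotypes.dosage[:, genotypes.index_of(arch.cis_variant)]
        if arch.trans_variant is not None:
            y += arch.beta_trans * genotypes.dosage[:, genotypes.index_of(arch.trans_variant)]
        if arch.h2_poly > 0:
            if m_bg == 0:
                raise ValueError("h2_poly > 0 but no background variants available")
            u = rng.normal(0.0, np.sqrt(arch.h2_poly / m_bg), size=m_bg)
            y += bg_std @ u
        y += rng.normal(0.0, np.sqrt(var_e), size=n)
        bio[arch.name] = y
    bio = pd.DataFrame(bio, index=genotypes.samples)

    # replicate runs
    n_rep = int(round(replicate_fraction * n))
    rep_samples = set(rng.choice(genotypes.samples, size=n_rep, replace=False))
    rows, run_ids, replicate_map = [], [], {}
    for s in genotypes.samples:
        runs = [f"{s}_r1", f"{s}_r2"] if s in rep_samples else [f"{s}_r1"]
        replicate_map[s] = runs
        for r in runs:
            rows.append(bio.loc[s].to_numpy() + rng.normal(0, technical_sd, bio.shape[1]))
            run_ids.append(r)
    run_values = pd.DataFrame(rows, index=run_ids, columns=bio.columns)

    # missing-not-at-random censoring + uniform dropout
    vals = run_values.to_numpy()
    if missing_rule.nmar_quantile > 0:
        cut = np.nanquantile(vals, missing_rule.nmar_quantile, axis=0)
        vals[vals < cut] = np.nan
    if missing_rule.random_rate > 0:
        drop = rng.random(vals.shape) < missing_rule.random_rate
        vals[drop] = np.nan
    run_values = pd.DataFrame(vals, index=run_ids, columns=bio.columns)

    labels = [f"batch{k + 1}" for k in range(n_subcohorts)]
    assign = rng.permuted(np.arange(n)) % n_subcohorts
    subcohort = pd.Series([labels[a] for a in assign], index=genotypes.samples)
    return run_values, replicate_map, subcohort


# ---------------------------------------------------------------------------
# summary-statistic scenarios for colocalization / MR testing


def simulate_cis_summary_pair(
    n_exposure: int = 20_000,
    n_outcome: int = 20_000,
    n_snps: int = 30,
    r_adj: float = 0.85,
    maf_range=(0.1, 0.5),
    causal_exposure: int = 10,
    beta_exposure: float = 0.3,
    causal_outcome: int | None = None,
    b_xy: float = 0.3,
    seed: int = 0,
    ld_seed: int | None = None,
):
    """Exposure and outcome GWAS summary statistics over one cis region.

    Two independent cohorts are simulated over the same LD structure. The
    exposure (protein) has a causal variant at index ``causal_exposure``; the
    outcome is driven by the exposure's genetic value times ``b_xy`` when
    ``causal_outcome`` is None (single shared causal variant: colocalization),
    or by its own causal variant at ``causal_outcome`` (linkage scenario).

    Returns ``(cis_stats, outcome_stats, ld_ref)`` where ld_ref is the
    exposure-cohort genotypes (usable as the LD reference).
    """
    from . import gwas as _gwas  # deferred: avoid import cycle

    rng = np.random.default_rng([seed, 105])
    ld_seed = seed if ld_seed is None else ld_seed
    g_exp = simulate_genotypes(
        n_exposure, n_snps, ld_block_sizes=[n_snps], maf_range=maf_range,
        r_adj=r_adj, seed=2 * seed + 1, structure_seed=ld_seed,
    )
    g_out = simulate_genotypes(
        n_outcome, n_snps, ld_block_sizes=[n_snps], maf_range=maf_range,
        r_adj=r_adj, seed=2 * seed + 2, structure_seed=ld_seed,
    )
    x_exp = beta_exposure * g_exp.dosage[:, causal_exposure]
    protein = x_exp + rng.normal(0, 1.0, n_exposure)
    if causal_outcome is None:
        gv = b_xy * beta_exposure * g_out.dosage[:, causal_exposure]
    else:
        gv = b_xy * beta_exposure * g_out.dosage[:, causal_outcome]
    y = gv + rng.normal(0, 1.0, n_outcome)
    cis_stats = _gwas.ols_scan(protein, g_exp)
    outcome_stats = _gwas.ols_scan(y, g_out)
    return cis_stats, outcome_stats, g_exp


def simulate_mr_summary_pair(
    n_exposure: int = 20_000,
    n_outcome: int = 20_000,
    n_instruments: int = 10,
    gamma: float = 0.15,
    b_xy: float = 0.2,
    pleiotropy: dict | None = None,
    maf_range=(0.1, 0.5),
    seed: int = 0,
):
    """Two-sample MR summary statistics with independent instruments.

    Exposure x = sum(gamma_i g_i) + noise in cohort 1; outcome
    y = b_xy * (genetic value of x) + pleiotropic terms + noise in cohort 2.
    ``pleiotropy`` maps instrument index -> direct effect on the outcome
    (violating the exclusion restriction for that instrument).

    Returns ``(exposure_stats, outcome_stats, ld_ref)``.
    """
    from . import gwas as _gwas

    rng = np.random.default_rng([seed, 106])
    g_exp = simulate_genotypes(n_exposure, n_instruments, maf_range=maf_range,
                               r_adj=0.0, seed=2 * seed + 1, structure_seed=seed)
    g_out = simulate_genotypes(n_outcome, n_instruments, maf_range=maf_range,
                               r_adj=0.0, seed=2 * seed + 2, structure_seed=seed)
    gam = np.full(n_instruments, gamma)
    x1 = g_exp.dosage @ gam
    exposure = x1 + rng.normal(0, 1.0, n_exposure)
    y = b_xy * (g_out.dosage @ gam)
    if pleiotropy:
        for j, eff in pleiotropy.items():
            y = y + eff * g_out.dosage[:, j]
    y = y + rng.normal(0, 1.0, n_outcome)
    exposure_stats = _gwas.ols_scan(exposure, g_exp)
    outcome_stats = _gwas.ols_scan(y, g_out)
    return exposure_stats, outcome_stats, g_exp


# ---------------------------------------------------------------------------
# mediation cohort


def simulate_mediation_cohort(
    genotypes: GenotypeMatrix,
    truth: ArchitectureTruth,
    seed: int = 0,
    n_bmi_instruments: int = 10,
    cis_variant: str | None = None,
    beta_cis: float = 0.0,
):
    """Simulate (BMI, protein, binary disease) under a liability-threshold model.

    BMI is a genetic score over designated instrument SNPs plus noise;
    protein = alpha*BMI + optional cis effect + noise; disease arises when
    ``direct*BMI + beta*protein + Logistic(0,1)`` exceeds the threshold that
    yields the stated prevalence, so the conditional disease model is exactly
    logistic with slope ``beta`` per protein unit.

    Returns ``(phenotypes, truth.mediation)`` with phenotype columns
    ``bmi, protein, disease`` indexed by sample, plus the instrument ids used.
    """
    med = truth.mediation
    if med is None:
        raise ValueError("truth.mediation must be specified")
    if not (0 < med.prevalence < 1):
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng([seed, 104])
    n = genotypes.n_samples

    inst_idx = np.arange(min(n_bmi_instruments, genotypes.n_variants))
    g = genotypes.dosage[:, inst_idx]
    sd = g.std(axis=0)
    gs = (g - g.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    w = rng.normal(0.0, np.sqrt(med.bmi_h2 / len(inst_idx)), size=len(inst_idx))
    bmi = gs @ w + rng.normal(0.0, np.sqrt(1.0 - med.bmi_h2), size=n)

    protein = med.alpha * bmi + rng.normal(0.0, np.sqrt(med.protein_var_e), size=n)
    if cis_variant is not None:
        protein = protein + beta_cis * genotypes.dosage[:, genotypes.index_of(cis_variant)]

    liability = med.direct * bmi + med.beta * protein + rng.logistic(0.0, 1.0, size=n)
    thresh = np.quantile(liability, 1.0 - med.prevalence)
    disease = (liability > thresh).astype(int)

    pheno = pd.DataFrame(
        {"bmi": bmi, "protein": protein, "disease": disease}, index=genotypes.samples
    )
    instruments = [genotypes.variants["id"].iloc[int(j)] for j in inst_idx]
    return pheno, med, instruments
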