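"""Generalized summary-data MR (GSMR), clumping, and two-step MR mediation.

GSMR pools per-instrument Wald ratios b_xy(i) = b_zy(i)/b_zx(i) by
generalized least squares with an LD-aware covariance, after iteratively
removing pleiotropic instruments whose deviation from the pooled estimate is
significant (HEIDI-outlier). The mediation estimator is the product of
coefficients: indirect = alpha * beta with the Goodman standard error
sigma_ab = sqrt(alpha^2 s_b^2 + beta^2 s_a^2 - s_a^2 s_b^2); when the
radicand is negative (possible for tiny effects) the first-order form
sqrt(alpha^2 s_b^2 + beta^2 s_a^2) is used and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .smr import smr_single


@dataclass
class CausalEstimate:
    """One exposure -> outcome effect with provenance."""

    exposure: str
    outcome: str
    method: str  # wald | smr | smr_multi | gsmr | mediation
    b_xy: float
    se: float
    p: float
    n_instruments: int
    instruments: list = field(default_factory=list)
    removed_instruments: list = field(default_factory=list)
    p_heidi: float | None = None

    @property
    def passed_heidi(self) -> bool | None:
        return None if self.p_heidi is None else self.p_heidi > 0.05

    @property
    def odds_ratio(self) -> float:
        """exp(b_xy) for log-odds outcomes."""
        return float(np.exp(self.b_xy))


def clump(stats_df: pd.DataFrame, ld_ref, p_threshold: float = 5e-8, r2: float = 0.05) -> list:
    """Greedy LD clumping of summary statistics.

    Repeatedly takes the most significant SNP below ``p_threshold`` and
    removes every remaining SNP with r^2 >= ``r2`` to it. Deterministic and
    independent of input row order (ties on p broken by snp id).
    Returns the retained snp ids.
    """
    df = stats_df[stats_df["p"] < p_threshold]
    df = df.sort_values(["p", "snp"], kind="mergesort")
    ids = [s for s in df["snp"] if s in set(ld_ref.variants["id"])]
    kept: list[str] = []
    g = {s: ld_ref.dosage[:, ld_ref.index_of(s)] for s in ids}
    removed = set()
    for s in ids:
        if s in removed:
            continue
        kept.append(s)
        xs = g[s]
        for t in ids:
            if t in removed or t == s:
                continue
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(xs, g[t])[0, 1]
            if np.isfinite(r) and r * r >= r2:
                removed.add(t)
    return kept


def _wald_ratios(exposure: pd.DataFrame, outcome: pd.DataFrame, snps: list):
    """Per-instrument Wald ratios with first-order and full delta variances.

    The first-order variance (outcome error only) drives the pooling weights
    — weights involving the estimated bzy would be anticorrelated with the
    ratio and bias the pooled estimate toward zero — while the full
    delta-method variance (exposure error included) is used for the reported
    standard error and the outlier test.
    """
    exp = exposure.set_index("snp").loc[snps]
    out = outcome.set_index("snp").loc[snps]
    bzx, sezx = exp["b"].to_numpy(dtype=float), exp["se"].to_numpy(dtype=float)
    bzy, sezy = out["b"].to_numpy(dtype=float), out["se"].to_numpy(dtype=float)
    if np.any(bzx == 0):
        raise ValueError("instrument with zero exposure effect")
    bxy = bzy / bzx
    var1 = sezy**2 / bzx**2
    var_full = var1 + bzy**2 * sezx**2 / bzx**4
    return bxy, var1, var_full, (bzx, sezx, bzy, sezy)


def gsmr(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    instruments: list,
    ld_ref=None,
    heidi_outlier_p: float = 0.01,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> CausalEstimate:
    """GSMR estimate of the exposure -> outcome effect from summary data.

    Instruments must be harmonized to shared effect alleles in both summary
    sets. Pleiotropic instruments are removed iteratively: at each round the
    instrument whose Wald ratio deviates most from the current pooled
    estimate, with two-sided normal p < ``heidi_outlier_p``, is dropped and
    the estimate refit. Pooling is GLS with covariance built from LD r between
    instruments and the delta-method variances; with one instrument the
    estimate is the plain Wald ratio (identical to single-SNP SMR's b_xy).
    """
    snps = list(instruments)
    have = set(exposure_stats["snp"]) & set(outcome_stats["snp"])
    snps = [s for s in snps if s in have]
    if len(snps) == 0:
        raise ValueError("no valid instruments shared by both summary sets")
    removed = []
    while True:
        bxy, var1, var_full, raw = _wald_ratios(exposure_stats, outcome_stats, snps)
        if ld_ref is not None and len(snps) > 1:
            from .smr import ld_r_matrix

            r = ld_r_matrix(ld_ref, snps)
        else:
            r = np.eye(len(snps))
        sd1 = np.sqrt(var1)
        sd = np.sqrt(var_full)
        omega1 = r * np.outer(sd1, sd1)
        omega_full = r * np.outer(sd, sd)
        # GLS with first-order weights; se propagates the full covariance
        ones = np.ones(len(snps))
        w = np.linalg.pinv(omega1) @ ones
        denom = float(w @ ones)
        b_pool = float(w @ bxy / denom)
        se_pool = float(np.sqrt(w @ omega_full @ w) / denom)
        if len(snps) > 1:
            # multiplicative overdispersion floor (random-effects IVW): residual
            # heterogeneity of the Wald ratios under the pooling weights inflates
            # the pooled se, never deflates it
            d = bxy - b_pool
            q = float(d @ np.linalg.pinv(omega1) @ d)
            se_pool *= np.sqrt(max(1.0, q / (len(snps) - 1)))
        if len(snps) == 1:
            break
        # HEIDI-outlier: deviation of each instrument from the pooled estimate
        z = (bxy - b_pool) / sd
        p_dev = 2 * stats.norm.sf(np.abs(z))
        worst = int(np.argmin(p_dev))
        if p_dev[worst] >= heidi_outlier_p:
            break
        removed.append(snps[worst])
        snps = [s for i, s in enumerate(snps) if i != worst]
        if len(snps) == 0:
            raise ValueError("no valid instruments: all removed as pleiotropic outliers")
    p = float(2 * stats.norm.sf(abs(b_pool / se_pool))) if se_pool > 0 else 1.0
    method = "wald" if len(snps) == 1 else "gsmr"
    return CausalEstimate(
        exposure_name, outcome_name, method, b_pool, se_pool, p,
        len(snps), snps, removed,
    )


def bidirectional(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    ld_ref,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.05,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
):
    """Run GSMR in both directions with independently clumped instruments.

    Returns ``(forward, reverse)`` CausalEstimates; a direction with no
    instrument below the threshold yields None for that direction.
    """
    fwd_inst = clump(exposure_stats, ld_ref, p_threshold, clump_r2)
    rev_inst = clump(outcome_stats, ld_ref, p_threshold, clump_r2)
    fwd = (
        gsmr(exposure_stats, outcome_stats, fwd_inst, ld_ref,
             exposure_name=exposure_name, outcome_name=outcome_name)
        if fwd_inst else None
    )
    rev = (
        gsmr(outcome_stats, exposure_stats, rev_inst, ld_ref,
             exposure_name=outcome_name, outcome_name=exposure_name)
        if rev_inst else None
    )
    return fwd, rev


def convert_sd_units(b_per_sd: float, se_per_sd: float, sd: float):
    """Convert an effect per 1-SD exposure to per-unit (divide b and se by sd)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return b_per_sd / sd, se_per_sd / sd


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    alpha: float
    se_alpha: float
    beta: float
    se_beta: float
    indirect: float
    se_indirect: float
    z: float
    p: float
    used_fallback_se: bool
    total: float | None = None
    se_total: float | None = None


def mediate(alpha: float, se_alpha: float, beta: float, se_beta: float,
            exposure: str = "exposure", mediator: str = "mediator",
            outcome: str = "outcome") -> MediationResult:
    """Product-of-coefficients mediation with the Goodman SE.

    indirect = alpha*beta; sigma_ab = sqrt(a^2 s_b^2 + b^2 s_a^2 - s_a^2 s_b^2),
    falling back to the first-order delta form when the radicand is negative.
    """
    if se_alpha <= 0 or se_beta <= 0:
        raise ValueError("standard errors must be positive")
    indirect = alpha * beta
    radicand = alpha**2 * se_beta**2 + beta**2 * se_alpha**2 - se_alpha**2 * se_beta**2
    fallback = radicand < 0
    if fallback:
        radicand = alpha**2 * se_beta**2 + beta**2 * se_alpha**2
    se_ind = float(np.sqrt(radicand))
    z = indirect / se_ind if se_ind > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return MediationResult(
        exposure, mediator, outcome, alpha, se_alpha, beta, se_beta,
        float(indirect), se_ind, float(z), p, bool(fallback),
    )


def two_step_mr(
    bmi_stats: pd.DataFrame,
    protein_stats: pd.DataFrame,
    disease_stats: pd.DataFrame,
    ld_ref,
    bmi_sd: float | None = None,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.05,
    mediator_name: str = "protein",
) -> MediationResult:
    """Two-step MR mediation of the BMI -> protein -> disease path.

    Step 0: total effect, GSMR of disease on BMI instruments. Step 1:
    alpha = GSMR(BMI -> protein), converted from per-SD to per-unit when
    ``bmi_sd`` is given. Step 2: beta = GSMR(protein -> disease) with the
    protein's own instruments. Indirect effect and SE via :func:`mediate`.
    """
    bmi_inst = clump(bmi_stats, ld_ref, p_threshold, clump_r2)
    # mediator instruments must not be exposure instruments: a BMI-associated
    # SNP reaching significance in the protein GWAS acts only through BMI and
    # would re-estimate the exposure path (and is typically weak for the
    # protein), so the beta leg uses the protein's own variants
    prot_inst = [s for s in clump(protein_stats, ld_ref, p_threshold, clump_r2)
                 if s not in set(bmi_inst)]
    if not bmi_inst:
        raise ValueError("no BMI instruments below threshold")
    if not prot_inst:
        raise ValueError("no protein instruments below threshold")
    total = gsmr(bmi_stats, disease_stats, bmi_inst, ld_ref,
                 exposure_name="bmi", outcome_name="disease")
    a_est = gsmr(bmi_stats, protein_stats, bmi_inst, ld_ref,
                 exposure_name="bmi", outcome_name=mediator_name)
    alpha, se_alpha = a_est.b_xy, a_est.se
    if bmi_sd is not None:
        alpha, se_alpha = convert_sd_units(alpha, se_alpha, bmi_sd)
    b_est = gsmr(protein_stats, disease_stats, prot_inst, ld_ref,
                 exposure_name=mediator_name, outcome_name="disease")
    res = mediate(alpha, se_alpha, b_est.b_xy, b_est.se,
                  exposure="bmi", mediator=mediator_name, outcome="disease")
    res.total, res.se_total = total.b_xy, total.se
    return res
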