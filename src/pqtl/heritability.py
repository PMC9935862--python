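"""Per-protein heritability partition and the analytic GWAS power calculator.

The variance explained by a lead pQTL on a unit-variance (RINT) phenotype is
q^2 = 2 b^2 MAF (1 - MAF); SNPs selected jointly with the lead contribute
q_j^2 = 2 b b_j MAF (1 - MAF) with b_j the conditional-analysis estimate.
The polygenic background is estimated by LD score regression on the SNPs
remaining after excluding everything within 10 Mb of a lead pQTL, because a
single strong locus inflates chi-square statistics of its LD neighbourhood
and would be double-counted.

Power uses the noncentral chi-square of the single-SNP Wald test with
NCP = 2 f (1-f) b^2 N / (1 - 2 f (1-f) b^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix


def variance_explained(b: float, maf: float) -> float:
    """q^2 = 2 b^2 maf (1 - maf) on a unit-variance phenotype."""
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    return 2.0 * b * b * maf * (1.0 - maf)


def joint_variance_explained(b_marginal: float, b_joint: float, maf: float) -> float:
    """q_j^2 = 2 b b_j maf (1 - maf); may be negative when signs differ."""
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    return 2.0 * b_marginal * b_joint * maf * (1.0 - maf)


def compute_ld_scores(ld_ref: GenotypeMatrix, window_bp: float = 1e6) -> np.ndarray:
    """Per-variant LD score: sum of bias-adjusted r^2 over the window (self included).

    Uses r^2_adj = r^2 - (1 - r^2)/(n - 2); a window holding only the variant
    itself gives l = 1.
    """
    g = ld_ref.dosage
    n = ld_ref.n_samples
    sd = g.std(axis=0)
    gc = np.where(sd > 0, (g - g.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    pos = ld_ref.variants["pos"].to_numpy(dtype=float)
    chrom = ld_ref.variants["chrom"].astype(str).to_numpy()
    m = ld_ref.n_variants
    ell = np.ones(m)
    for j in range(m):
        near = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window_bp)
        near[j] = False
        idx = np.where(near)[0]
        if idx.size == 0 or sd[j] == 0:
            continue
        r2 = (gc[:, idx].T @ gc[:, j] / n) ** 2
        r2_adj = r2 - (1.0 - r2) / (n - 2)
        ell[j] = 1.0 + float(np.clip(r2_adj, 0.0, None).sum())
    return ell


@dataclass
class PolygenicFit:
    h2_poly: float
    intercept: float
    m_snps: int
    n_excluded: int


def ldsc_polygenic(
    assoc: pd.DataFrame,
    ld_scores: np.ndarray,
    n: float,
    m_total: int,
    lead_pqtls=(),
    exclusion_mb: float = 10.0,
    min_snps: int = 50,
) -> PolygenicFit:
    """LD score regression for the polygenic background.

    Regresses per-SNP chi-square on N*l/M with a free intercept after
    dropping every SNP within ``exclusion_mb`` Mb of a lead pQTL
    (``lead_pqtls`` is an iterable of (chrom, pos)). One heteroskedasticity
    reweighting pass with weights 1/(1 + N h2 l / M)^2 follows an unweighted
    first fit.
    """
    chi2 = (assoc["b"].to_numpy() / assoc["se"].to_numpy()) ** 2
    pos = assoc["pos"].to_numpy(dtype=float)
    chrom = assoc["chrom"].astype(str).to_numpy()
    keep = np.ones(len(assoc), dtype=bool)
    for lc, lp in lead_pqtls:
        keep &= ~((chrom == str(lc)) & (np.abs(pos - float(lp)) <= exclusion_mb * 1e6))
    if keep.sum() < min_snps:
        raise ValueError(f"only {int(keep.sum())} SNPs left after lead exclusion (<{min_snps})")
    y = chi2[keep]
    x = n * np.asarray(ld_scores)[keep] / m_total

    def wls(weights):
        xmat = np.column_stack([np.ones_like(x), x])
        wx = xmat * weights[:, None]
        beta = np.linalg.solve(xmat.T @ wx, wx.T @ y)
        return beta  # [intercept, slope=h2]

    beta = wls(np.ones_like(x))
    h2 = max(0.0, float(beta[1]))
    w = 1.0 / (1.0 + h2 * x) ** 2
    beta = wls(w)
    return PolygenicFit(float(beta[1]), float(beta[0]), int(keep.sum()), int((~keep).sum()))


def power(f: float, b: float, n: float, p_threshold: float) -> float:
    """Analytic power of the 1-df association test.

    NCP = 2f(1-f)b^2 N / (1 - 2f(1-f)b^2); the test rejects when the statistic
    exceeds the central chi-square(1) quantile at 1 - p_threshold, and power
    is the noncentral chi-square(1, NCP) upper tail there. At b = 0 the power
    equals p_threshold exactly.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    share = 2.0 * f * (1.0 - f) * b * b
    if share >= 1.0:
        raise ValueError("2f(1-f)b^2 must be < 1 (variance share)")
    t = stats.chi2.ppf(1.0 - p_threshold, df=1)
    if b == 0:
        return float(p_threshold)
    ncp = share * n / (1.0 - share)
    return float(stats.ncx2.sf(t, df=1, nc=ncp))


def heritability_table(
    leads: pd.DataFrame,
    polygenic: dict,
) -> pd.DataFrame:
    """Combine per-feature lead q^2 sums with LDSC polygenic fits.

    ``leads`` needs columns (feature, q2); ``polygenic`` maps feature ->
    PolygenicFit (or None).
    """
    rows = []
    for feat, grp in leads.groupby("feature"):
        fit = polygenic.get(feat)
        rows.append(
            {
                "feature": feat,
                "h2_lead": float(grp["q2"].sum()),
                "h2_poly": fit.h2_poly if fit else np.nan,
                "intercept": fit.intercept if fit else np.nan,
                "m_snps": fit.m_snps if fit else 0,
                "n_leads": len(grp),
            }
        )
    return pd.DataFrame(rows)
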