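"""Summary-data Mendelian randomization (SMR) and the HEIDI colocalization test.

SMR tests whether a protein and an outcome share a causal variant by taking
the top cis-pQTL as instrument: b_xy = b_zy / b_zx with the chi-square
statistic T = z_x^2 z_y^2 / (z_x^2 + z_y^2). HEIDI (heterogeneity in
dependent instruments) asks whether the Wald ratios of surrounding cis SNPs
agree with the top SNP's: under a single shared causal variant they do, under
linkage they diverge. Multi-SNP SMR sums the per-instrument statistics and
refers the total to a weighted chi-square via moment matching on the
instruments' LD matrix. SNPs in the MHC region (chr6:28,477,797-33,448,354)
are excluded throughout because of its LD complexity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

MHC_CHROM = "6"
MHC_START = 28_477_797
MHC_END = 33_448_354


def exclude_mhc(variants: pd.DataFrame) -> pd.DataFrame:
    """Remove variants inside the MHC region (inclusive bounds)."""
    inside = (
        (variants["chrom"].astype(str) == MHC_CHROM)
        & (variants["pos"] >= MHC_START)
        & (variants["pos"] <= MHC_END)
    )
    return variants.loc[~inside].reset_index(drop=True)


def smr_single(bzx: float, se_zx: float, bzy: float, se_zy: float):
    """Single-instrument SMR: returns (b_xy, se_xy, p_smr).

    T_SMR = z_x^2 z_y^2 / (z_x^2 + z_y^2) ~ chi-square(1); se is |b_xy|/sqrt(T).
    """
    if bzx == 0:
        raise ValueError("bzx = 0: Wald ratio undefined")
    zx, zy = bzx / se_zx, bzy / se_zy
    b_xy = bzy / bzx
    denom = zx**2 + zy**2
    t = (zx**2 * zy**2) / denom if denom > 0 else 0.0
    p = float(stats.chi2.sf(t, df=1)) if t > 0 else 1.0
    se_xy = abs(b_xy) / np.sqrt(t) if t > 0 else np.inf
    return float(b_xy), float(se_xy), p


def ld_r_matrix(ld_ref, snp_ids) -> np.ndarray:
    """LD correlation matrix of the given variant ids from reference genotypes."""
    idx = [ld_ref.index_of(s) for s in snp_ids]
    g = ld_ref.dosage[:, idx]
    if g.shape[1] == 1:
        return np.ones((1, 1))
    return np.corrcoef(g, rowvar=False)


def select_heidi_snps(
    cis_stats: pd.DataFrame,
    ld: np.ndarray,
    top_idx: int,
    p_in: float = 1.57e-3,
    r2_low: float = 0.05,
    r2_high: float = 0.9,
    max_snps: int = 20,
) -> list:
    """Indices of cis SNPs usable for HEIDI alongside the top SNP.

    Keeps SNPs with pQTL p < ``p_in`` whose r^2 with the top SNP lies in
    [r2_low, r2_high]; if more than ``max_snps`` qualify, the most significant
    are kept.
    """
    p = cis_stats["p"].to_numpy()
    r2 = ld[top_idx] ** 2
    cand = [
        j
        for j in range(len(cis_stats))
        if j != top_idx and p[j] < p_in and r2_low <= r2[j] <= r2_high
    ]
    cand.sort(key=lambda j: p[j])
    return cand[:max_snps]


def _bxy_cov(cis: pd.DataFrame, out: pd.DataFrame, ld: np.ndarray, idx: list) -> np.ndarray:
    """Delta-method covariance of Wald ratios b_xy over the given SNP indices.

    Exposure and outcome samples are independent, so
    cov(bxy_i, bxy_j) = r_ij se_zy_i se_zy_j/(bzx_i bzx_j)
                      + r_ij se_zx_i se_zx_j bzy_i bzy_j/(bzx_i^2 bzx_j^2).
    """
    bzx = cis["b"].to_numpy()[idx]
    sezx = cis["se"].to_numpy()[idx]
    bzy = out["b"].to_numpy()[idx]
    sezy = out["se"].to_numpy()[idx]
    r = ld[np.ix_(idx, idx)]
    term1 = r * np.outer(sezy, sezy) / np.outer(bzx, bzx)
    term2 = (
        r * np.outer(sezx, sezx) * np.outer(bzy, bzy) / np.outer(bzx**2, bzx**2)
    )
    return term1 + term2


def _satterthwaite_p(t: float, cov_std: np.ndarray) -> float:
    """Tail of a sum of correlated 1-df chi-squares by two-moment matching.

    ``cov_std`` is the correlation matrix of the underlying standardized
    normals; the sum has mean k and variance 2*sum(R^2)."""
    k = cov_std.shape[0]
    var = 2.0 * float((cov_std**2).sum())
    mean = float(k)
    a = var / (2.0 * mean)
    df = 2.0 * mean**2 / var
    return float(stats.chi2.sf(t / a, df=df))


def heidi(
    cis_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    ld: np.ndarray,
    top_idx: int,
    snp_idx: list,
) -> float:
    """HEIDI p-value: heterogeneity of Wald ratios against the top SNP.

    d_i = b_xy(i) - b_xy(top); T = sum (d_i / sd_i)^2 referred to the
    distribution of a correlated chi-square sum via Satterthwaite matching on
    the correlation matrix of the d_i.
    """
    if len(snp_idx) == 0:
        raise ValueError("no SNPs selected for HEIDI")
    all_idx = [top_idx] + list(snp_idx)
    bzx = cis_stats["b"].to_numpy()
    bzy = outcome_stats["b"].to_numpy()
    bxy = bzy[all_idx] / bzx[all_idx]
    d = bxy[1:] - bxy[0]
    cov = _bxy_cov(cis_stats, outcome_stats, ld, all_idx)
    # cov of d_i = bxy_i - bxy_top
    cov_d = cov[1:, 1:] - cov[1:, :1] - cov[:1, 1:] + cov[0, 0]
    sd = np.sqrt(np.diag(cov_d))
    good = sd > 0
    if not good.all():
        d, cov_d, sd = d[good], cov_d[np.ix_(good, good)], sd[good]
        if d.size == 0:
            return 1.0
    z = d / sd
    t = float((z**2).sum())
    corr_d = cov_d / np.outer(sd, sd)
    # guard against numerically singular correlation
    corr_d = np.clip(corr_d, -1.0, 1.0)
    return _satterthwaite_p(t, corr_d)


def smr_multi(
    cis_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    ld: np.ndarray,
    p_instrument: float = 5e-8,
    dedup_r2: float = 0.9,
):
    """Multi-SNP SMR: sum of per-instrument T_SMR against a weighted chi-square.

    Instruments are cis SNPs with pQTL p < ``p_instrument``, deduplicated so
    no pair has r^2 >= ``dedup_r2`` (keeping the more significant). The null
    distribution is matched to sum(lambda_i chi2_1) with lambda the
    eigenvalues of the instruments' LD correlation matrix. One instrument
    falls back to single-SNP SMR. Returns (T, p, instrument indices).
    """
    p = cis_stats["p"].to_numpy()
    order = [int(j) for j in np.argsort(p, kind="mergesort") if p[j] < p_instrument]
    chosen: list[int] = []
    for j in order:
        if all(ld[j, k] ** 2 < dedup_r2 for k in chosen):
            chosen.append(j)
    if len(chosen) == 0:
        raise ValueError("no instruments below the significance threshold")
    if len(chosen) == 1:
        j = chosen[0]
        _, _, p_single = smr_single(
            cis_stats["b"].iloc[j], cis_stats["se"].iloc[j],
            outcome_stats["b"].iloc[j], outcome_stats["se"].iloc[j],
        )
        zx = cis_stats["b"].iloc[j] / cis_stats["se"].iloc[j]
        zy = outcome_stats["b"].iloc[j] / outcome_stats["se"].iloc[j]
        t = zx**2 * zy**2 / (zx**2 + zy**2)
        return float(t), p_single, chosen
    t_sum = 0.0
    for j in chosen:
        zx = cis_stats["b"].iloc[j] / cis_stats["se"].iloc[j]
        zy = outcome_stats["b"].iloc[j] / outcome_stats["se"].iloc[j]
        t_sum += zx**2 * zy**2 / (zx**2 + zy**2)
    lam = np.linalg.eigvalsh(ld[np.ix_(chosen, chosen)])
    lam = np.clip(lam, 0.0, None)
    a = (lam**2).sum() / lam.sum()
    df = lam.sum() ** 2 / (lam**2).sum()
    p_multi = float(stats.chi2.sf(t_sum / a, df=df))
    return float(t_sum), p_multi, chosen


def colocalization_grid(results: pd.DataFrame, n_exposures: int, n_outcomes: int, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the Bonferroni-grid + HEIDI gate to an SMR results table.

    ``results`` needs columns (p_smr, p_heidi). A pair is significant iff
    p_smr < alpha/(n_exposures*n_outcomes) and p_heidi > 0.05; missing HEIDI
    means not significant.
    """
    thr = alpha / (n_exposures * n_outcomes)
    out = results.copy()
    heidi_pass = out["p_heidi"].to_numpy(dtype=float) > 0.05
    heidi_pass &= np.isfinite(out["p_heidi"].to_numpy(dtype=float))
    out["passed_heidi"] = heidi_pass
    out["significant"] = (out["p_smr"].to_numpy() < thr) & heidi_pass
    out.attrs["smr_threshold"] = thr
    return out
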