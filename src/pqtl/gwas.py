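"""Genotype QC, GRM, PCA, relatedness pruning and mixed-linear-model GWAS.

The association model is y = Xb + g + e with g ~ N(0, sigma_g^2 A) for a
SNP-derived genomic relationship matrix A. Variance components come from a
single restricted-maximum-likelihood fit of the null (covariates-only) model;
every SNP is then tested by generalized least squares under the fitted
V = sigma_g^2 A + sigma_e^2 I, with the candidate SNP kept inside the GRM
(no leave-one-chromosome-out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import GenotypeMatrix


@dataclass
class GRM:
    """Genomic relationship matrix: symmetric relatedness among samples."""

    samples: list
    values: np.ndarray
    n_snps: int

    def __post_init__(self):
        if self.values.shape != (len(self.samples),) * 2:
            raise ValueError("GRM shape inconsistent with sample list")


# ---------------------------------------------------------------------------
# variant / sample QC


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts (mid-p off).

    Sums the probabilities of all heterozygote counts at the observed rare
    allele total that are no more likely than the observed configuration.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    # enumerate heterozygote counts with the same parity as n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # unnormalized log-probabilities of the exact HWE distribution
    from scipy.special import gammaln

    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs + 1e-12].sum()))


def hard_calls(dosage: np.ndarray) -> np.ndarray:
    """Nearest-integer genotype calls from dosages."""
    return np.clip(np.rint(dosage), 0, 2)


def qc_variants(
    genotypes: GenotypeMatrix,
    hwe_p: float = 1e-5,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
    min_rsq: float = 0.3,
) -> GenotypeMatrix:
    """Remove variants failing HWE, missingness, MAF or imputation-quality rules.

    MAF and RSQR cutoffs are strict (> min), matching "MAF >0.05" and
    "RSQR >0.3"; HWE removes p < ``hwe_p``; missing call rate removes > 0.05.
    """
    g = genotypes.dosage
    miss_rate = np.isnan(g).mean(axis=0)
    f = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(f, 1 - f)
    calls = hard_calls(g)
    keep = np.ones(genotypes.n_variants, dtype=bool)
    for j in range(genotypes.n_variants):
        if miss_rate[j] > max_missing or maf[j] <= min_maf:
            keep[j] = False
            continue
        if genotypes.variants["rsq"].iloc[j] <= min_rsq:
            keep[j] = False
            continue
        cj = calls[~np.isnan(g[:, j]), j]
        n_het = int((cj == 1).sum())
        n0, n2 = int((cj == 0).sum()), int((cj == 2).sum())
        if hwe_exact_p(n_het, n0, n2) < hwe_p:
            keep[j] = False
    return genotypes.subset_variants(keep)


def qc_samples(
    genotypes: GenotypeMatrix,
    pcs: np.ndarray | None = None,
    het_sd: float = 3.0,
    pc_sd: float = 5.0,
) -> list:
    """Return sample ids passing heterozygosity (+-3 SD) and PC1/PC2 (+-5 SD) filters.

    Boundaries are strict: a sample is removed only when |z| > the cutoff.
    """
    calls = hard_calls(genotypes.dosage)
    het = (calls == 1).mean(axis=1)
    sd = het.std()
    z_het = (het - het.mean()) / sd if sd > 0 else np.zeros_like(het)
    drop = np.abs(z_het) > het_sd
    if pcs is not None:
        for k in range(min(2, pcs.shape[1])):
            pc = pcs[:, k]
            s = pc.std()
            if s > 0:
                drop |= np.abs((pc - pc.mean()) / s) > pc_sd
    return [s for s, d in zip(genotypes.samples, drop) if not d]


# ---------------------------------------------------------------------------
# GRM / PCA / relatedness


def ld_prune(genotypes: GenotypeMatrix, r2: float = 0.2, window: int = 50) -> np.ndarray:
    """Greedy sliding-window pruning: keep a variant iff r^2 with every kept
    variant in the trailing window is below ``r2``. Returns a boolean mask."""
    g = genotypes.dosage
    m = genotypes.n_variants
    keep_idx: list[int] = []
    mask = np.zeros(m, dtype=bool)
    sd = g.std(axis=0)
    gc = g - g.mean(axis=0)
    for j in range(m):
        if sd[j] == 0:
            continue
        ok = True
        for k in reversed(keep_idx):
            if j - k > window:
                break
            r = (gc[:, j] @ gc[:, k]) / (genotypes.n_samples * sd[j] * sd[k])
            if r * r >= r2:
                ok = False
                break
        if ok:
            keep_idx.append(j)
            mask[j] = True
    return mask


def compute_grm(genotypes: GenotypeMatrix, prune_r2: float | None = 0.2) -> GRM:
    """GCTA-style GRM: A_jk = mean over SNPs of (x_j - 2f)(x_k - 2f) / (2f(1-f)).

    Variants are LD-pruned (greedy, r^2 < ``prune_r2``) first unless
    ``prune_r2`` is None; monomorphic variants are skipped.
    """
    geno = genotypes
    if prune_r2 is not None:
        geno = genotypes.subset_variants(ld_prune(genotypes, r2=prune_r2))
    if geno.n_variants < 2:
        raise ValueError("need at least 2 variants after pruning")
    f = geno.freq()
    poly = (f > 0) & (f < 1)
    g = geno.dosage[:, poly]
    f = f[poly]
    z = (g - 2 * f) / np.sqrt(2 * f * (1 - f))
    a = (z @ z.T) / z.shape[1]
    return GRM(list(geno.samples), a, int(z.shape[1]))


def prune_related(grm: GRM, threshold: float = 0.05) -> list:
    """Greedily drop one member of each pair with relatedness > ``threshold``.

    Repeatedly removes the sample in the most over-threshold pairs (ties
    broken toward the later sample id) until no pair remains. Returns kept ids.
    """
    a = grm.values.copy()
    np.fill_diagonal(a, 0.0)
    active = set(range(len(grm.samples)))
    while True:
        counts = {
            i: int((a[i, sorted(active)] > threshold).sum()) for i in active
        }
        worst = max(counts.values(), default=0)
        if worst == 0:
            break
        cand = [i for i, c in counts.items() if c == worst]
        drop = max(cand, key=lambda i: grm.samples[i])
        active.discard(drop)
        a[drop, :] = a[:, drop] = 0.0
    return [grm.samples[i] for i in sorted(active)]


def pca_covariates(grm: GRM, k: int = 5) -> np.ndarray:
    """Top-k eigenvectors of the GRM with a deterministic sign convention
    (the largest-|loading| element of each PC is positive)."""
    if k == 0:
        return np.empty((len(grm.samples), 0))
    w, v = np.linalg.eigh(grm.values)
    order = np.argsort(w)[::-1]
    if k > (w > 1e-10).sum():
        raise ValueError(f"k={k} exceeds GRM rank")
    pcs = v[:, order[:k]]
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ---------------------------------------------------------------------------
# REML and the association scan


@dataclass
class REMLResult:
    sigma_g2: float
    sigma_e2: float
    loglik: float
    converged: bool
    h2: float


def _grm_eigen(grm: GRM):
    d, u = np.linalg.eigh(grm.values)
    return np.clip(d, 0.0, None), u


def reml_fit(
    y: np.ndarray,
    covariates: np.ndarray | None,
    grm: GRM,
    tol: float = 1e-6,
    max_iter: int = 100,
    _eig=None,
) -> REMLResult:
    """Restricted maximum likelihood for y = Xb + g + e, g ~ N(0, sigma_g^2 A).

    After one eigendecomposition A = U D U' the restricted likelihood is
    profiled over the variance ratio gamma = sigma_g^2/sigma_e^2 and maximized
    by Brent search, which is exact for this two-component model. Boundary
    estimates (sigma_g^2 = 0) are allowed.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.allclose(y, y[0]):
        raise ValueError("phenotype is constant")
    x = np.column_stack([np.ones(n)] + ([covariates] if covariates is not None and np.size(covariates) else []))
    p = x.shape[1]
    d, u = _grm_eigen(grm) if _eig is None else _eig
    yt, xt = u.T @ y, u.T @ x

    def neg_restricted_ll(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        w = gamma * d + 1.0
        xw = xt / w[:, None]
        xtx = xt.T @ xw
        beta = np.linalg.solve(xtx, xw.T @ yt)
        r = yt - xt @ beta
        rss = float(r @ (r / w))
        s2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(s2)
            + np.log(w).sum()
            + np.linalg.slogdet(xtx)[1]
            + (n - p)
        )
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    gamma = float(np.exp(res.x))
    w = gamma * d + 1.0
    xw = xt / w[:, None]
    beta = np.linalg.solve(xt.T @ xw, xw.T @ yt)
    r = yt - xt @ beta
    s_e2 = float(r @ (r / w)) / (n - p)
    s_g2 = gamma * s_e2
    if res.x < -11.5:  # boundary: effectively sigma_g^2 = 0
        s_g2, s_e2 = 0.0, float(r @ r) / (n - p)
    h2 = s_g2 / (s_g2 + s_e2) if (s_g2 + s_e2) > 0 else 0.0
    if not res.success:
        raise RuntimeError(f"REML did not converge (last gamma={gamma:.3g})")
    return REMLResult(s_g2, s_e2, -res.fun, bool(res.success), h2)


def mlma_scan(
    y: np.ndarray,
    covariates: np.ndarray | None,
    genotypes: GenotypeMatrix,
    grm: GRM,
    reml: REMLResult | None = None,
    n_label: int | None = None,
    _eig=None,
) -> pd.DataFrame:
    """Per-SNP GLS association under V from the null REML fit.

    Returns an AssocStats frame with columns
    ``snp, chrom, pos, a1, a2, freq, b, se, p, n`` (freq is the a1 allele
    frequency; b is the effect per a1 allele on the phenotype scale).
    Monomorphic SNPs get NA effect rows.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    d, u = _grm_eigen(grm) if _eig is None else _eig
    if reml is None:
        reml = reml_fit(y, covariates, grm, _eig=(d, u))
    w = reml.sigma_g2 * d + reml.sigma_e2
    sw = 1.0 / np.sqrt(w)

    x = np.column_stack([np.ones(n)] + ([covariates] if covariates is not None and np.size(covariates) else []))
    xt = (u.T @ x) * sw[:, None]
    yt = (u.T @ y) * sw
    gt = (u.T @ genotypes.dosage) * sw[:, None]

    q, _ = np.linalg.qr(xt)
    ry = yt - q @ (q.T @ yt)
    rg = gt - q @ (q.T @ gt)

    sxx = np.einsum("ij,ij->j", rg, rg)
    sxy = rg.T @ ry
    poly = sxx > 1e-12
    b = np.full(genotypes.n_variants, np.nan)
    se = np.full(genotypes.n_variants, np.nan)
    b[poly] = sxy[poly] / sxx[poly]
    se[poly] = 1.0 / np.sqrt(sxx[poly])
    chi2 = (b / se) ** 2
    p = stats.chi2.sf(chi2, df=1)

    v = genotypes.variants
    return pd.DataFrame(
        {
            "snp": v["id"].to_numpy(),
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "a1": v["a1"].to_numpy(),
            "a2": v["a2"].to_numpy(),
            "freq": genotypes.freq(),
            "b": b,
            "se": se,
            "p": p,
            "n": n_label if n_label is not None else n,
        }
    )


def ols_scan(y: np.ndarray, genotypes: GenotypeMatrix, covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Vectorized per-SNP simple (or covariate-adjusted) linear regression.

    Produces the same AssocStats layout as :func:`mlma_scan`; the standard
    error uses the per-SNP residual variance with df = n - p - 1, i.e. the
    usual OLS output a summary-statistics consumer expects.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.column_stack([np.ones(n)] + ([covariates] if covariates is not None and np.size(covariates) else []))
    q, _ = np.linalg.qr(x)
    ry = y - q @ (q.T @ y)
    rg = genotypes.dosage - q @ (q.T @ genotypes.dosage)
    sxx = np.einsum("ij,ij->j", rg, rg)
    sxy = rg.T @ ry
    syy = float(ry @ ry)
    poly = sxx > 1e-12
    b = np.full(genotypes.n_variants, np.nan)
    se = np.full(genotypes.n_variants, np.nan)
    b[poly] = sxy[poly] / sxx[poly]
    dof = n - x.shape[1] - 1
    rss = syy - b**2 * sxx
    se[poly] = np.sqrt(np.clip(rss[poly], 1e-300, None) / (dof * sxx[poly]))
    tstat = b / se
    p = 2 * stats.t.sf(np.abs(tstat), df=dof)
    v = genotypes.variants
    return pd.DataFrame(
        {
            "snp": v["id"].to_numpy(),
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "a1": v["a1"].to_numpy(),
            "a2": v["a2"].to_numpy(),
            "freq": genotypes.freq(),
            "b": b,
            "se": se,
            "p": p,
            "n": n,
        }
    )


def logistic_scan(y: np.ndarray, genotypes: GenotypeMatrix, covariates: np.ndarray | None = None,
                  max_iter: int = 50, tol: float = 1e-8) -> pd.DataFrame:
    """Per-SNP logistic regression (Newton/IRLS) for a binary phenotype.

    Effects are on the log-odds scale per a1 allele.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    base = [np.ones(n)] + ([covariates] if covariates is not None and np.size(covariates) else [])
    b_out = np.full(genotypes.n_variants, np.nan)
    se_out = np.full(genotypes.n_variants, np.nan)
    for j in range(genotypes.n_variants):
        xj = genotypes.dosage[:, j]
        if xj.std() == 0:
            continue
        x = np.column_stack(base + [xj])
        beta = np.zeros(x.shape[1])
        for _ in range(max_iter):
            eta = x @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            grad = x.T @ (y - mu)
            hess = (x * w[:, None]).T @ x
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                break
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        try:
            cov = np.linalg.inv((x * w[:, None]).T @ x)
        except np.linalg.LinAlgError:
            continue
        b_out[j] = beta[-1]
        se_out[j] = np.sqrt(cov[-1, -1])
    zstat = b_out / se_out
    p = 2 * stats.norm.sf(np.abs(zstat))
    v = genotypes.variants
    return pd.DataFrame(
        {
            "snp": v["id"].to_numpy(),
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "a1": v["a1"].to_numpy(),
            "a2": v["a2"].to_numpy(),
            "freq": genotypes.freq(),
            "b": b_out,
            "se": se_out,
            "p": p,
            "n": n,
        }
    )
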