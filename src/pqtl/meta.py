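"""Random-effects meta-analysis, significance calling, lead/secondary signals.

Pooling across sub-cohorts uses the DerSimonian-Laird moment estimator of the
between-cohort variance tau^2. A variant-protein association is declared
genome-wide significant only when three criteria hold simultaneously:
(i) meta-analysis p below 5e-8 divided by the number of features tested,
(ii) p < 0.05 in every sub-cohort, and (iii) a consistent direction of effect
across the sub-cohorts. Secondary signals at a locus come from a stepwise
conditional-and-joint (COJO) selection on summary statistics plus an LD
reference, and replication uses Benjamini-Hochberg FDR plus sign agreement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def meta_random_effects(b, se):
    """DerSimonian-Laird random-effects pooling of per-cohort (b, se).

    Returns ``(b_re, se_re, p, tau2, q)``. With a single cohort the input is
    passed through with tau2 = 0.
    """
    b = np.asarray(b, dtype=float)
    se = np.asarray(se, dtype=float)
    if b.size != se.size or b.size == 0:
        raise ValueError("b and se must be equal-length, non-empty")
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all se must be finite and > 0")
    k = b.size
    if k == 1:
        p = 2 * stats.norm.sf(abs(b[0] / se[0]))
        return float(b[0]), float(se[0]), float(p), 0.0, 0.0
    w = 1.0 / se**2
    b_fixed = (w * b).sum() / w.sum()
    q = float((w * (b - b_fixed) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom)
    ws = 1.0 / (se**2 + tau2)
    b_re = float((ws * b).sum() / ws.sum())
    se_re = float(ws.sum() ** -0.5)
    p = float(2 * stats.norm.sf(abs(b_re / se_re)))
    return b_re, se_re, p, tau2, q


def meta_analyze(cohort_stats: list) -> pd.DataFrame:
    """Pool per-cohort AssocStats frames (aligned on snp) by DerSimonian-Laird.

    Returns a MetaRecord frame with pooled ``b, se, p, tau2, q`` plus
    per-cohort effect/p columns, keeping variant metadata from the first
    cohort. Only variants present in every cohort are pooled.
    """
    if len(cohort_stats) == 0:
        raise ValueError("need at least one cohort")
    common = cohort_stats[0]["snp"]
    for st in cohort_stats[1:]:
        common = common[common.isin(st["snp"])]
    frames = [st.set_index("snp").loc[common] for st in cohort_stats]
    bmat = np.column_stack([f["b"].to_numpy() for f in frames])
    semat = np.column_stack([f["se"].to_numpy() for f in frames])
    pmat = np.column_stack([f["p"].to_numpy() for f in frames])

    out = frames[0][["chrom", "pos", "a1", "a2", "freq"]].copy()
    res = []
    for i in range(len(common)):
        ok = np.isfinite(bmat[i]) & np.isfinite(semat[i]) & (semat[i] > 0)
        if not ok.any():
            res.append((np.nan, np.nan, np.nan, np.nan, np.nan))
        else:
            res.append(meta_random_effects(bmat[i][ok], semat[i][ok]))
    out["b"], out["se"], out["p"], out["tau2"], out["q"] = map(np.array, zip(*res))
    out["n"] = np.column_stack([f["n"].to_numpy() for f in frames]).sum(axis=1)
    for j in range(bmat.shape[1]):
        out[f"b_c{j + 1}"] = bmat[:, j]
        out[f"p_c{j + 1}"] = pmat[:, j]
    return out.reset_index()


def call_significant(meta: pd.DataFrame, n_features: int, alpha: float = 5e-8) -> pd.DataFrame:
    """Apply the three-criterion genome-wide significance rule.

    Adds boolean columns ``meets_meta_threshold`` (meta p < alpha/n_features),
    ``all_cohorts_p05``, ``direction_consistent`` and their conjunction
    ``genome_wide_significant``. Missing per-cohort evidence makes a record
    indeterminate, never significant.
    """
    out = meta.copy()
    bcols = [c for c in meta.columns if c.startswith("b_c")]
    pcols = [c for c in meta.columns if c.startswith("p_c")]
    threshold = alpha / n_features
    pc = meta[pcols].to_numpy()
    bc = meta[bcols].to_numpy()
    contributing = np.isfinite(pc) & np.isfinite(bc)
    any_contrib = contributing.any(axis=1)
    # evidence criteria are evaluated over the cohorts contributing to the meta
    out["meets_meta_threshold"] = np.nan_to_num(meta["p"].to_numpy(), nan=1.0) < threshold
    p_ok = np.where(contributing, pc < 0.05, True)
    out["all_cohorts_p05"] = any_contrib & p_ok.all(axis=1)
    signs = np.where(contributing, np.sign(bc), 0.0)
    n_contrib = contributing.sum(axis=1)
    out["direction_consistent"] = any_contrib & (np.abs(signs.sum(axis=1)) == n_contrib)
    out["genome_wide_significant"] = (
        out["meets_meta_threshold"] & out["all_cohorts_p05"] & out["direction_consistent"]
    )
    out.attrs["significance_threshold"] = threshold
    return out


def bonferroni_grid_threshold(n_exposures: int, n_outcomes: int = 1, alpha: float = 0.05) -> float:
    """Per-test threshold for an exposures x outcomes testing grid."""
    if n_exposures < 1 or n_outcomes < 1:
        raise ValueError("grid dimensions must be >= 1")
    return alpha / (n_exposures * n_outcomes)


def extract_lead(meta: pd.DataFrame) -> pd.Series | None:
    """Most significant genome-wide-significant record for one feature.

    Ties on p are broken by larger |b|, then lexicographically smaller snp id.
    Returns None when nothing is significant.
    """
    sig = meta[meta["genome_wide_significant"]]
    if len(sig) == 0:
        return None
    sig = sig.assign(_absb=-sig["b"].abs())
    sig = sig.sort_values(["p", "_absb", "snp"], kind="mergesort")
    return sig.drop(columns="_absb").iloc[0]


def classify_cis_trans(chrom, pos, tss_chrom, tss_pos, window: float = 1_000_000):
    """Label a variant cis iff same chromosome and |pos - TSS| <= window (1 Mb).

    Returns ``(label, distance)``; distance is signed pos - TSS on the same
    chromosome, NaN otherwise. Missing TSS -> ("unassigned", nan).
    """
    if tss_chrom is None or tss_pos is None or (isinstance(tss_pos, float) and np.isnan(tss_pos)):
        return "unassigned", float("nan")
    if str(chrom) != str(tss_chrom):
        return "trans", float("nan")
    dist = float(pos) - float(tss_pos)
    return ("cis" if abs(dist) <= window else "trans"), dist


# ---------------------------------------------------------------------------
# COJO stepwise conditional/joint analysis


def harmonize_to_reference(stats_df: pd.DataFrame, ref_variants: pd.DataFrame, drop_ambiguous: bool = False) -> pd.DataFrame:
    """Align summary statistics to a reference's effect alleles.

    Records whose alleles match the reference after a possible swap (b and
    freq flipped) or strand flip are kept; unresolvable allele pairs are
    dropped. With ``drop_ambiguous``, complementary (A/T, C/G) variants are
    removed since their strand cannot be resolved.
    """
    ref = ref_variants.set_index("id")
    rows = []
    for _, r in stats_df.iterrows():
        if r["snp"] not in ref.index:
            continue
        ra1, ra2 = ref.loc[r["snp"], "a1"], ref.loc[r["snp"], "a2"]
        a1, a2 = str(r["a1"]).upper(), str(r["a2"]).upper()
        if drop_ambiguous and COMPLEMENT.get(a1) == a2:
            continue
        flip1, flip2 = COMPLEMENT.get(a1, "N"), COMPLEMENT.get(a2, "N")
        r = r.copy()
        if (a1, a2) == (ra1, ra2) or (flip1, flip2) == (ra1, ra2):
            pass
        elif (a2, a1) == (ra1, ra2) or (flip2, flip1) == (ra1, ra2):
            r["b"] = -r["b"]
            r["freq"] = 1.0 - r["freq"]
            r["a1"], r["a2"] = ra1, ra2
        else:
            continue
        rows.append(r)
    return pd.DataFrame(rows).reset_index(drop=True)


def cojo_stepwise(
    assoc: pd.DataFrame,
    ld_ref: GenotypeMatrix,
    p_threshold: float,
    collinearity_r2: float = 0.9,
    window_bp: float = 10e6,
    freq_diff: float = 0.2,
) -> pd.DataFrame:
    """Forward stepwise selection of jointly significant SNPs from summary stats.

    Joint effects are computed from marginal (b, se, freq, N) by
    reconstructing X'X with the LD reference's observed per-SNP variances and
    correlations (SNP pairs farther apart than ``window_bp`` are treated as
    uncorrelated) and recovering the phenotype sum of squares from each SNP's
    marginal fit. Candidates in LD r^2 >= ``collinearity_r2`` with a selected
    SNP, or with |freq - freq_ref| > ``freq_diff``, are never added.

    Returns the selected SNPs with joint ``b_joint, se_joint, p_joint``.
    """
    df = harmonize_to_reference(assoc, ld_ref.variants)
    if len(df) == 0:
        return pd.DataFrame(columns=list(assoc.columns) + ["b_joint", "se_joint", "p_joint"])
    ref_idx = {v: i for i, v in enumerate(ld_ref.variants["id"])}
    gi = np.array([ref_idx[s] for s in df["snp"]])
    g = ld_ref.dosage[:, gi]
    gc = g - g.mean(axis=0)
    var0 = (gc**2).mean(axis=0)
    ok = var0 > 0
    ref_f = g.mean(axis=0) / 2.0
    ok &= (df["freq"].to_numpy() - ref_f) ** 2 <= freq_diff**2
    df, gc, var0 = df.loc[ok].reset_index(drop=True), gc[:, ok], var0[ok]
    if len(df) == 0:
        return pd.DataFrame(columns=list(assoc.columns) + ["b_joint", "se_joint", "p_joint"])

    n_arr = df["n"].to_numpy(dtype=float)
    b_m = df["b"].to_numpy(dtype=float)
    se_m = df["se"].to_numpy(dtype=float)
    pos = df["pos"].to_numpy(dtype=float)
    chrom = df["chrom"].astype(str).to_numpy()
    sxx = n_arr * var0  # X'X diagonal (centered), scaled to the GWAS sample size
    n_ref = ld_ref.n_samples
    corr = np.corrcoef(gc, rowvar=False) if len(df) > 1 else np.ones((1, 1))
    # zero out correlations beyond the window or across chromosomes
    far = (np.abs(pos[:, None] - pos[None, :]) > window_bp) | (chrom[:, None] != chrom[None, :])
    corr = np.where(far, 0.0, corr)
    yty = float(np.median(sxx * (b_m**2 + se_m**2 * (n_arr - 2))))
    n_eff = float(np.median(n_arr))
    xy = sxx * b_m

    def joint_fit(sel: list):
        idx = np.array(sel)
        s = np.sqrt(sxx[idx])
        bmat = corr[np.ix_(idx, idx)] * np.outer(s, s)
        try:
            binv = np.linalg.inv(bmat)
        except np.linalg.LinAlgError:
            return None
        bj = binv @ xy[idx]
        rss = yty - bj @ xy[idx]
        dof = n_eff - len(sel) - 1
        if rss <= 0 or dof <= 0:
            return None
        s2 = rss / dof
        sej = np.sqrt(s2 * np.diag(binv))
        pj = stats.chi2.sf((bj / sej) ** 2, df=1)
        return bj, sej, pj

    order = np.argsort(df["p"].to_numpy(), kind="mergesort")
    top = int(order[0])
    if df["p"].iloc[top] >= p_threshold:
        return pd.DataFrame(columns=list(df.columns) + ["b_joint", "se_joint", "p_joint"])
    selected = [top]
    changed = True
    while changed:
        changed = False
        best = None
        for j in range(len(df)):
            if j in selected:
                continue
            if np.any(corr[j, selected] ** 2 >= collinearity_r2):
                continue
            fit = joint_fit(selected + [j])
            if fit is None:
                continue
            pj_cand = fit[2][-1]
            if pj_cand < p_threshold and (best is None or pj_cand < best[1]):
                best = (j, pj_cand)
        if best is not None:
            selected.append(best[0])
            changed = True
            # backward check: drop previously selected SNPs that lost joint significance
            fit = joint_fit(selected)
            if fit is not None:
                weak = [selected[i] for i in range(len(selected) - 1) if fit[2][i] >= p_threshold]
                for wsnp in weak:
                    selected.remove(wsnp)
    fit = joint_fit(selected)
    out = df.iloc[selected].copy().reset_index(drop=True)
    if fit is None:
        out["b_joint"] = out["b"]
        out["se_joint"] = out["se"]
        out["p_joint"] = out["p"]
    else:
        out["b_joint"], out["se_joint"], out["p_joint"] = fit
    return out


# ---------------------------------------------------------------------------
# replication


def benjamini_hochberg(p) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def replicate_fdr(discovery: pd.DataFrame, replication: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Flag discovery pQTLs replicated at BH FDR plus direction agreement.

    Replication stats are harmonized to the discovery alleles (strand flips
    resolved; ambiguous A/T and C/G variants dropped). Each discovery record
    gets status ``replicated`` / ``not_replicated`` / ``untested``.
    """
    ref = discovery.rename(columns={"snp": "id"})[["id", "a1", "a2"]]
    rep = harmonize_to_reference(replication, ref, drop_ambiguous=True)
    rep = rep.set_index("snp")
    tested = discovery["snp"].isin(rep.index)
    out = discovery.copy()
    out["status"] = "untested"
    if tested.any():
        sub = discovery.loc[tested]
        p_rep = rep.loc[sub["snp"], "p"].to_numpy(dtype=float)
        b_rep = rep.loc[sub["snp"], "b"].to_numpy(dtype=float)
        adj = benjamini_hochberg(p_rep)
        ok = (adj < fdr) & (np.sign(b_rep) == np.sign(sub["b"].to_numpy()))
        out.loc[tested, "status"] = np.where(ok, "replicated", "not_replicated")
        out.loc[tested, "p_rep_adj"] = adj
        out.loc[tested, "b_rep"] = b_rep
    return out


def replication_rate(n_replicated: int, n_tested: int) -> float:
    """Replication percentage (e.g. 165 of 195 -> 84.6)."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return 100.0 * n_replicated / n_tested
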