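"""Meta-analysis, significance calling, cis/trans, COJO and replication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pqtl import gwas, meta
from pqtl import simulate as sim


def dl_oracle(b, se):
    """Independent brute-force DerSimonian-Laird implementation."""
    b, se = np.asarray(b, float), np.asarray(se, float)
    w = se**-2
    bf = np.sum(w * b) / np.sum(w)
    q = np.sum(w * (b - bf) ** 2)
    tau2 = max(0.0, (q - (len(b) - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
    ws = 1 / (se**2 + tau2)
    bre = np.sum(ws * b) / np.sum(ws)
    sere = np.sum(ws) ** -0.5
    return bre, sere, 2 * stats.norm.sf(abs(bre / sere)), tau2, q


class TestRandomEffects:
    def test_hand_example(self):
        b, se, p, tau2, q = meta.meta_random_effects([0.5, 0.3], [0.1, 0.1])
        assert q == pytest.approx(2.0)
        assert tau2 == pytest.approx(0.01)
        assert b == pytest.approx(0.4)
        assert se == pytest.approx(0.1)

    def test_homogeneous_cohorts(self):
        b, se, p, tau2, q = meta.meta_random_effects([0.2] * 4, [0.1] * 4)
        assert tau2 == 0.0
        assert b == pytest.approx(0.2)
        assert se == pytest.approx(0.05)

    def test_reduces_to_fixed_effects_when_q_small(self):
        b = [0.10, 0.11, 0.09]
        se = [0.1, 0.1, 0.1]
        bre, sere, _, tau2, q = meta.meta_random_effects(b, se)
        assert q <= 2 and tau2 == 0.0
        w = np.array(se, float) ** -2
        assert bre == pytest.approx(np.sum(w * b) / w.sum())

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            k = rng.integers(2, 8)
            b = rng.normal(0, 1, k)
            se = rng.uniform(0.01, 1.0, k)
            got = meta.meta_random_effects(b, se)
            want = dl_oracle(b, se)
            assert np.allclose(got, want, atol=1e-12)

    def test_single_cohort_passthrough(self):
        b, se, p, tau2, q = meta.meta_random_effects([0.3], [0.1])
        assert (b, se, tau2) == (0.3, 0.1, 0.0)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            meta.meta_random_effects([0.1, 0.2], [0.1, 0.0])


def meta_frame(p_meta, cohort_b, cohort_p):
    row = {"snp": "v0", "chrom": "1", "pos": 100, "a1": "A", "a2": "G",
           "freq": 0.3, "b": 0.5, "se": 0.1, "p": p_meta, "tau2": 0.0, "q": 0.0, "n": 100}
    for j, (bb, pp) in enumerate(zip(cohort_b, cohort_p), 1):
        row[f"b_c{j}"] = bb
        row[f"p_c{j}"] = pp
    return pd.DataFrame([row])


class TestSignificance:
    def test_printed_threshold_for_304_proteins(self):
        out = meta.call_significant(
            meta_frame(1e-10, [0.5] * 4, [0.01] * 4), n_features=304
        )
        assert out.attrs["significance_threshold"] == pytest.approx(5e-8 / 304)
        assert out.attrs["significance_threshold"] == pytest.approx(1.645e-10, rel=1e-3)
        assert bool(out["genome_wide_significant"].iloc[0])

    def test_direction_inconsistency_blocks(self):
        out = meta.call_significant(
            meta_frame(1e-12, [0.5, 0.5, 0.5, -0.1], [0.01] * 4), n_features=1
        )
        assert not bool(out["genome_wide_significant"].iloc[0])

    def test_weak_cohort_blocks(self):
        out = meta.call_significant(
            meta_frame(1e-12, [0.5] * 4, [0.01, 0.01, 0.01, 0.06]), n_features=1
        )
        assert not bool(out["genome_wide_significant"].iloc[0])

    def test_missing_cohort_evidence_never_significant(self):
        out = meta.call_significant(
            meta_frame(1e-12, [np.nan] * 4, [np.nan] * 4), n_features=1
        )
        assert not bool(out["genome_wide_significant"].iloc[0])

    @given(st.floats(1e-300, 0.04))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_cohort_p(self, p_small):
        base = meta.call_significant(
            meta_frame(1e-12, [0.5] * 4, [0.04] * 4), n_features=1
        )["genome_wide_significant"].iloc[0]
        better = meta.call_significant(
            meta_frame(1e-12, [0.5] * 4, [p_small] * 4), n_features=1
        )["genome_wide_significant"].iloc[0]
        assert bool(better) >= bool(base)


class TestLeadAndCisTrans:
    def _records(self, rows):
        df = pd.DataFrame(rows)
        df["genome_wide_significant"] = df.get("sig", True)
        return df

    def test_lowest_p_wins(self):
        df = self._records([
            {"snp": "a", "p": 1e-12, "b": 0.2},
            {"snp": "b", "p": 1e-15, "b": 0.1},
        ])
        assert meta.extract_lead(df)["snp"] == "b"

    def test_tie_broken_by_abs_effect(self):
        df = self._records([
            {"snp": "a", "p": 1e-12, "b": 0.2},
            {"snp": "b", "p": 1e-12, "b": -0.3},
        ])
        assert meta.extract_lead(df)["snp"] == "b"

    def test_no_significant_returns_none(self):
        df = self._records([{"snp": "a", "p": 1e-3, "b": 0.2, "sig": False}])
        assert meta.extract_lead(df) is None

    @pytest.mark.parametrize(
        "pos,tss,expected",
        [(5_000_000, 5_000_000, "cis"), (6_000_000, 5_000_000, "cis"),
         (6_000_001, 5_000_000, "trans"), (4_000_000, 5_000_000, "cis")],
    )
    def test_one_mb_boundary(self, pos, tss, expected):
        label, dist = meta.classify_cis_trans("1", pos, "1", tss)
        assert label == expected

    def test_other_chromosome_always_trans(self):
        label, dist = meta.classify_cis_trans("2", 100, "1", 100)
        assert label == "trans" and np.isnan(dist)

    def test_missing_tss_unassigned(self):
        label, _ = meta.classify_cis_trans("1", 100, None, None)
        assert label == "unassigned"


class TestCOJO:
    def _locus(self, seed, n=1500, betas=((3, 0.3), (15, 0.25))):
        g = sim.simulate_genotypes(
            n, 30, ld_block_sizes=[10, 10, 10], r_adj=0.4, seed=seed,
            maf_range=(0.2, 0.5),
        )
        rng = np.random.default_rng(seed + 1)
        y = rng.normal(0, 1, n)
        for j, b in betas:
            y = y + b * g.dosage[:, j]
        return g, y, gwas.ols_scan(y, g)

    def test_joint_equals_multiple_regression_on_same_sample(self):
        g, y, stats_df = self._locus(seed=31, n=2000)
        sel = meta.cojo_stepwise(stats_df, g, p_threshold=1e-5)
        assert len(sel) >= 2
        idx = [g.index_of(s) for s in sel["snp"]]
        x = np.column_stack([np.ones(len(y))] + [g.dosage[:, i] for i in idx])
        bh = np.linalg.lstsq(x, y, rcond=None)[0]
        rss = y @ y - bh @ (x.T @ y)
        se = np.sqrt(rss / (len(y) - x.shape[1]) * np.diag(np.linalg.inv(x.T @ x)))
        assert np.allclose(sel["b_joint"], bh[1:], atol=1e-6)
        assert np.allclose(sel["se_joint"], se[1:], atol=1e-6)

    def test_two_independent_causals_both_selected(self):
        g, y, stats_df = self._locus(seed=32, n=2500)
        sel = meta.cojo_stepwise(stats_df, g, p_threshold=1e-5)
        assert {"snp3", "snp15"} <= set(sel["snp"])
        truth = {"snp3": 0.3, "snp15": 0.25}
        for _, r in sel.iterrows():
            if r["snp"] in truth:
                assert abs(r["b_joint"] - truth[r["snp"]]) < 2 * r["se_joint"]

    def test_shadow_snp_not_selected(self):
        # one causal SNP inside a tight LD block: only one SNP selected
        g = sim.simulate_genotypes(3000, 10, ld_block_sizes=[10], r_adj=0.98,
                                   maf_range=(0.3, 0.5), seed=33)
        rng = np.random.default_rng(34)
        y = 0.3 * g.dosage[:, 4] + rng.normal(0, 1, 3000)
        stats_df = gwas.ols_scan(y, g)
        sel = meta.cojo_stepwise(stats_df, g, p_threshold=1e-5, collinearity_r2=0.9)
        assert len(sel) == 1

    def test_below_threshold_returns_empty(self):
        g, y, stats_df = self._locus(seed=35, n=300, betas=())
        sel = meta.cojo_stepwise(stats_df, g, p_threshold=1e-10)
        assert len(sel) == 0


class TestReplication:
    def test_bh_hand_computation(self):
        adj = meta.benjamini_hochberg([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def _tables(self, b_rep):
        disc = pd.DataFrame({
            "snp": ["v1", "v2"], "a1": ["A", "A"], "a2": ["G", "G"],
            "b": [0.5, 0.4],
        })
        rep = pd.DataFrame({
            "snp": ["v1", "v2"], "a1": ["A", "A"], "a2": ["G", "G"],
            "freq": [0.3, 0.3], "b": b_rep, "se": [0.1, 0.1],
            "p": [0.001, 0.002], "n": 500,
        })
        return disc, rep

    def test_direction_agreement_required(self):
        disc, rep = self._tables([0.5, -0.4])
        out = meta.replicate_fdr(disc, rep)
        assert list(out["status"]) == ["replicated", "not_replicated"]

    def test_absent_variant_untested(self):
        disc, rep = self._tables([0.5, 0.4])
        out = meta.replicate_fdr(disc, rep.iloc[:1])
        assert out.loc[out["snp"] == "v2", "status"].iloc[0] == "untested"

    def test_allele_swap_harmonized(self):
        disc, rep = self._tables([0.5, 0.4])
        rep.loc[0, ["a1", "a2"]] = ["G", "A"]
        rep.loc[0, "b"] = -0.5  # same direction once flipped
        out = meta.replicate_fdr(disc, rep)
        assert out["status"].iloc[0] == "replicated"

    def test_printed_replication_rate(self):
        assert meta.replication_rate(165, 195) == pytest.approx(84.6, abs=0.05)


class TestHarmonize:
    def _ref(self):
        return pd.DataFrame({"id": ["v1", "v2"], "a1": ["A", "C"], "a2": ["G", "T"]})

    def test_strand_flip_resolved(self):
        df = pd.DataFrame({"snp": ["v1"], "a1": ["T"], "a2": ["C"],  # complement of A/G
                           "b": [0.3], "freq": [0.2], "se": [0.1], "p": [0.01], "n": [100]})
        out = meta.harmonize_to_reference(df, self._ref())
        assert len(out) == 1 and out["b"].iloc[0] == 0.3

    def test_ambiguous_pair_dropped_when_requested(self):
        ref = pd.DataFrame({"id": ["v3"], "a1": ["A"], "a2": ["T"]})
        df = pd.DataFrame({"snp": ["v3"], "a1": ["A"], "a2": ["T"], "b": [0.3],
                           "freq": [0.2], "se": [0.1], "p": [0.01], "n": [100]})
        assert len(meta.harmonize_to_reference(df, ref, drop_ambiguous=True)) == 0

    def test_mismatched_alleles_dropped(self):
        # v1 reference is A/G; a C allele cannot be reconciled by swap or flip
        df = pd.DataFrame({"snp": ["v1"], "a1": ["A"], "a2": ["C"], "b": [0.3],
                           "freq": [0.2], "se": [0.1], "p": [0.01], "n": [100]})
        assert len(meta.harmonize_to_reference(df, self._ref())) == 0

    def test_grid_threshold_arithmetic(self):
        assert meta.bonferroni_grid_threshold(51, 93) == pytest.approx(0.05 / 4743)
        assert meta.bonferroni_grid_threshold(1, 1) == 0.05
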