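"""Genotype QC, GRM, PCA, relatedness, REML and the mixed-model scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pqtl import gwas
from pqtl import simulate as sim
from pqtl.simulate import GenotypeMatrix


def make_geno(dosage, mafs=None, chrom="1"):
    n, m = dosage.shape
    variants = pd.DataFrame(
        {"id": [f"v{j}" for j in range(m)], "chrom": chrom,
         "pos": 10_000 * (1 + np.arange(m)), "a1": "A", "a2": "G",
         "maf": mafs if mafs is not None else np.full(m, 0.3), "rsq": 1.0}
    )
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, np.asarray(dosage, float))


class TestVariantQC:
    def test_hwe_exact_proportions_retained(self):
        # (AA, Aa, aa) = (25, 50, 25) is exact HWE: p = 1
        assert gwas.hwe_exact_p(50, 25, 25) == pytest.approx(1.0, abs=1e-9)

    def test_hwe_extreme_deficit_removed(self):
        g = np.zeros((100, 2))
        g[:50, 0] = 2.0  # 50 AA / 50 aa, no hets: gross HWE violation
        g[:, 1] = np.tile([0, 1, 1, 2], 25)  # well-behaved companion SNP
        geno = make_geno(g)
        out = gwas.qc_variants(geno, min_maf=0.01)
        assert list(out.variants["id"]) == ["v1"]

    def test_maf_threshold_strict(self):
        rng = np.random.default_rng(0)
        g = np.column_stack([
            rng.binomial(2, 0.04, 2000),  # MAF ~0.04: removed
            rng.binomial(2, 0.30, 2000),
        ])
        out = gwas.qc_variants(make_geno(g))
        assert list(out.variants["id"]) == ["v1"]

    def test_rsq_boundary(self):
        rng = np.random.default_rng(1)
        g = np.column_stack([rng.binomial(2, 0.3, 500), rng.binomial(2, 0.3, 500)])
        geno = make_geno(g)
        geno.variants.loc[0, "rsq"] = 0.29
        geno.variants.loc[1, "rsq"] = 0.31
        out = gwas.qc_variants(geno)
        assert list(out.variants["id"]) == ["v1"]


class TestSampleQC:
    def test_uniform_het_keeps_all(self):
        g = np.tile([0.0, 1.0, 2.0, 1.0], (10, 5))
        geno = make_geno(g)
        assert gwas.qc_samples(geno) == geno.samples

    def test_het_outlier_removed(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.5, size=(200, 400)).astype(float)
        g[0] = 1.0  # all-heterozygous sample: extreme het rate
        geno = make_geno(g)
        kept = gwas.qc_samples(geno)
        assert "s0" not in kept and len(kept) >= 195

    def test_pc_boundary_is_strict(self):
        g = np.tile([0.0, 1.0, 2.0, 1.0], (20, 5))
        geno = make_geno(g)
        pcs = np.zeros((20, 2))
        pcs[:, 1] = np.random.default_rng(0).normal(size=20)
        pcs[0, 1] = pcs[:, 1].std() * 4.9 + pcs[:, 1].mean()  # z=4.9 < 5: kept
        kept = gwas.qc_samples(geno, pcs=pcs)
        assert "s0" in kept


class TestGRM:
    def test_hand_arithmetic_single_snp(self):
        # samples j, k both with x = 2 at f = 0.5: A_jk = (2-1)(2-1)/(2*0.5*0.5) = 2
        g = np.array([[2.0, 2.0], [2.0, 2.0], [0.0, 0.0], [0.0, 0.0]])
        grm = gwas.compute_grm(make_geno(g), prune_r2=None)
        assert grm.values[0, 1] == pytest.approx(2.0)
        assert grm.values[0, 2] == pytest.approx(-2.0)  # opposite homozygotes

    def test_independent_samples_offdiag_near_zero(self):
        g = sim.simulate_genotypes(500, 2000, seed=8, maf_range=(0.2, 0.5))
        grm = gwas.compute_grm(g, prune_r2=None)
        off = grm.values[~np.eye(500, dtype=bool)]
        assert abs(off.mean()) < 0.01
        assert grm.values.diagonal().mean() == pytest.approx(1.0, abs=0.05)

    def test_duplicated_sample_detected(self):
        g = sim.simulate_genotypes(100, 2000, seed=9, maf_range=(0.2, 0.5))
        dup = g.dosage.copy()
        dup[1] = dup[0]
        grm = gwas.compute_grm(make_geno(dup, mafs=g.variants["maf"]), prune_r2=None)
        assert grm.values[0, 1] > 0.9

    def test_sample_order_equivariance(self):
        g = sim.simulate_genotypes(60, 300, seed=10)
        grm = gwas.compute_grm(g, prune_r2=None)
        perm = np.random.default_rng(1).permutation(60)
        g2 = GenotypeMatrix([g.samples[i] for i in perm], g.variants, g.dosage[perm])
        grm2 = gwas.compute_grm(g2, prune_r2=None)
        assert np.allclose(grm2.values, grm.values[np.ix_(perm, perm)])

    def test_ld_pruning_removes_correlated(self):
        g = sim.simulate_genotypes(2000, 10, ld_block_sizes=[10], r_adj=0.95,
                                   maf_range=(0.3, 0.5), seed=12)
        mask = gwas.ld_prune(g, r2=0.2)
        assert mask.sum() < 5


class TestRelatednessAndPCA:
    def _grm(self, values, ids=None):
        ids = ids or [f"s{i}" for i in range(len(values))]
        return gwas.GRM(ids, np.asarray(values, float), 1000)

    def test_unrelated_set_unchanged(self):
        grm = self._grm(np.eye(4))
        assert gwas.prune_related(grm) == [f"s{i}" for i in range(4)]

    def test_duplicate_pair_one_removed(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.9
        kept = gwas.prune_related(self._grm(a))
        assert len(kept) == 2 and "s2" in kept

    def test_related_triangle_two_removed(self):
        a = np.eye(3) + 0.3
        np.fill_diagonal(a, 1.0)
        kept = gwas.prune_related(self._grm(a))
        assert len(kept) == 1

    def test_pca_separates_populations(self):
        rng = np.random.default_rng(5)
        f1, f2 = rng.uniform(0.1, 0.5, 200), rng.uniform(0.1, 0.5, 200)
        f2 = np.clip(f1 + rng.choice([-0.25, 0.25], 200), 0.05, 0.95)
        g = np.vstack([
            rng.binomial(2, f1, size=(150, 200)),
            rng.binomial(2, f2, size=(150, 200)),
        ]).astype(float)
        grm = gwas.compute_grm(make_geno(g), prune_r2=None)
        pcs = gwas.pca_covariates(grm, k=2)
        lab = np.repeat([0.0, 1.0], 150)
        assert abs(np.corrcoef(pcs[:, 0], lab)[0, 1]) > 0.9

    def test_pca_orthonormal_and_sign_fixed(self):
        g = sim.simulate_genotypes(80, 400, seed=14)
        grm = gwas.compute_grm(g, prune_r2=None)
        pcs = gwas.pca_covariates(grm, k=5)
        assert np.allclose(pcs.T @ pcs, np.eye(5), atol=1e-8)
        for j in range(5):
            assert pcs[np.argmax(np.abs(pcs[:, j])), j] > 0

    def test_pca_k0_empty(self):
        g = sim.simulate_genotypes(20, 50, seed=15)
        grm = gwas.compute_grm(g, prune_r2=None)
        assert gwas.pca_covariates(grm, k=0).shape == (20, 0)


class TestREML:
    def test_h2_recovery(self):
        rng = np.random.default_rng(2)
        g = sim.simulate_genotypes(2000, 800, seed=16, maf_range=(0.1, 0.5))
        grm = gwas.compute_grm(g, prune_r2=None)
        z = (g.dosage - g.dosage.mean(0)) / g.dosage.std(0)
        u = rng.normal(0, np.sqrt(0.5 / 800), 800)
        y = z @ u + rng.normal(0, np.sqrt(0.5), 2000)
        fit = gwas.reml_fit(y, None, grm)
        assert fit.converged
        assert fit.h2 == pytest.approx(0.5, abs=0.1)

    def test_identity_grm_total_variance(self):
        rng = np.random.default_rng(3)
        grm = gwas.GRM([f"s{i}" for i in range(500)], np.eye(500), 100)
        y = rng.normal(0, 2.0, 500)
        fit = gwas.reml_fit(y, None, grm)
        assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(y.var(ddof=1), rel=0.05)

    def test_constant_phenotype_errors(self):
        grm = gwas.GRM(["a", "b", "c"], np.eye(3), 10)
        with pytest.raises(ValueError, match="constant"):
            gwas.reml_fit(np.ones(3), None, grm)


class TestMLMAScan:
    def test_collapses_to_ols_when_no_genetic_variance(self):
        rng = np.random.default_rng(4)
        g = sim.simulate_genotypes(400, 100, seed=17)
        grm = gwas.compute_grm(g, prune_r2=None)
        y = rng.normal(size=400)
        # model collapse: with sigma_g^2 = 0 supplied, V = sigma_e^2 I and the
        # GLS effect must equal plain OLS
        fit = gwas.REMLResult(0.0, float(y.var(ddof=1)), 0.0, True, 0.0)
        mlm = gwas.mlma_scan(y, None, g, grm, reml=fit)
        ols = gwas.ols_scan(y, g)
        assert np.nanmax(np.abs(mlm["b"] - ols["b"])) < 1e-8

    def test_effect_recovery_within_two_se(self):
        rng = np.random.default_rng(6)
        g = sim.simulate_genotypes(2000, 50, seed=18, maf_range=(0.25, 0.35))
        y = 0.3 * g.dosage[:, 7] + rng.normal(0, 1, 2000)
        grm = gwas.compute_grm(g, prune_r2=None)
        st = gwas.mlma_scan(y, None, g, grm)
        row = st.iloc[7]
        assert abs(row["b"] - 0.3) < 2 * row["se"]

    def test_p_consistent_with_chi2_of_z(self):
        rng = np.random.default_rng(7)
        g = sim.simulate_genotypes(300, 30, seed=19)
        grm = gwas.compute_grm(g, prune_r2=None)
        st = gwas.mlma_scan(rng.normal(size=300), None, g, grm)
        expected = stats.chi2.sf((st["b"] / st["se"]) ** 2, df=1)
        assert np.allclose(st["p"], expected, rtol=1e-8)

    def test_monomorphic_snp_gets_na(self):
        g = sim.simulate_genotypes(100, 5, seed=20)
        g.dosage[:, 2] = 1.0
        grm = gwas.compute_grm(g, prune_r2=None)
        st = gwas.mlma_scan(np.random.default_rng(1).normal(size=100), None, g, grm)
        assert np.isnan(st["b"].iloc[2])

    def test_ols_scan_matches_linregress(self):
        rng = np.random.default_rng(8)
        g = sim.simulate_genotypes(150, 3, seed=21)
        y = rng.normal(size=150)
        st = gwas.ols_scan(y, g)
        ref = stats.linregress(g.dosage[:, 1], y)
        assert st["b"].iloc[1] == pytest.approx(ref.slope, abs=1e-12)
        assert st["se"].iloc[1] == pytest.approx(ref.stderr, abs=1e-12)

    def test_logistic_scan_recovers_log_odds(self):
        rng = np.random.default_rng(9)
        g = sim.simulate_genotypes(8000, 3, seed=22, maf_range=(0.3, 0.5))
        eta = -1.5 + 0.4 * g.dosage[:, 0]
        y = (rng.random(8000) < 1 / (1 + np.exp(-eta))).astype(float)
        st = gwas.logistic_scan(y, g)
        assert abs(st["b"].iloc[0] - 0.4) < 2.5 * st["se"].iloc[0]
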