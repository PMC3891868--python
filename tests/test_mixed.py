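"""Genomic kinship, REML polygenic fit and GRAMMAR adjustment."""

import numpy as np
import pytest

from audiogene.cohort import SimConfig, simulate_cohort
from audiogene.genio import GenotypeMatrix, SnpMeta
from audiogene.mixed import (
    KinshipMatrix,
    fit_polygenic,
    genomic_kinship,
    grammar_adjust,
)


def _gm(dosage):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    snps = [SnpMeta(f"s{j}", "1", j + 1, "A", "G") for j in range(m)]
    return GenotypeMatrix([f"i{k}" for k in range(n)], snps, dosage)


class TestKinship:
    def test_hand_computed_three_by_four(self):
        dosage = np.array(
            [
                [0, 1, 2, 1],
                [1, 1, 0, 2],
                [2, 0, 1, 1],
            ],
            dtype=float,
        )
        gm = _gm(dosage)
        p = dosage.mean(axis=0) / 2.0
        X = (dosage - 2 * p) / np.sqrt(2 * p * (1 - p))
        expected = X @ X.T / 4.0
        # bending may perturb only if negative eigenvalues exist; check raw too
        K = genomic_kinship(gm)
        np.testing.assert_allclose(K.values, expected, atol=1e-8)

    def test_duplicated_individual_has_kij_equal_kii(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.4, size=(5, 200)).astype(float)
        dosage = np.vstack([base, base[0]])  # individual 5 duplicates 0
        K = genomic_kinship(_gm(dosage))
        assert K.values[0, 5] == pytest.approx(K.values[0, 0], abs=1e-8)

    def test_invariant_to_snp_and_individual_order(self):
        rng = np.random.default_rng(1)
        dosage = rng.binomial(2, 0.3, size=(8, 300)).astype(float)
        K = genomic_kinship(_gm(dosage))
        K_snpshuf = genomic_kinship(_gm(dosage[:, rng.permutation(300)]))
        np.testing.assert_allclose(K.values, K_snpshuf.values, atol=1e-10)
        perm = rng.permutation(8)
        K_indshuf = genomic_kinship(_gm(dosage[perm]))
        np.testing.assert_allclose(
            K_indshuf.values, K.values[np.ix_(perm, perm)], atol=1e-10
        )

    def test_monomorphic_snps_skipped(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.4, size=(6, 100)).astype(float)
        with_mono = np.hstack([dosage, np.zeros((6, 20)), np.full((6, 5), 2.0)])
        np.testing.assert_allclose(
            genomic_kinship(_gm(with_mono)).values,
            genomic_kinship(_gm(dosage)).values,
            atol=1e-10,
        )

    def test_missing_dosages_pairwise(self):
        rng = np.random.default_rng(3)
        dosage = rng.binomial(2, 0.4, size=(6, 500)).astype(float)
        holey = dosage.copy()
        holey[rng.random(holey.shape) < 0.05] = np.nan
        K = genomic_kinship(_gm(holey))
        K_full = genomic_kinship(_gm(dosage))
        assert np.max(np.abs(K.values - K_full.values)) < 0.15
        np.testing.assert_allclose(K.values, K.values.T, atol=1e-12)

    def test_psd_after_bending(self):
        rng = np.random.default_rng(4)
        K = genomic_kinship(_gm(rng.binomial(2, 0.3, size=(30, 60)).astype(float)))
        assert np.min(np.linalg.eigvalsh(K.values)) >= -1e-9


class TestPolygenicFit:
    def test_identity_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(5)
        n = 120
        sex = rng.integers(0, 2, n).astype(float)
        age = rng.uniform(18, 80, n)
        y = 3.0 + 1.5 * sex + 0.2 * age + rng.normal(0, 2, n)
        K = KinshipMatrix([f"i{k}" for k in range(n)], np.eye(n))
        fit = fit_polygenic(y, sex, age, K)
        assert not fit.identifiable
        X = np.column_stack([np.ones(n), sex, age])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        got = [fit.fixed_effects[c] for c in ("intercept", "sex", "age")]
        np.testing.assert_allclose(got, beta_ols, atol=1e-8)

    def test_null_h2_estimates_near_zero(self):
        h2s = []
        for i in range(10):
            cfg = SimConfig(
                n_individuals=300, n_snps=800, n_sib_pairs=40, h2=0.0,
                shared_factor_loadings=(0.0,) * 7, noise_sd=5.0, seed=500 + i,
            )
            c = simulate_cohort(cfg)
            K = genomic_kinship(c.genotypes)
            fit = fit_polygenic(
                c.audiograms["thr_2000"].to_numpy(),
                c.audiograms["sex"].to_numpy(float),
                c.audiograms["age"].to_numpy(float),
                K,
            )
            h2s.append(fit.h2_hat)
        assert np.mean(h2s) < 0.05

    def test_h2_recovery_with_sibs(self):
        h2s = []
        for i in range(8):
            cfg = SimConfig(
                n_individuals=400, n_snps=1500, n_sib_pairs=100, h2=0.5,
                shared_factor_loadings=(0.0,) * 7, noise_sd=5.0, seed=900 + i,
            )
            c = simulate_cohort(cfg)
            K = genomic_kinship(c.genotypes)
            fit = fit_polygenic(
                c.audiograms["thr_1000"].to_numpy(),
                c.audiograms["sex"].to_numpy(float),
                c.audiograms["age"].to_numpy(float),
                K,
            )
            h2s.append(fit.h2_hat)
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.12)

    def test_zero_variance_trait_rejected(self):
        n = 40
        K = KinshipMatrix([f"i{k}" for k in range(n)], np.eye(n))
        with pytest.raises(Exception, match="zero-variance"):
            fit_polygenic(np.full(n, 3.0), None, None, K)


class TestGrammarAdjust:
    def test_h2_zero_residuals_equal_ols(self):
        rng = np.random.default_rng(6)
        n = 100
        sex = rng.integers(0, 2, n).astype(float)
        age = rng.uniform(18, 80, n)
        y = 1.0 + 0.5 * sex + 0.1 * age + rng.normal(0, 1, n)
        K = KinshipMatrix([f"i{k}" for k in range(n)], np.eye(n))
        adj = grammar_adjust(y, sex, age, K, h2_fixed=0.0)
        X = np.column_stack([np.ones(n), sex, age])
        ols_resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(adj.residuals, ols_resid, atol=1e-8)
        assert adj.gamma == pytest.approx(1.0, abs=1e-10)

    def test_residuals_orthogonal_to_covariates(self, small_cohort):
        c = small_cohort
        K = genomic_kinship(c.genotypes)
        sex = c.audiograms["sex"].to_numpy(float)
        age = c.audiograms["age"].to_numpy(float)
        adj = grammar_adjust(
            c.audiograms["thr_4000"].to_numpy(), sex, age, K, genotypes=c.genotypes
        )
        # environmental residuals are orthogonal to X in the V^-1 metric by
        # construction; with the BLUP subtracted they decorrelate from X
        for v in (np.ones_like(sex), sex, age):
            r = np.corrcoef(adj.residuals, v)[0, 1] if np.var(v) > 0 else adj.residuals.mean()
            assert abs(float(np.nan_to_num(r))) < 0.12

    def test_age_effect_recovered(self):
        cfg = SimConfig(
            n_individuals=1000, n_snps=50, n_sib_pairs=0, h2=0.0,
            shared_factor_loadings=(0.0,) * 7, noise_sd=1.0,
            age_slope_per_freq=(0.5,) * 7, seed=31,
        )
        c = simulate_cohort(cfg)
        K = KinshipMatrix(c.genotypes.individual_ids, np.eye(1000))
        adj = grammar_adjust(
            c.audiograms["thr_250"].to_numpy(),
            c.audiograms["sex"].to_numpy(float),
            c.audiograms["age"].to_numpy(float),
            K,
        )
        assert adj.fixed_effects["age"] == pytest.approx(0.5, abs=0.05)

    def test_per_model_gammas_present_with_panel(self, small_cohort):
        c = small_cohort
        K = genomic_kinship(c.genotypes)
        adj = grammar_adjust(
            c.audiograms["thr_1000"].to_numpy(),
            c.audiograms["sex"].to_numpy(float),
            c.audiograms["age"].to_numpy(float),
            K,
            genotypes=c.genotypes,
        )
        assert set(adj.gammas) == {"additive", "dominant", "recessive", "overdominant"}
        for g in adj.gammas.values():
            assert 0.1 < g < 2.0
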