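"""Gene-based genotype-PC association test internals."""

import numpy as np
import pytest
from scipy import stats

from audiogene.cohort import SimConfig, simulate_cohort
from audiogene.genio import GeneInterval, GenotypeMatrix, SnpMeta
from audiogene.genetest import (
    gene_based_test,
    genotype_pcs,
    run_gene_test,
    select_intragenic_snps,
    select_pcs,
)
from audiogene.mixed import AdjustedTrait


def _gm(dosage, positions=None, chrom="1"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = positions or [(j + 1) * 10 for j in range(m)]
    snps = [SnpMeta(f"s{j}", chrom, positions[j], "A", "G") for j in range(m)]
    return GenotypeMatrix([f"i{k}" for k in range(n)], snps, dosage)


def _adj(residuals):
    r = np.asarray(residuals, dtype=float)
    return AdjustedTrait(
        ids=[f"i{k}" for k in range(r.size)], residuals=r, trait_name="t",
        h2_hat=0.0, fixed_effects={}, gamma=1.0, sigma2=1.0, s_r2=1.0,
    )


class TestIntragenicSelection:
    def test_inclusive_boundaries(self):
        rng = np.random.default_rng(0)
        gm = _gm(rng.binomial(2, 0.4, size=(5, 4)), positions=[99, 100, 200, 201])
        sub = select_intragenic_snps(gm, GeneInterval("G", "1", 100, 200))
        assert sub.snp_ids == ["s1", "s2"]

    def test_wrong_chromosome_empty(self):
        rng = np.random.default_rng(1)
        gm = _gm(rng.binomial(2, 0.4, size=(5, 3)))
        sub = select_intragenic_snps(gm, GeneInterval("G", "2", 1, 1000))
        assert sub.n_snps == 0

    def test_constructed_52_snp_gene(self):
        cfg = SimConfig(n_individuals=60, n_snps=200, n_sib_pairs=0, seed=9)
        c = simulate_cohort(cfg)
        # SNPs sit every 5 kb starting at 5 kb; [5000, 260000] holds 52 SNPs
        sub = select_intragenic_snps(
            c.genotypes, GeneInterval("SLC16A6-like", "1", 5000, 260000)
        )
        assert sub.n_snps == 52


class TestGenotypePcs:
    def test_single_snp_fraction_one(self):
        rng = np.random.default_rng(2)
        gm = _gm(rng.binomial(2, 0.4, size=(30, 1)))
        _, fr = genotype_pcs(gm)
        assert fr[0] == pytest.approx(1.0, abs=1e-12)

    def test_perfectly_correlated_snps_rank_one(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, size=30).astype(float)
        gm = _gm(np.column_stack([g, g]))
        _, fr = genotype_pcs(gm)
        assert fr[0] == pytest.approx(1.0, abs=1e-10)

    def test_five_snp_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        G = rng.binomial(2, 0.35, size=(40, 5)).astype(float)
        gm = _gm(G)
        scores, fr = genotype_pcs(gm)
        cov = np.cov(G, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(fr, evals / evals.sum(), atol=1e-10)
        # scores are centered projections: column variances match eigenvalues
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=1), evals, atol=1e-8
        )

    def test_all_constant_submatrix_errors(self):
        gm = _gm(np.ones((10, 3)))
        with pytest.raises(Exception, match="constant"):
            genotype_pcs(gm)

    def test_missing_dosages_mean_imputed(self):
        rng = np.random.default_rng(5)
        G = rng.binomial(2, 0.4, size=(30, 4)).astype(float)
        Gm = G.copy()
        Gm[0, 0] = np.nan
        _, fr = genotype_pcs(_gm(Gm))
        assert fr.sum() == pytest.approx(1.0, abs=1e-10)


class TestSelectPcs:
    def test_strict_inequality_boundary(self):
        # threshold 1/5 = 0.2; fraction exactly 0.2 is NOT selected
        assert select_pcs(np.array([0.5, 0.3, 0.2]), 5) == [0, 1]

    def test_degenerate_single_snp_fallback(self):
        assert select_pcs(np.array([1.0]), 1) == [0]

    def test_selection_matches_direct_simulation_oracle(self):
        rng = np.random.default_rng(6)
        n, m = 2000, 20
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        _, fr = genotype_pcs(_gm(G, positions=list(range(1, m + 1))))
        expected = [k for k, f in enumerate(fr) if f > 1.0 / m]
        assert select_pcs(fr, m) == expected
        assert 0 < len(expected) < m


class TestGeneBasedTest:
    def test_single_pc_f_equals_squared_t(self):
        rng = np.random.default_rng(7)
        n = 80
        g = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        scores, fr = genotype_pcs(_gm(g))
        y = 0.3 * scores[:, 0] + rng.normal(size=n)
        res = gene_based_test(_adj(y), scores, fr, [0])
        # simple regression t test on the same score
        x = scores[:, 0]
        xc = x - x.mean()
        beta = float(xc @ (y - y.mean())) / float(xc @ xc)
        resid = (y - y.mean()) - beta * xc
        se = np.sqrt(resid @ resid / (n - 2) / (xc @ xc))
        t = beta / se
        p_t = 2 * stats.t.sf(abs(t), n - 2)
        assert res.p_value == pytest.approx(p_t, abs=1e-10)

    def test_variance_explained_partitions(self):
        rng = np.random.default_rng(8)
        G = rng.binomial(2, 0.3, size=(100, 8)).astype(float)
        gm = _gm(G)
        scores, fr = genotype_pcs(gm)
        sel = select_pcs(fr, 8)
        res = gene_based_test(_adj(rng.normal(size=100)), scores, fr, sel)
        unsel = [k for k in range(len(fr)) if k not in sel]
        assert res.variance_explained + 100 * fr[unsel].sum() == pytest.approx(100.0, abs=1e-8)

    def test_result_invariant_to_orderings(self):
        cfg = SimConfig(n_individuals=150, n_snps=30, n_sib_pairs=0, seed=10)
        c = simulate_cohort(cfg)
        rng = np.random.default_rng(11)
        y = rng.normal(size=150)

        def adj_for(ids, resid):
            return AdjustedTrait(
                ids=list(ids), residuals=resid, trait_name="t", h2_hat=0.0,
                fixed_effects={}, gamma=1.0, sigma2=1.0, s_r2=1.0,
            )

        gene = GeneInterval("G", "1", 1, 10 ** 9)
        base = run_gene_test(adj_for(c.genotypes.individual_ids, y), c.genotypes, gene)
        # shuffle SNP columns
        perm = rng.permutation(30)
        gm_s = c.genotypes.subset_snps(perm)
        shuf = run_gene_test(adj_for(c.genotypes.individual_ids, y), gm_s, gene)
        assert shuf.p_value == pytest.approx(base.p_value, abs=1e-9)
        assert shuf.n_selected_pcs == base.n_selected_pcs
        # shuffle individuals (consistently)
        iperm = rng.permutation(150)
        ids = [c.genotypes.individual_ids[i] for i in iperm]
        gm_i = c.genotypes.subset_individuals(ids)
        ishuf = run_gene_test(adj_for(ids, y[iperm]), gm_i, gene)
        assert ishuf.p_value == pytest.approx(base.p_value, abs=1e-9)

    def test_empty_gene_untestable(self):
        rng = np.random.default_rng(12)
        gm = _gm(rng.binomial(2, 0.4, size=(20, 3)))
        res = run_gene_test(_adj(rng.normal(size=20)), gm, GeneInterval("G", "9", 1, 100))
        assert res.untestable and res.total_n_snps == 0

    def test_too_few_individuals_untestable(self):
        rng = np.random.default_rng(13)
        G = rng.binomial(2, 0.45, size=(5, 10)).astype(float)
        scores, fr = genotype_pcs(_gm(G))
        res = gene_based_test(
            _adj(rng.normal(size=5)), scores, fr, [0, 1, 2, 3], total_n_snps=10
        )
        assert res.untestable

    def test_power_monotone_in_effect_size(self):
        """Empirical gene-test power never decreases with effect size
        (paired seeds across the effect grid)."""
        from audiogene.cohort import SnpEffect
        from audiogene.mixed import KinshipMatrix, grammar_adjust

        powers = []
        for eff_sd in (0.1, 0.5):
            hits = 0
            for i in range(30):
                beta = eff_sd / np.sqrt(2 * 0.3 * 0.7)
                cfg = SimConfig(
                    n_individuals=300, n_snps=30, n_sib_pairs=0, ld_rho=0.8,
                    maf_range=(0.3, 0.3), h2=0.0, shared_factor_loadings=(0.0,) * 7,
                    noise_sd=1.0, snp_effects=(SnpEffect(15, "additive", beta),),
                    seed=3000 + i,
                )
                c = simulate_cohort(cfg)
                K = KinshipMatrix(c.genotypes.individual_ids, np.eye(300))
                adj = grammar_adjust(
                    c.audiograms["thr_2000"].to_numpy(),
                    c.audiograms["sex"].to_numpy(float),
                    c.audiograms["age"].to_numpy(float), K,
                )
                r = run_gene_test(adj, c.genotypes, GeneInterval("G", "1", 1, 10 ** 9))
                hits += r.p_value < 0.05
            powers.append(hits / 30)
        assert powers[1] >= powers[0]
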