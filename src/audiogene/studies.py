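"""Reproducible simulation studies of the pipeline's operating characteristics.

Each function runs a self-contained Monte-Carlo (or exact) study of one
statistical property the analysis relies on — type-I error of the SNP and
gene tests under relatedness, effect-size and heritability recovery,
power of the gene-based test, determinism of the candidate funnel, and the
audiogram-profile classifier's detection/false-call rates — using the
synthetic-cohort generator as the data source.  All randomness flows from
the ``seed`` argument, so results are exactly reproducible.

Problem sizes default to desk-scale settings (hundreds of individuals,
hundreds of SNPs, 50-1000 replicates) chosen so each study finishes in
seconds to a few minutes on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import GENETIC_MODELS, encode_genetic_model, replication_check, snp_test, AssociationResult
from .candidates import run_candidate_filter, GwasHit
from .cohort import SimConfig, SnpEffect, simulate_audiograms, simulate_cohort
from .genio import GeneInterval, GenotypeMatrix, SnpMeta, qc_filter
from .genetest import gene_based_test, genotype_pcs, run_gene_test, select_pcs
from .mixed import KinshipMatrix, fit_polygenic, genomic_kinship, grammar_adjust
from .traits import compute_pta, THRESHOLD_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "gene_test_null_calibration",
    "snp_test_null_calibration",
    "ols_limit_discrepancy",
    "beta_recovery_study",
    "h2_recovery_study",
    "gene_test_power_study",
    "gene_test_internals_check",
    "candidate_funnel_study",
    "profile_classifier_study",
    "printed_replication_examples",
    "pta_qc_exactness",
]

_NOFACTOR = (0.0,) * 7


def _identity_adjust(cohort, trait="thr_2000"):
    n = cohort.genotypes.n_individuals
    K = KinshipMatrix(cohort.genotypes.individual_ids, np.eye(n))
    audio = cohort.audiograms
    return grammar_adjust(
        audio[trait].to_numpy(float), audio["sex"].to_numpy(float),
        audio["age"].to_numpy(float), K, trait_name=trait,
    )


def gene_test_null_calibration(
    n_reps: int = 1000, n: int = 400, n_snps: int = 40, ld_rho: float = 0.8,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Empirical rejection rate of the gene-based test on null cohorts.

    The trait is independent of the genotypes (no polygenic term, no SNP
    effects); the gene spans the full simulated panel.
    """
    ss = np.random.SeedSequence([seed, 101])
    seeds = ss.generate_state(n_reps)
    gene = GeneInterval("NULLGENE", "1", 1, 10 ** 9)
    rej = 0
    for s in seeds:
        cfg = SimConfig(
            n_individuals=n, n_snps=n_snps, n_sib_pairs=0, ld_rho=ld_rho,
            h2=0.0, shared_factor_loadings=_NOFACTOR, noise_sd=5.0,
            seed=int(s % 2 ** 31),
        )
        c = simulate_cohort(cfg)
        adj = _identity_adjust(c)
        r = run_gene_test(adj, c.genotypes, gene)
        rej += r.p_value < alpha
    return rej / n_reps


def snp_test_null_calibration(
    n_reps: int = 1000, n: int = 400, n_snps: int = 500, sib_fraction: float = 0.25,
    h2: float = 0.4, n_cohorts: int = 25, snps_per_draw: int = 10,
    alpha: float = 0.05, seed: int = 0,
) -> dict[str, float]:
    """Type-I error of the four genetic-model SNP tests under relatedness.

    Cohorts carry sibling pairs (``sib_fraction`` of individuals) and a
    polygenic background; each genotype cohort is reused for several
    independent trait draws (kinship and its eigendecomposition are fit
    once per cohort), and each draw tests a spread of panel SNPs under all
    four codings after GRAMMAR adjustment.
    """
    draws_per_cohort = max(1, n_reps // n_cohorts)
    n_pairs = int(round(sib_fraction * n / 2))
    ss = np.random.SeedSequence([seed, 202])
    cohort_seeds = ss.generate_state(n_cohorts)
    rej = {m: 0 for m in GENETIC_MODELS}
    tot = {m: 0 for m in GENETIC_MODELS}
    for cs in cohort_seeds:
        cfg = SimConfig(
            n_individuals=n, n_snps=n_snps, n_sib_pairs=n_pairs, h2=h2,
            shared_factor_loadings=_NOFACTOR, noise_sd=5.0, seed=int(cs % 2 ** 31),
        )
        c = simulate_cohort(cfg)
        K = genomic_kinship(c.genotypes)
        test_idx = np.linspace(0, n_snps - 1, snps_per_draw).astype(int)
        for d in range(draws_per_cohort):
            cfg_d = replace(cfg, seed=int((cs + 7919 * (d + 1)) % 2 ** 31))
            audio = simulate_audiograms(c.genotypes, c.pedigree, cfg_d)
            adj = grammar_adjust(
                audio["thr_2000"].to_numpy(float), audio["sex"].to_numpy(float),
                audio["age"].to_numpy(float), K, genotypes=c.genotypes,
            )
            for m in GENETIC_MODELS:
                for j in test_idx:
                    coded = encode_genetic_model(c.genotypes.dosage[:, j], m)
                    r = snp_test(adj, coded, model=m)
                    if not r.untestable:
                        tot[m] += 1
                        rej[m] += r.p_value < alpha
    return {m: rej[m] / tot[m] for m in GENETIC_MODELS}


def ols_limit_discrepancy(n: int = 100, n_snps: int = 50, seed: int = 0) -> float:
    """Max |difference| between the calibrated test (K = I, h2 pinned 0) and
    closed-form OLS of the residuals on each SNP, over betas, SEs and
    p-values."""
    rng = np.random.default_rng(seed)
    sex = rng.integers(0, 2, n).astype(float)
    age = rng.uniform(18, 80, n)
    y = 2.0 + sex + 0.3 * age + rng.normal(0, 2, n)
    G = rng.binomial(2, rng.uniform(0.1, 0.5, n_snps), size=(n, n_snps)).astype(float)
    K = KinshipMatrix([f"i{k}" for k in range(n)], np.eye(n))
    adj = grammar_adjust(y, sex, age, K, h2_fixed=0.0)
    worst = 0.0
    r = adj.residuals
    for j in range(n_snps):
        g = G[:, j]
        res = snp_test(adj, g)
        # closed-form simple OLS of residuals on g with intercept
        gc = g - g.mean()
        rc = r - r.mean()
        sxx = float(gc @ gc)
        beta = float(gc @ rc) / sxx
        rss = float(rc @ rc) - beta * beta * sxx
        se = np.sqrt(rss / (n - 2) / sxx)
        p = 2 * stats.norm.sf(abs(beta / se))
        worst = max(
            worst, abs(res.beta - beta), abs(res.se - se), abs(res.p_value - p)
        )
    return worst


def beta_recovery_study(
    n_reps: int = 200, n: int = 1000, maf: float = 0.3,
    variance_explained: float = 0.01, seed: int = 0,
) -> dict[str, float]:
    """Additive effect recovery: mean estimated beta and 95% CI coverage.

    The causal SNP explains ``variance_explained`` of the trait variance at
    the given MAF; the trait otherwise is pure noise plus covariate effects.
    """
    het = 2 * maf * (1 - maf)
    beta_true = np.sqrt(variance_explained / ((1 - variance_explained) * het))
    ss = np.random.SeedSequence([seed, 303])
    betas, cover = [], 0
    for s in ss.generate_state(n_reps):
        cfg = SimConfig(
            n_individuals=n, n_snps=5, n_sib_pairs=0, maf_range=(maf, maf),
            ld_rho=0.0, h2=0.0, shared_factor_loadings=_NOFACTOR, noise_sd=1.0,
            snp_effects=(SnpEffect(2, "additive", float(beta_true)),),
            seed=int(s % 2 ** 31),
        )
        c = simulate_cohort(cfg)
        adj = _identity_adjust(c, "thr_500")
        r = snp_test(adj, encode_genetic_model(c.genotypes.dosage[:, 2], "additive"))
        betas.append(r.beta)
        cover += (r.beta - 1.96 * r.se) <= beta_true <= (r.beta + 1.96 * r.se)
    return {
        "beta_true": float(beta_true),
        "beta_mean": float(np.mean(betas)),
        "relative_error": float(abs(np.mean(betas) / beta_true - 1.0)),
        "ci95_coverage": cover / n_reps,
    }


def h2_recovery_study(
    n_reps: int = 50, n: int = 800, n_sib_pairs: int = 200, h2: float = 0.5,
    n_snps: int = 2000, seed: int = 0,
) -> float:
    """Mean REML heritability estimate on cohorts simulated at known h2."""
    ss = np.random.SeedSequence([seed, 404])
    h2s = []
    for s in ss.generate_state(n_reps):
        cfg = SimConfig(
            n_individuals=n, n_snps=n_snps, n_sib_pairs=n_sib_pairs, h2=h2,
            shared_factor_loadings=_NOFACTOR, noise_sd=5.0, seed=int(s % 2 ** 31),
        )
        c = simulate_cohort(cfg)
        K = genomic_kinship(c.genotypes)
        fit = fit_polygenic(
            c.audiograms["thr_1000"].to_numpy(float),
            c.audiograms["sex"].to_numpy(float),
            c.audiograms["age"].to_numpy(float), K,
        )
        h2s.append(fit.h2_hat)
    return float(np.mean(h2s))


def gene_test_power_study(
    effect_sds: tuple[float, ...] = (0.1, 0.25, 0.5),
    n_reps: int = 200, n: int = 500, n_snps: int = 40, maf: float = 0.3,
    ld_rho: float = 0.8, alpha: float = 0.05, seed: int = 0,
) -> dict[float, float]:
    """Gene-based test power vs standardized causal effect size.

    ``effect_sds`` are standardized effects: the causal genotype term has
    SD = effect_sd trait SDs (beta = effect_sd / sqrt(2 p q) per allele).
    Replicates are seed-paired across effect sizes.
    """
    het = 2 * maf * (1 - maf)
    ss = np.random.SeedSequence([seed, 505])
    rep_seeds = ss.generate_state(n_reps)
    gene = GeneInterval("POWGENE", "1", 1, 10 ** 9)
    power = {}
    for eff in effect_sds:
        beta = eff / np.sqrt(het)
        hits = 0
        for s in rep_seeds:  # identical seeds across effect sizes (paired)
            cfg = SimConfig(
                n_individuals=n, n_snps=n_snps, n_sib_pairs=0, ld_rho=ld_rho,
                maf_range=(maf, maf), h2=0.0, shared_factor_loadings=_NOFACTOR,
                noise_sd=1.0,
                snp_effects=(SnpEffect(n_snps // 2, "additive", float(beta)),),
                seed=int(s % 2 ** 31),
            )
            c = simulate_cohort(cfg)
            adj = _identity_adjust(c)
            r = run_gene_test(adj, c.genotypes, gene)
            hits += r.p_value < alpha
        power[eff] = hits / n_reps
    return power


def gene_test_internals_check(seed: int = 0) -> dict[str, float]:
    """Exact oracle checks of the gene-test internals on a 5-SNP toy.

    Returns the worst absolute discrepancies: eigenvalue fractions vs a
    brute-force covariance eigendecomposition, the >1/N selection vs direct
    enumeration, and the F(1, nu) = t^2 identity for a single selected PC.
    """
    rng = np.random.default_rng(seed)
    n, m = 60, 5
    G = rng.binomial(2, 0.35, size=(n, m)).astype(float)
    gm = GenotypeMatrix(
        [f"i{k}" for k in range(n)],
        [SnpMeta(f"s{j}", "1", j + 1, "A", "G") for j in range(m)],
        G,
    )
    scores, fr = genotype_pcs(gm)
    cov = np.cov(G, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    frac_err = float(np.max(np.abs(fr - evals / evals.sum())))
    sel = select_pcs(fr, m)
    sel_oracle = [k for k, f in enumerate(fr) if f > 1.0 / m]
    sel_err = 0.0 if sel == (sel_oracle or [0]) else 1.0

    # single-PC case: joint F test equals squared-t simple regression
    y = 0.4 * scores[:, 0] + rng.normal(size=n)
    from .mixed import AdjustedTrait

    adj = AdjustedTrait(
        ids=gm.individual_ids, residuals=y, trait_name="t", h2_hat=0.0,
        fixed_effects={}, gamma=1.0, sigma2=1.0, s_r2=1.0,
    )
    res = gene_based_test(adj, scores, fr, [0])
    x = scores[:, 0] - scores[:, 0].mean()
    beta = float(x @ (y - y.mean())) / float(x @ x)
    resid = (y - y.mean()) - beta * x
    se = np.sqrt(float(resid @ resid) / (n - 2) / float(x @ x))
    p_t = 2 * stats.t.sf(abs(beta / se), n - 2)
    f_vs_t2 = float(abs(res.p_value - p_t))
    return {"fraction_err": frac_err, "selection_err": sel_err, "f_vs_t2_err": f_vs_t2}


def candidate_funnel_study(seed: int = 0, n_shuffles: int = 10) -> dict[str, float]:
    """Determinism of the candidate funnel on a 30-hit, 3-cluster fixture.

    One cluster anchors three genes at ~39/92/100 kb from its top SNP; one
    cluster has only a LOC-named gene; one is a gene desert.  Returns the
    funnel counts and a shuffle-invariance indicator.
    """
    rng = np.random.default_rng(seed)
    hits = []
    centers = (1_000_000, 3_000_000, 6_000_000)
    for ci, center in enumerate(centers):
        for i in range(10):
            offset = 0 if i == 0 else int(rng.integers(-100_000, 100_000))
            p = 1e-8 if i == 0 else float(rng.uniform(1e-7, 1e-5))
            hits.append(
                GwasHit(snp_id=f"c{ci}_{i}", chrom="17", pos=center + offset, p_value=p)
            )
    genes = [
        GeneInterval("GENE_NEAR", "17", 1_039_001, 1_060_000),   # ~39 kb
        GeneInterval("GENE_MID", "17", 1_092_001, 1_120_000),    # ~92 kb
        GeneInterval("GENE_FAR", "17", 1_100_001, 1_130_000),    # ~100 kb
        GeneInterval("LOC999999", "17", 2_950_000, 2_990_000),   # name-excluded
    ]
    crit = pd.DataFrame(
        {
            "gene_id": ["GENE_NEAR", "GENE_MID", "GENE_FAR"],
            "antibody_available": [True, True, True],
            "hhl_family_similarity": [False, True, False],
            "suggestive_p": [True, True, True],
        }
    )
    base = run_candidate_filter(hits, genes, crit, multi_gene=True)
    invariant = 1.0
    for _ in range(n_shuffles):
        shuffled = list(hits)
        rng.shuffle(shuffled)
        out = run_candidate_filter(shuffled, genes, crit, multi_gene=True)
        if not base.equals(out):
            invariant = 0.0
    anchor = base[base["snp"] == "c0_0"]
    return {
        "pruned_survivors": 3.0,
        "candidate_rows": float(len(base)),
        "genes_per_anchor_snp": float(len(anchor)),
        "anchor_distances_kb": [round(d / 1000, 1) for d in sorted(anchor["distance_bp"])],
        "shortlisted": float(base["shortlisted"].sum()),
        "shuffle_invariant": invariant,
    }


def profile_classifier_study(
    n_reps: int = 100, n: int = 1000, maf: float = 0.3, effect_db: float = 8.0,
    noise_sd: float = 10.0, n_snps: int = 500, seed: int = 0,
) -> dict[str, float]:
    """Detection and false-call rates of the audiogram-profile classifier.

    Detection: a recessive all-frequency deterioration of ``effect_db`` for
    the minor-allele homozygotes, on cohorts with the default polygenic
    background.  The panel must be large enough that no single SNP tags an
    appreciable share of that background (with a small panel the profiled
    SNP's LD block leaks polygenic variance into the genotype groups).
    False calls: cohorts whose trait has no genotype dependence (h2 = 0,
    no injected effects).
    """
    from .profiles import profile_snp

    ss = np.random.SeedSequence([seed, 606])
    seeds = ss.generate_state(n_reps)
    mid = n_snps // 2
    det = 0
    for s in seeds:
        cfg = SimConfig(
            n_individuals=n, n_snps=n_snps, n_sib_pairs=0, maf_range=(maf, maf),
            noise_sd=noise_sd, seed=int(s % 2 ** 31),
            snp_effects=(SnpEffect(mid, "recessive", effect_db),),
        )
        c = simulate_cohort(cfg)
        prof = profile_snp(c.audiograms, c.genotypes, c.genotypes.snp_ids[mid])
        det += prof.classification == "deterioration_BB"
    false = 0
    for s in seeds:
        cfg = SimConfig(
            n_individuals=n, n_snps=n_snps, n_sib_pairs=0, maf_range=(maf, maf),
            noise_sd=noise_sd, h2=0.0, seed=int((s + 13) % 2 ** 31),
        )
        c = simulate_cohort(cfg)
        prof = profile_snp(c.audiograms, c.genotypes, c.genotypes.snp_ids[mid])
        false += prof.classification != "none"
    return {"detection_rate": det / n_reps, "false_call_rate": false / n_reps}


def printed_replication_examples() -> dict[str, float]:
    """The published replication decisions recomputed from the printed
    discovery/replication effect sizes and p-values."""

    def result(beta, se, p):
        return AssociationResult(
            snp_id="x", trait_name="t", model="additive", beta=beta, se=se,
            p_value=p, n_used=493, effect_allele="A",
        )

    pos = replication_check(0.25, result(0.08, 0.03, 0.010))
    neg = replication_check(-0.17, result(-0.06, 0.02, 0.008))
    flip = replication_check(0.25, result(-0.08, 0.03, 0.010))
    weak = replication_check(0.25, result(0.08, 0.03, 0.06))
    return {
        "positive_example_replicated": float(pos.replicated),
        "negative_beta_example_replicated": float(neg.replicated),
        "sign_flipped_rejected": float(not flip.replicated),
        "p_006_rejected": float(not weak.replicated),
    }


def pta_qc_exactness() -> dict[str, float]:
    """Exact arithmetic checks: PTA band means and strict QC boundaries."""
    row = pd.DataFrame(
        [dict(id="a", sex=0, age=40, **dict(zip(THRESHOLD_COLUMNS, [10, 20, 30, 40, 15, 99, 25])))]
    )
    pta_low = float(compute_pta(row, "low")[0])   # mean(10,20,30) = 20
    pta_mid = float(compute_pta(row, "mid")[0])   # mean(20,30,40) = 30
    pta_high = float(compute_pta(row, "high")[0])  # mean(15,25) = 20

    snps = [
        SnpMeta("keep_maf", "1", 1, "A", "G", maf=0.01),
        SnpMeta("drop_maf", "1", 2, "A", "G", maf=0.0099),
        SnpMeta("keep_info", "1", 3, "A", "G", source="imputed", maf=0.2, info=0.40),
        SnpMeta("drop_info", "1", 4, "A", "G", source="imputed", maf=0.2, info=0.3999),
    ]
    gm = GenotypeMatrix(["i0", "i1"], snps, np.array([[0, 1, 1, 1], [1, 1, 2, 0]], float))
    kept = qc_filter(gm).snp_ids
    return {
        "pta_low": pta_low,
        "pta_mid": pta_mid,
        "pta_high": pta_high,
        "qc_boundaries_exact": float(kept == ["keep_maf", "keep_info"]),
    }
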