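"""Synthetic replication-cohort generator.

Emulates a rural isolate cohort of ~500 adults with related individuals,
locally correlated SNP panels and correlated multi-frequency hearing
thresholds, so the full analysis chain (QC, trait derivation, kinship
adjustment, SNP and gene tests, audiogram profiles) can be exercised and
calibrated without access to real genotype data.

Genotypes: each individual carries two haplotypes; each haplotype is a
Gaussian-copula AR(1) latent vector thresholded against per-SNP allele
frequency quantiles, which yields hard calls in {0,1,2} with tunable local
LD (``ld_rho``) and a uniform MAF spectrum on ``maf_range``.  Sibling pairs
share each haplotype with probability 1/2, giving an expected kinship
coefficient of 1/4.

Audiograms: threshold(i, f) = baseline_f + age_i * slope_f + sex_i * sexeff_f
+ sum_k coded-genotype * effect_k + loading_f * factor_i + polygenic_{i,f}
+ noise.  The polygenic term is g = Z u over the simulated standardized
genotypes (u iid normal), i.e. multivariate normal with covariance
proportional to the realized genomic relationship matrix, scaled so that
h2 = s2_g / (s2_g + noise_sd^2) per frequency.  The single common factor
induces the strong inter-frequency correlation seen in real audiograms
(one dominant principal component).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix, SnpMeta, write_vcf
from . import genio

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SnpEffect", "SyntheticCohort", "simulate_genotypes",
           "simulate_audiograms", "simulate_cohort", "write_cohort"]

#: audiometric frequencies, kHz
FREQS_KHZ = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0)
N_FREQ = len(FREQS_KHZ)


class ConfigError(ValueError):
    """A simulation parameter is non-finite or out of range."""


@dataclass(frozen=True)
class SnpEffect:
    """An injected genotype effect on every frequency, in dB per coded unit.

    ``model`` follows the association coding: additive (0/1/2 effect-allele
    copies), dominant, recessive or overdominant.
    """

    snp_index: int
    model: str = "additive"
    effect: float = 0.0


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the replication setting: ~500 adults (ages 18-80,
    balanced sexes) from communities with related individuals (a quarter of
    the sample in sibling pairs), a locally correlated SNP panel, moderate
    polygenic background, age- and sex-dependent thresholds and one strong
    common factor across frequencies.
    """

    n_individuals: int = 500
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.8
    n_sib_pairs: int = 62
    baseline_curve: tuple[float, ...] = (5.0, 4.0, 4.0, 5.0, 8.0, 10.0, 12.0)
    age_slope_per_freq: tuple[float, ...] = (0.10, 0.10, 0.15, 0.25, 0.45, 0.55, 0.65)
    sex_effect_per_freq: tuple[float, ...] = (0.0, 0.0, 0.5, 1.0, 3.0, 4.0, 5.0)
    h2: float = 0.4
    shared_factor_loadings: tuple[float, ...] = (6.0,) * 7
    noise_sd: float = 3.0
    snp_effects: tuple[SnpEffect, ...] = ()
    seed: int = 0
    chrom: str = "1"
    spacing_bp: int = 5000

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ConfigError("counts must be positive")
        if self.n_sib_pairs < 0 or 2 * self.n_sib_pairs > self.n_individuals:
            raise ConfigError("n_sib_pairs must fit in the cohort")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ConfigError("ld_rho must be in [0, 1)")
        if not (0 <= self.h2 < 1):
            raise ConfigError("h2 must be in [0, 1)")
        for name in ("baseline_curve", "age_slope_per_freq",
                     "sex_effect_per_freq", "shared_factor_loadings"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_FREQ,):
                raise ConfigError(f"{name} needs {N_FREQ} entries")
            if not np.all(np.isfinite(v)):
                raise ConfigError(f"{name} contains non-finite values")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ConfigError("noise_sd must be finite and >= 0")
        for e in self.snp_effects:
            if not (0 <= e.snp_index < self.n_snps):
                raise ConfigError(f"snp_effects index {e.snp_index} out of range")
            if e.model not in ("additive", "dominant", "recessive", "overdominant"):
                raise ConfigError(f"unknown genetic model {e.model!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snp_effects"] = [asdict(e) for e in self.snp_effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["snp_effects"] = tuple(SnpEffect(**e) for e in d.get("snp_effects", ()))
        for k in ("maf_range", "baseline_curve", "age_slope_per_freq",
                  "sex_effect_per_freq", "shared_factor_loadings"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    audiograms: pd.DataFrame  # columns: id, sex, age, thr_250 ... thr_8000
    pedigree: list[tuple[str, str]]
    true_params: SimConfig


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _ar1_normals(rng: np.random.Generator, n_rows: int, n_snps: int, rho: float) -> np.ndarray:
    """Rows of AR(1) standard normals with lag-1 correlation rho."""
    z = rng.standard_normal((n_rows, n_snps))
    if rho > 0:
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, n_snps):
            z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
    return z


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Hard-call genotypes with AR(1) local LD and sibling-pair relatedness.

    Deterministic for a fixed config (seeded); sample MAF is written into the
    SNP metadata.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)  # effect-allele frequency per SNP
    cut = stats.norm.ppf(p)

    # two haplotypes per individual
    hap = np.empty((2, n, m), dtype=np.int8)
    for h in range(2):
        z = _ar1_normals(rng, n, m, config.ld_rho)
        hap[h] = (z < cut).astype(np.int8)

    # sibling pairs occupy the first 2*n_sib_pairs slots: (0,1), (2,3), ...
    pedigree: list[tuple[int, int]] = []
    for k in range(config.n_sib_pairs):
        a, b = 2 * k, 2 * k + 1
        pedigree.append((a, b))
        for h in range(2):
            if rng.random() < 0.5:
                hap[h, b] = hap[h, a]
    dosage = hap.sum(axis=0).astype(float)

    ids = [f"ind{i:04d}" for i in range(n)]
    snps = []
    maf_sample = np.minimum(dosage.mean(axis=0) / 2.0, 1 - dosage.mean(axis=0) / 2.0)
    for j in range(m):
        snps.append(
            SnpMeta(
                snp_id=f"snp{j:05d}",
                chrom=config.chrom,
                pos=(j + 1) * config.spacing_bp,
                effect_allele="A",
                other_allele="G",
                strand="+",
                source="genotyped",
                maf=float(maf_sample[j]),
            )
        )
    gm = GenotypeMatrix(ids, snps, dosage)
    gm._pedigree_idx = pedigree  # kept for simulate_cohort; ids below
    return gm


# ---------------------------------------------------------------------------
# audiograms
# ---------------------------------------------------------------------------

def _coded(dosage_col: np.ndarray, model: str) -> np.ndarray:
    g = np.where(dosage_col < 0.5, 0.0, np.where(dosage_col > 1.5, 2.0, 1.0))
    if model == "additive":
        return dosage_col
    if model == "dominant":
        return (g >= 1).astype(float)
    if model == "recessive":
        return (g == 2).astype(float)
    return (g == 1).astype(float)  # overdominant


def simulate_audiograms(
    genotypes: GenotypeMatrix,
    pedigree: Sequence[tuple[str, str]],
    config: SimConfig,
) -> pd.DataFrame:
    """Per-individual thresholds at the 7 frequencies plus sex and age.

    Returns a DataFrame with columns id, sex, age, thr_250 ... thr_8000.
    The polygenic term is built from the genotypes themselves (independent
    draws per frequency), so its covariance is h2-scaled twice-genomic-kinship.
    """
    ped_ids = {i for pair in pedigree for i in pair}
    if not ped_ids.issubset(set(genotypes.individual_ids)):
        raise genio.InputError("pedigree ids not all present in genotype matrix")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_001]))
    n = genotypes.n_individuals
    ages = rng.uniform(18.0, 80.0, size=n)
    sexes = rng.integers(0, 2, size=n).astype(float)

    base = np.asarray(config.baseline_curve, dtype=float)
    slope = np.asarray(config.age_slope_per_freq, dtype=float)
    sexeff = np.asarray(config.sex_effect_per_freq, dtype=float)
    load = np.asarray(config.shared_factor_loadings, dtype=float)

    thr = (
        base[None, :]
        + ages[:, None] * slope[None, :]
        + sexes[:, None] * sexeff[None, :]
    )

    for eff in config.snp_effects:
        c = _coded(genotypes.dosage[:, eff.snp_index], eff.model)
        thr += np.outer(c, np.full(N_FREQ, eff.effect))

    factor = rng.standard_normal(n)
    thr += np.outer(factor, load)

    if config.h2 > 0:
        # polygenic: Z u per frequency, Z = standardized dosages
        p = genotypes.dosage.mean(axis=0) / 2.0
        ok = (p > 0) & (p < 1)
        Z = (genotypes.dosage[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        mm = Z.shape[1]
        sg = config.noise_sd * np.sqrt(config.h2 / (1.0 - config.h2))
        u = rng.standard_normal((mm, N_FREQ)) * (sg / np.sqrt(mm))
        thr += Z @ u

    if config.noise_sd > 0:
        thr += rng.standard_normal((n, N_FREQ)) * config.noise_sd

    cols = {"id": genotypes.individual_ids, "sex": sexes.astype(int), "age": ages}
    for k, f in enumerate(FREQS_KHZ):
        cols[f"thr_{int(f * 1000)}"] = thr[:, k]
    return pd.DataFrame(cols)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Genotypes + audiograms + pedigree from one config and seed."""
    gm = simulate_genotypes(config)
    ped = [
        (gm.individual_ids[a], gm.individual_ids[b])
        for a, b in getattr(gm, "_pedigree_idx", [])
    ]
    audio = simulate_audiograms(gm, ped, config)
    return SyntheticCohort(genotypes=gm, audiograms=audio, pedigree=ped, true_params=config)


def write_cohort(cohort: SyntheticCohort, out_prefix: str | Path) -> dict[str, str]:
    """Write VCF + phenotype TSV + pedigree TSV + true-parameter JSON."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": f"{out_prefix}.vcf",
        "pheno": f"{out_prefix}.pheno.tsv",
        "pedigree": f"{out_prefix}.pedigree.tsv",
        "params": f"{out_prefix}.params.json",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    cohort.audiograms.to_csv(paths["pheno"], sep="\t", index=False, float_format="%.6f")
    with open(paths["pedigree"], "w") as fh:
        fh.write("id1\tid2\n")
        for a, b in cohort.pedigree:
            fh.write(f"{a}\t{b}\n")
    with open(paths["params"], "w") as fh:
        json.dump(cohort.true_params.to_dict(), fh, indent=2)
    return paths
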