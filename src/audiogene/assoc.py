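"""Per-SNP association under four genetic models and the replication rule.

Each test regresses the kinship/sex/age-adjusted trait residuals on a coded
genotype vector and divides the resulting statistic by the GRAMMAR-gamma
calibration factor.  Codings: additive uses the raw dosage (0..2 effect
allele copies); dominant, recessive and overdominant first hard-call the
dosage (thresholds 0.5 / 1.5) and then code carrier status, minor-homozygote
status or heterozygote status respectively.

A discovery hit is declared replicated when the replication effect has the
same sign as the discovery effect and the replication p-value is below the
nominal level (default 5%); no multiplicity correction is applied across
the four genetic models, which are not independent tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix, InputError
from .mixed import AdjustedTrait

logger = logging.getLogger(__name__)

__all__ = [
    "GENETIC_MODELS",
    "AssociationResult",
    "ReplicationDecision",
    "encode_genetic_model",
    "snp_test",
    "test_snp_panel",
    "replication_check",
]

GENETIC_MODELS = ("additive", "dominant", "recessive", "overdominant")

#: binary codings with a non-reference cell smaller than this are flagged
LOW_CONFIDENCE_CELL = 10


@dataclass
class AssociationResult:
    snp_id: str
    trait_name: str
    model: str
    beta: float
    se: float
    p_value: float
    n_used: int
    effect_allele: str
    maf: float | None = None
    untestable: bool = False
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise InputError(f"p-value {self.p_value} outside (0, 1]")


@dataclass
class ReplicationDecision:
    snp_id: str
    discovery_beta: float
    replication_beta: float
    replication_p: float
    same_direction: bool
    replicated: bool
    alpha: float = 0.05


def encode_genetic_model(dosage: np.ndarray, model: str) -> np.ndarray:
    """Code a dosage vector under a genetic model; NaN propagates.

    Non-additive models act on hard-call classes (dosage < 0.5 -> 0,
    0.5..1.5 -> 1, > 1.5 -> 2).
    """
    if model not in GENETIC_MODELS:
        raise InputError(f"unknown genetic model {model!r}")
    d = np.asarray(dosage, dtype=float)
    finite = d[np.isfinite(d)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise InputError("dosages outside [0, 2]")
    if model == "additive":
        return d.copy()
    g = np.where(d < 0.5, 0.0, np.where(d > 1.5, 2.0, 1.0))
    g = np.where(np.isfinite(d), g, np.nan)
    if model == "dominant":
        return np.where(np.isnan(g), np.nan, (g >= 1).astype(float))
    if model == "recessive":
        return np.where(np.isnan(g), np.nan, (g == 2).astype(float))
    return np.where(np.isnan(g), np.nan, (g == 1).astype(float))  # overdominant


def snp_test(
    adj: AdjustedTrait,
    coded: np.ndarray,
    snp_id: str = "?",
    model: str = "additive",
    effect_allele: str = "?",
    maf: float | None = None,
    use_t: bool = False,
) -> AssociationResult:
    """Regression/score test of adjusted residuals on one coded genotype.

    Missing genotypes are dropped (complete cases per test).  The naive
    regression z statistic is divided by sqrt(gamma) and the naive beta by
    gamma; p-values use the large-sample normal reference by default
    (``use_t`` switches to the t reference with n-2 df).
    """
    c = np.asarray(coded, dtype=float)
    r = adj.residuals
    if c.size != r.size:
        raise InputError("coded vector and residuals differ in length")
    mask = np.isfinite(c)
    c, r = c[mask], r[mask]
    n = c.size
    var_c = float(np.var(c))
    if n < 3 or var_c == 0.0:
        logger.info("snp %s (%s): monomorphic/insufficient coding, untestable", snp_id, model)
        return AssociationResult(
            snp_id=snp_id, trait_name=adj.trait_name, model=model,
            beta=0.0, se=np.nan, p_value=1.0, n_used=n,
            effect_allele=effect_allele, maf=maf, untestable=True,
        )
    low_conf = False
    if model != "additive":
        n_alt = int(np.sum(c == 1))
        if min(n_alt, n - n_alt) < LOW_CONFIDENCE_CELL:
            low_conf = True

    cc = c - c.mean()
    rc = r - r.mean()
    sxx = float(cc @ cc)
    beta = float(cc @ rc) / sxx
    rss = float(rc @ rc) - beta * beta * sxx
    dof = n - 2
    sigma2 = max(rss, 0.0) / dof
    se = np.sqrt(sigma2 / sxx)
    gamma = adj.gamma_for(model)
    beta_c = beta / gamma
    se_c = se / np.sqrt(gamma)
    if se_c == 0.0:
        z = np.inf * np.sign(beta_c) if beta_c != 0 else 0.0
        p = np.nextafter(0, 1) if beta_c != 0 else 1.0
    else:
        z = beta_c / se_c
        p = 2.0 * (stats.t.sf(abs(z), dof) if use_t else stats.norm.sf(abs(z)))
        p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return AssociationResult(
        snp_id=snp_id, trait_name=adj.trait_name, model=model,
        beta=float(beta_c), se=float(se_c), p_value=float(p), n_used=n,
        effect_allele=effect_allele, maf=maf, low_confidence=low_conf,
    )


def test_snp_panel(
    adj: AdjustedTrait,
    gm: GenotypeMatrix,
    models: tuple[str, ...] = GENETIC_MODELS,
    use_t: bool = False,
) -> pd.DataFrame:
    """All SNPs x all requested models against one adjusted trait."""
    if list(gm.individual_ids) != list(adj.ids):
        raise InputError("genotype and adjusted-trait individual ids differ")
    rows = []
    maf = gm.computed_maf()
    for j, meta in enumerate(gm.snps):
        for model in models:
            coded = encode_genetic_model(gm.dosage[:, j], model)
            res = snp_test(
                adj, coded, snp_id=meta.snp_id, model=model,
                effect_allele=meta.effect_allele,
                maf=meta.maf if meta.maf is not None else float(maf[j]),
                use_t=use_t,
            )
            rows.append(
                {
                    "snp": res.snp_id, "trait": res.trait_name, "model": res.model,
                    "maf": res.maf, "beta": res.beta, "se": res.se,
                    "p": res.p_value, "n": res.n_used,
                    "effect_allele": res.effect_allele,
                    "strand": meta.strand, "source": meta.source,
                    "info": meta.info,
                    "untestable": res.untestable,
                    "low_confidence": res.low_confidence,
                }
            )
    return pd.DataFrame(rows)


def _alleles_match(a1: str, a2: str, b1: str, b2: str) -> str:
    """'same', 'flipped' or 'mismatch' for (effect, other) allele pairs."""
    if (a1, a2) == (b1, b2):
        return "same"
    if (a1, a2) == (b2, b1):
        return "flipped"
    return "mismatch"


def replication_check(
    discovery_beta: float,
    replication: AssociationResult,
    alpha: float = 0.05,
    discovery_effect_allele: str | None = None,
    discovery_other_allele: str | None = None,
    replication_other_allele: str | None = None,
) -> ReplicationDecision:
    """Nominal-significance replication with the effect-direction requirement.

    When discovery alleles are supplied, a swapped effect/other pair on the
    replication side is resolved by negating the replication beta; a true
    allele mismatch raises.  No correction across genetic models is applied.
    """
    rep_beta = replication.beta
    if discovery_effect_allele is not None:
        status = _alleles_match(
            discovery_effect_allele,
            discovery_other_allele or "?",
            replication.effect_allele,
            replication_other_allele or "?",
        )
        if status == "flipped":
            rep_beta = -rep_beta
        elif status == "mismatch":
            raise InputError(
                f"{replication.snp_id}: effect alleles irreconcilable "
                f"({discovery_effect_allele}/{discovery_other_allele} vs "
                f"{replication.effect_allele}/{replication_other_allele})"
            )
    same_dir = bool(np.sign(discovery_beta) == np.sign(rep_beta)) and rep_beta != 0
    replicated = bool(same_dir and replication.p_value < alpha and not replication.untestable)
    return ReplicationDecision(
        snp_id=replication.snp_id,
        discovery_beta=float(discovery_beta),
        replication_beta=float(rep_beta),
        replication_p=float(replication.p_value),
        same_direction=same_dir,
        replicated=replicated,
        alpha=alpha,
    )
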