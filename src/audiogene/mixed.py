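"""Genomic kinship, polygenic REML and GRAMMAR-gamma trait adjustment.

The association strategy is two-stage: fit the polygenic mixed model
``y = X b + g + e`` once per trait (X = intercept, sex, age; Var(g) =
s2_g K, Var(e) = s2_e I, K the genomic relationship matrix), subtract the
fixed effects and the BLUP of the polygenic effect, and hand the resulting
environmental residuals to fast per-SNP tests.  Because those residuals are
shrunken, the naive residual-regression score statistic is deflated; a
scalar calibration factor gamma (the average ratio of the naive to the
exact mixed-model score statistic over a panel of SNPs) restores nominal
type-I error, following the GRAMMAR-gamma strategy.

Kinship is the centered-and-scaled allele-sharing estimator
``K_ij = (1/M) sum_m (g_im - 2 p_m)(g_jm - 2 p_m) / (2 p_m (1 - p_m))``
(Astle-Balding / VanRaden form; diagonal ~= 1, full sibs ~= 0.5 on the
off-diagonal, i.e. twice the kinship coefficient).  Negative eigenvalues
are clipped to zero (bending) with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .genio import GenotypeMatrix, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "KinshipMatrix",
    "PolygenicFit",
    "AdjustedTrait",
    "genomic_kinship",
    "fit_polygenic",
    "grammar_adjust",
]

_H2_MAX = 0.99


class ComputationError(RuntimeError):
    pass


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix with its eigendecomposition.

    ``values`` is the (possibly bent) PSD matrix; ``eigvals``/``eigvecs``
    are cached for reuse across traits.
    """

    ids: list[str]
    values: np.ndarray
    eigvals: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    eigvecs: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if K.shape != (n, n):
            raise InputError(f"kinship shape {K.shape} does not match {n} ids")
        if not np.allclose(K, K.T, atol=1e-12):
            raise InputError("kinship matrix is not symmetric")
        if self.eigvals is None or self.eigvecs is None:
            if not np.any(K - np.diag(np.diagonal(K))):
                # diagonal (e.g. identity) kinship: trivial eigensystem
                self.eigvals = np.clip(np.diagonal(K).copy(), 0.0, None)
                self.eigvecs = np.eye(n)
                self.values = np.diag(self.eigvals)
                return
            evals, evecs = np.linalg.eigh(K)
            n_neg = int(np.sum(evals < -1e-10))
            if n_neg:
                logger.warning(
                    "bending kinship: clipping %d negative eigenvalues "
                    "(most negative %.3g) to 0", n_neg, evals.min(),
                )
            evals = np.clip(evals, 0.0, None)
            self.eigvals = evals
            self.eigvecs = evecs
            self.values = (evecs * evals) @ evecs.T

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, ids: list[str]) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])


def genomic_kinship(gm: GenotypeMatrix, min_snps_warn: int = 50) -> KinshipMatrix:
    """Genomic relationship matrix from dosages.

    Monomorphic SNPs are skipped with a warning; missing dosages are
    excluded pairwise (each pair is averaged over the SNPs where both
    individuals are observed).
    """
    if gm.n_snps < min_snps_warn:
        logger.warning(
            "genomic_kinship on only %d SNPs; estimates will be noisy", gm.n_snps
        )
    D = gm.dosage
    p = np.nanmean(D, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int(np.sum(~poly))
    if n_mono:
        logger.warning("genomic_kinship: skipping %d monomorphic SNPs", n_mono)
    if not np.any(poly):
        raise ComputationError("no polymorphic SNPs available for kinship")
    D = D[:, poly]
    p = p[poly]
    obs = np.isfinite(D)
    X = (D - 2 * p) / np.sqrt(2 * p * (1 - p))
    X = np.where(obs, X, 0.0)
    counts = obs.astype(float) @ obs.T.astype(float)
    if np.any(counts == 0):
        raise ComputationError("some individual pairs share no observed SNPs")
    K = (X @ X.T) / counts
    K = (K + K.T) / 2.0
    return KinshipMatrix(list(gm.individual_ids), K)


# ---------------------------------------------------------------------------
# REML polygenic fit
# ---------------------------------------------------------------------------

@dataclass
class PolygenicFit:
    """REML fit of the polygenic model for one trait."""

    h2_hat: float
    fixed_effects: dict[str, float]
    sigma2: float  # total variance s2_g + s2_e
    reml_loglik: float
    identifiable: bool
    covariate_names: list[str]
    # rotated-space context, reused by grammar_adjust
    _ctx: dict = field(default_factory=dict, repr=False)

    @property
    def sigma2_g(self) -> float:
        return self.h2_hat * self.sigma2

    @property
    def sigma2_e(self) -> float:
        return (1.0 - self.h2_hat) * self.sigma2


def _design(sex, age, n: int) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(n)]
    names = ["intercept"]
    if sex is not None:
        cols.append(np.asarray(sex, dtype=float))
        names.append("sex")
    if age is not None:
        cols.append(np.asarray(age, dtype=float))
        names.append("age")
    return np.column_stack(cols), names


def _reml_neg2ll(h2: float, ys: np.ndarray, Xs: np.ndarray, lam: np.ndarray):
    """-2 x profiled REML log-likelihood (up to a constant), plus the GLS fit."""
    n, p = Xs.shape
    w = h2 * lam + (1.0 - h2)
    Xw = Xs / w[:, None]
    XtWX = Xs.T @ Xw
    XtWy = Xw.T @ ys
    beta = np.linalg.solve(XtWX, XtWy)
    resid = ys - Xs @ beta
    rss = float(resid @ (resid / w))
    sigma2 = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(XtWX)
    neg2ll = (n - p) * np.log(sigma2) + float(np.sum(np.log(w))) + logdet_xx
    return neg2ll, beta, sigma2, resid, w


def fit_polygenic(
    trait: np.ndarray,
    sex: np.ndarray | None,
    age: np.ndarray | None,
    K: KinshipMatrix,
    h2_fixed: float | None = None,
) -> PolygenicFit:
    """REML estimate of heritability and fixed effects for one trait.

    The likelihood is profiled over the total variance and maximized in
    ``h2 = s2_g / (s2_g + s2_e)`` on [0, 0.99] by bounded scalar
    minimization (tolerance 1e-6) on the eigenbasis of K.  With ``h2_fixed``
    the ratio is pinned (e.g. 0 to collapse onto OLS).
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if n < 30:
        logger.warning("fit_polygenic on n=%d (< 30); estimates will be unstable", n)
    if K.n != n:
        raise InputError(f"kinship is {K.n}x{K.n} but trait has {n} entries")
    if not np.all(np.isfinite(y)):
        raise InputError("trait contains missing values; complete cases required")
    if float(np.var(y)) == 0.0:
        raise InputError("zero-variance trait")

    X, names = _design(sex, age, n)
    U, lam = K.eigvecs, K.eigvals
    ys = U.T @ y
    Xs = U.T @ X

    identifiable = bool(lam.max() - lam.min() > 1e-8)
    if h2_fixed is not None:
        h2 = float(h2_fixed)
    elif not identifiable:
        logger.warning(
            "kinship eigenvalues are constant (K ~ I): h2 is not identifiable; "
            "returning h2=0 (OLS fixed effects)"
        )
        h2 = 0.0
    else:
        res = optimize.minimize_scalar(
            lambda h: _reml_neg2ll(h, ys, Xs, lam)[0],
            bounds=(0.0, _H2_MAX),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success:  # pragma: no cover - bounded brent rarely fails
            raise ComputationError(f"REML optimization failed: {res.message}")
        h2 = float(res.x)

    neg2ll, beta, sigma2, resid_s, w = _reml_neg2ll(h2, ys, Xs, lam)
    fit = PolygenicFit(
        h2_hat=h2,
        fixed_effects=dict(zip(names, map(float, beta))),
        sigma2=float(sigma2),
        reml_loglik=-0.5 * neg2ll,
        identifiable=identifiable,
        covariate_names=names,
        _ctx={"U": U, "lam": lam, "w": w, "resid_s": resid_s, "n_fixed": X.shape[1]},
    )
    return fit


# ---------------------------------------------------------------------------
# GRAMMAR adjustment
# ---------------------------------------------------------------------------

@dataclass
class AdjustedTrait:
    """Environmental residuals of one trait plus test-calibration metadata."""

    ids: list[str]
    residuals: np.ndarray
    trait_name: str
    h2_hat: float
    fixed_effects: dict[str, float]
    gamma: float
    sigma2: float
    s_r2: float  # residual variance used by the naive score statistic
    gammas: dict[str, float] = field(default_factory=dict)  # per genetic model

    def gamma_for(self, model: str) -> float:
        return self.gammas.get(model, self.gamma)

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_hat <= 1.0):
            raise InputError("h2_hat outside [0, 1]")
        if len(self.ids) != self.residuals.size:
            raise InputError("residual length does not match id list")


def _code_panel(G: np.ndarray, model: str) -> np.ndarray:
    """Genetic-model coding of a dosage panel (NaN preserved)."""
    if model == "additive":
        return G
    cls = np.where(G < 0.5, 0.0, np.where(G > 1.5, 2.0, 1.0))
    cls = np.where(np.isfinite(G), cls, np.nan)
    if model == "dominant":
        return (cls >= 1).astype(float)
    if model == "recessive":
        return (cls == 2).astype(float)
    return (cls == 1).astype(float)  # overdominant


def _gamma_from_panel(
    G: np.ndarray, U: np.ndarray, w: np.ndarray, h2: float,
    sigma2: float, s_r2: float, model: str = "additive", max_snps: int = 1000,
) -> float:
    """Mean over SNPs of T_naive / T_exact for the score test of one coding.

    Per centered coded SNP g:  T_exact uses g' V0^-1 g, T_naive uses g' g
    and the empirical residual variance; the ratio is free of the phenotype
    draw.  The ratio depends on how the coded vector aligns with the
    kinship eigenstructure, so each genetic model gets its own scalar.
    """
    m = G.shape[1]
    if m > max_snps:
        idx = np.linspace(0, m - 1, max_snps).astype(int)
        G = G[:, idx]
    G = _code_panel(G, model)
    Gc = G - np.nanmean(G, axis=0)
    Gc = np.where(np.isfinite(Gc), Gc, 0.0)
    B = U.T @ Gc
    a = np.einsum("ij,ij->j", B, B / w[:, None])  # g' V0^-1 g
    b = np.einsum("ij,ij->j", B, B)  # g' g
    ok = b > 1e-12
    if not np.any(ok):
        logger.warning("gamma panel had no polymorphic SNPs under %s coding; gamma = 1", model)
        return 1.0
    ratios = (1.0 - h2) ** 2 * sigma2 * a[ok] / (b[ok] * s_r2)
    return float(np.mean(ratios))


def grammar_adjust(
    trait: np.ndarray,
    sex: np.ndarray | None,
    age: np.ndarray | None,
    K: KinshipMatrix,
    genotypes: GenotypeMatrix | None = None,
    trait_name: str = "trait",
    h2_fixed: float | None = None,
    fit: PolygenicFit | None = None,
) -> AdjustedTrait:
    """Residuals after removing fixed effects and the polygenic BLUP.

    ``residuals = y - X bhat - ghat`` with ``ghat`` the BLUP of the polygenic
    effect.  The gamma calibration factor is estimated from up to 1000 SNPs
    of ``genotypes`` when given, otherwise from the trace form
    ``tr(V0^-1 K) / tr(K)`` (equivalent to averaging over the SNPs that built
    K).  With h2 = 0 the residuals are exactly the OLS residuals and
    gamma = 1.
    """
    if fit is None:
        fit = fit_polygenic(trait, sex, age, K, h2_fixed=h2_fixed)
    ctx = fit._ctx
    U, lam, w, resid_s = ctx["U"], ctx["lam"], ctx["w"], ctx["resid_s"]
    h2 = fit.h2_hat
    # r = (1-h2) V0^-1 (y - X bhat), computed in the eigenbasis
    resid = U @ ((1.0 - h2) * resid_s / w)
    n_fixed = ctx["n_fixed"]
    s_r2 = float(resid @ resid) / (resid.size - n_fixed)
    if s_r2 <= 0:
        raise ComputationError("degenerate residual variance")

    gammas: dict[str, float] = {}
    if genotypes is not None:
        if list(genotypes.individual_ids) != list(K.ids):
            raise InputError("genotype and kinship individual ids differ")
        for model in ("additive", "dominant", "recessive", "overdominant"):
            gammas[model] = _gamma_from_panel(
                genotypes.dosage, U, w, h2, fit.sigma2, s_r2, model=model
            )
        gamma = gammas["additive"]
    else:
        tr_vk = float(np.sum(lam / w))
        tr_k = float(np.sum(lam))
        gamma = (
            (1.0 - h2) ** 2 * fit.sigma2 * tr_vk / (tr_k * s_r2)
            if tr_k > 0 else 1.0
        )
    logger.info(
        "grammar_adjust[%s]: h2=%.4f gamma=%.4f sigma2=%.4f",
        trait_name, h2, gamma, fit.sigma2,
    )
    return AdjustedTrait(
        ids=list(K.ids),
        residuals=resid,
        trait_name=trait_name,
        h2_hat=h2,
        fixed_effects=fit.fixed_effects,
        gamma=float(gamma),
        sigma2=fit.sigma2,
        s_r2=s_r2,
        gammas=gammas,
    )


def adjusted_trait_frame(adj: AdjustedTrait) -> pd.DataFrame:
    return pd.DataFrame({"id": adj.ids, adj.trait_name: adj.residuals})
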