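"""Audiometric endophenotypes: single frequencies, pure-tone averages and
threshold principal components.

Thirteen traits are derived per individual from the 7-frequency audiogram:
the 7 raw thresholds, three pure-tone averages (low = 0.25/0.5/1 kHz,
mid = 0.5/1/2 kHz, high = 4/8 kHz) and the scores of the first three
principal components of all frequencies combined.  The PCA is run on the
covariance matrix of the raw thresholds (dB scale preserved), before any
covariate adjustment; component signs are fixed so every loading vector has
non-negative sum, making higher PC1 correspond to worse hearing in typical
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FREQS_KHZ

logger = logging.getLogger(__name__)

__all__ = [
    "PTA_BANDS",
    "TRAIT_NAMES",
    "THRESHOLD_COLUMNS",
    "compute_pta",
    "compute_trait_pcs",
    "derive_all_traits",
    "DerivedTraits",
]

#: frequency sets (kHz) of the three pure-tone averages
PTA_BANDS: dict[str, tuple[float, ...]] = {
    "low": (0.25, 0.5, 1.0),
    "mid": (0.5, 1.0, 2.0),
    "high": (4.0, 8.0),
}

THRESHOLD_COLUMNS = [f"thr_{int(f * 1000)}" for f in FREQS_KHZ]

#: the 13 association traits, in canonical order
TRAIT_NAMES = THRESHOLD_COLUMNS + ["pta_low", "pta_mid", "pta_high", "pc1", "pc2", "pc3"]


class TraitError(ValueError):
    pass


@dataclass
class DerivedTraits:
    """13 derived traits per individual plus the threshold-PCA spectrum."""

    table: pd.DataFrame  # id, sex, age + the 13 trait columns
    variance_fractions: np.ndarray  # 7 eigenvalue fractions, non-increasing
    loadings: np.ndarray  # 7 x 3, sign-fixed


def _threshold_matrix(audiograms: pd.DataFrame) -> np.ndarray:
    missing = [c for c in THRESHOLD_COLUMNS if c not in audiograms.columns]
    if missing:
        raise TraitError(f"audiogram table lacks threshold columns {missing}")
    X = audiograms[THRESHOLD_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise TraitError("audiogram thresholds contain missing/non-finite values")
    return X


def compute_pta(thresholds: pd.DataFrame | np.ndarray, band: str) -> np.ndarray:
    """Unweighted mean threshold over the band's frequencies, in dB.

    ``thresholds`` is either the audiogram table (with thr_* columns) or a
    bare (n, 7) array in canonical frequency order.
    """
    if band not in PTA_BANDS:
        raise TraitError(f"unknown PTA band {band!r}; expected one of {list(PTA_BANDS)}")
    if isinstance(thresholds, pd.DataFrame):
        X = _threshold_matrix(thresholds)
    else:
        X = np.atleast_2d(np.asarray(thresholds, dtype=float))
        if X.shape[1] != len(FREQS_KHZ):
            raise TraitError(f"expected {len(FREQS_KHZ)} frequency columns")
    idx = [FREQS_KHZ.index(f) for f in PTA_BANDS[band]]
    return X[:, idx].mean(axis=1)


def compute_trait_pcs(
    audiograms: pd.DataFrame, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the 7 threshold columns on their covariance matrix.

    Returns ``(scores, variance_fractions, loadings)``: scores for the top
    ``n_components`` components (columns), the full 7-entry eigenvalue
    fraction vector (non-increasing, sums to 1) and the sign-fixed loading
    matrix (7 x n_components).  Signs are chosen so each loading sum is >= 0.
    """
    X = _threshold_matrix(audiograms)
    n = X.shape[0]
    if n < len(FREQS_KHZ) + 1:
        raise TraitError(f"need at least {len(FREQS_KHZ) + 1} complete audiograms, got {n}")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    if np.sum(evals > 0) < n_components:
        raise TraitError(
            f"covariance has fewer than {n_components} positive eigenvalues"
        )
    fractions = evals / evals.sum()
    load = evecs[:, :n_components].copy()
    flip = load.sum(axis=0) < 0
    load[:, flip] *= -1.0
    scores = Xc @ load
    return scores, fractions, load


def derive_all_traits(audiograms: pd.DataFrame) -> DerivedTraits:
    """One row per individual with the 13 named trait columns."""
    if "id" not in audiograms.columns:
        raise TraitError("audiogram table needs an 'id' column")
    scores, fractions, load = compute_trait_pcs(audiograms)
    out = audiograms[[c for c in ("id", "sex", "age") if c in audiograms.columns]].copy()
    X = _threshold_matrix(audiograms)
    for k, c in enumerate(THRESHOLD_COLUMNS):
        out[c] = X[:, k]
    for band in ("low", "mid", "high"):
        out[f"pta_{band}"] = compute_pta(audiograms, band)
    for k in range(3):
        out[f"pc{k + 1}"] = scores[:, k]
    return DerivedTraits(table=out, variance_fractions=fractions, loadings=load)
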