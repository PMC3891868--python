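import numpy as np
import pytest

from audiogene.cohort import SimConfig, simulate_cohort
from audiogene.mixed import KinshipMatrix, grammar_adjust


@pytest.fixture(scope="session")
def small_cohort():
    """200 adults, 150 SNPs, 20 sibling pairs — shared across read-only tests."""
    cfg = SimConfig(n_individuals=200, n_snps=150, n_sib_pairs=20, seed=1234)
    return simulate_cohort(cfg)


@pytest.fixture()
def identity_adjust():
    """Adjust a trait with K = I (h2 pinned at 0 -> plain OLS residuals)."""

    def _adjust(audio, trait_col, genotypes=None):
        n = len(audio)
        K = KinshipMatrix(list(audio["id"]), np.eye(n))
        return grammar_adjust(
            audio[trait_col].to_numpy(float),
            audio["sex"].to_numpy(float),
            audio["age"].to_numpy(float),
            K,
            genotypes=genotypes,
            trait_name=trait_col,
        )

    return _adjust
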