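"""Gene-based association test on genotype principal components.

Four steps per gene and trait: (1) the trait is adjusted for sex, age and
genomic kinship upstream (``mixed.grammar_adjust``); (2) only intragenic
SNPs (1-based inclusive gene interval) are kept; (3) PCA is run on the
individual x SNP matrix of genotypes hard-called to 0/1/2, and components
explaining strictly more than 1/N of the variance are selected (N = number
of intragenic SNPs); (4) the adjusted trait is regressed jointly on the
selected PC scores and the overall F test of the regression gives the
gene-level p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genio import GenotypeMatrix, GeneInterval, InputError
from .mixed import AdjustedTrait, ComputationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneTestResult",
    "select_intragenic_snps",
    "genotype_pcs",
    "select_pcs",
    "gene_based_test",
    "run_gene_test",
]


@dataclass
class GeneTestResult:
    gene_id: str
    trait_name: str
    total_n_snps: int
    n_selected_pcs: int
    variance_explained: float  # percent, sum of selected eigenvalue fractions
    p_value: float
    strand: str = "+"
    untestable: bool = False

    def __post_init__(self) -> None:
        if not self.untestable:
            if self.n_selected_pcs > self.total_n_snps:
                raise InputError("more selected PCs than SNPs")
            if not (0.0 < self.p_value <= 1.0):
                raise InputError(f"p-value {self.p_value} outside (0, 1]")


def select_intragenic_snps(gm: GenotypeMatrix, gene: GeneInterval) -> GenotypeMatrix:
    """SNPs with gene.start <= pos <= gene.end on the gene's chromosome,
    input order preserved.  An empty selection is returned as-is (flagged
    untestable downstream, not an exception)."""
    idx = [
        j for j, s in enumerate(gm.snps)
        if s.chrom == gene.chrom and gene.contains(s.pos)
    ]
    return gm.subset_snps(idx)


def genotype_pcs(
    sub: GenotypeMatrix, hard_call: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype submatrix; returns (scores, eigenvalue fractions).

    Genotypes are hard-called to 0/1/2 by default (``hard_call=False`` keeps
    raw dosages, for sensitivity analysis).  Columns are centered; fractions
    are non-increasing and sum to 1.  Missing genotypes are mean-imputed
    per SNP before the decomposition.
    """
    if sub.n_snps < 1:
        raise InputError("genotype_pcs needs at least one SNP")
    G = sub.hard_calls() if hard_call else sub.dosage.copy()
    col_mean = np.nanmean(G, axis=0)
    miss = ~np.isfinite(G)
    if miss.any():
        G[miss] = np.take(col_mean, np.nonzero(miss)[1])
    Gc = G - G.mean(axis=0)
    if not np.any(Gc):
        raise ComputationError("all-constant genotype submatrix")
    # SVD of the centered matrix = eigendecomposition of its covariance
    U, s, _ = np.linalg.svd(Gc, full_matrices=False)
    evals = s ** 2
    fractions = evals / evals.sum()
    scores = U * s
    return scores, fractions


def select_pcs(fractions: np.ndarray, N: int) -> list[int]:
    """Indices of PCs whose variance fraction is strictly > 1/N.

    If the strict rule selects nothing (degenerate spectra such as N = 1),
    PC1 is kept with a warning.
    """
    if N < 1:
        raise InputError("N must be >= 1")
    threshold = 1.0 / N
    selected = [k for k, f in enumerate(fractions) if f > threshold]
    if not selected:
        logger.warning(
            "1/N rule selected no PCs (N=%d, top fraction %.4f); keeping PC1",
            N, float(fractions[0]) if len(fractions) else float("nan"),
        )
        selected = [0]
    return selected


def gene_based_test(
    adj: AdjustedTrait,
    scores: np.ndarray,
    fractions: np.ndarray,
    selected: list[int],
    gene_id: str = "?",
    total_n_snps: int | None = None,
    strand: str = "+",
) -> GeneTestResult:
    """Joint F test of the adjusted trait on the selected PC scores."""
    y = adj.residuals
    S = scores[:, selected]
    n, k = S.shape
    if y.size != n:
        raise InputError("score matrix and residuals differ in length")
    if total_n_snps is None:
        total_n_snps = len(fractions)
    if n <= k + 1:
        logger.warning("gene %s: n=%d <= #PCs+1=%d, untestable", gene_id, n, k + 1)
        return GeneTestResult(
            gene_id=gene_id, trait_name=adj.trait_name,
            total_n_snps=total_n_snps, n_selected_pcs=k,
            variance_explained=float(100.0 * fractions[selected].sum()),
            p_value=1.0, strand=strand, untestable=True,
        )
    X = np.column_stack([np.ones(n), S])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    yc = y - y.mean()
    tss = float(yc @ yc)
    rss = float(((y - fitted) ** 2).sum())
    dof2 = n - k - 1
    if tss <= 0:
        raise InputError("zero-variance adjusted trait")
    f_stat = ((tss - rss) / k) / (rss / dof2)
    p = float(stats.f.sf(f_stat, k, dof2))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return GeneTestResult(
        gene_id=gene_id,
        trait_name=adj.trait_name,
        total_n_snps=int(total_n_snps),
        n_selected_pcs=k,
        variance_explained=float(100.0 * fractions[selected].sum()),
        p_value=p,
        strand=strand,
    )


def run_gene_test(
    adj: AdjustedTrait,
    gm: GenotypeMatrix,
    gene: GeneInterval,
    hard_call: bool = True,
) -> GeneTestResult:
    """The full 4-step test for one gene and one adjusted trait."""
    if list(gm.individual_ids) != list(adj.ids):
        raise InputError("genotype and adjusted-trait individual ids differ")
    sub = select_intragenic_snps(gm, gene)
    N = sub.n_snps
    if N == 0:
        logger.info("gene %s: no intragenic SNPs, untestable", gene.gene_id)
        return GeneTestResult(
            gene_id=gene.gene_id, trait_name=adj.trait_name,
            total_n_snps=0, n_selected_pcs=0, variance_explained=0.0,
            p_value=1.0, strand=gene.strand, untestable=True,
        )
    try:
        scores, fractions = genotype_pcs(sub, hard_call=hard_call)
    except ComputationError:
        logger.warning("gene %s: constant genotypes, untestable", gene.gene_id)
        return GeneTestResult(
            gene_id=gene.gene_id, trait_name=adj.trait_name,
            total_n_snps=N, n_selected_pcs=0, variance_explained=0.0,
            p_value=1.0, strand=gene.strand, untestable=True,
        )
    selected = select_pcs(fractions, N)
    return gene_based_test(
        adj, scores, fractions, selected,
        gene_id=gene.gene_id, total_n_snps=N, strand=gene.strand,
    )
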