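"""GWAS-hit-to-candidate-gene selection.

Reduces a list of suggestive discovery hits to a shortlist of candidate
genes in four stages mirroring the published funnel: (a) region pruning —
within +/-250 kb of every hit only the most significantly associated SNP
survives (greedy, best p first); (b) gene-desert removal — hits with no
annotated gene within the window are dropped; (c) name-based exclusion of
genes with unknown function (LOC*/FAM* designations) and a configurable
disease-exclusion list; (d) prioritization — a gene is shortlisted when an
antibody is available for expression work AND at least one further
criterion holds (highly suggestive p ~1e-7, similarity to hereditary
hearing-loss gene families, reported inner-ear expression, or a pathway
link).  Criteria flags are user-supplied inputs, not live database queries.

Every stage logs in/out counts so a full run reproduces the
683 -> 84 -> 19-style accounting of a real funnel.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field

import pandas as pd

from .genio import GeneInterval, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "GwasHit",
    "CandidateGene",
    "prune_regions",
    "annotate_and_filter",
    "prioritize",
    "run_candidate_filter",
    "DEFAULT_WINDOW",
    "DEFAULT_NAME_EXCLUSIONS",
]

DEFAULT_WINDOW = 250_000
DEFAULT_NAME_EXCLUSIONS = ("LOC*", "FAM*")

CRITERIA_FLAGS = (
    "antibody_available",
    "hhl_family_similarity",
    "suggestive_p",
    "highly_suggestive_p",
    "ear_expression_db",
    "pathway_link",
)


@dataclass(frozen=True)
class GwasHit:
    snp_id: str
    chrom: str
    pos: int
    p_value: float
    beta: float = 0.0
    effect_allele: str = "?"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise InputError(f"{self.snp_id}: p-value outside (0, 1]")


@dataclass
class CandidateGene:
    gene_id: str
    snp_id: str
    distance: int  # bp to nearest gene edge, 0 if intragenic
    criteria: dict[str, bool] = field(default_factory=dict)
    shortlisted: bool = False

    @property
    def intragenic(self) -> bool:
        return self.distance == 0


def prune_regions(hits: list[GwasHit], window: int = DEFAULT_WINDOW) -> list[GwasHit]:
    """Greedy region pruning: repeatedly keep the globally most significant
    remaining hit and discard every other hit within +/-window on its
    chromosome.  Ties on p break toward the smaller position, making the
    result independent of input order."""
    remaining = sorted(hits, key=lambda h: (h.p_value, h.chrom, h.pos, h.snp_id))
    survivors: list[GwasHit] = []
    while remaining:
        best = remaining.pop(0)
        survivors.append(best)
        remaining = [
            h for h in remaining
            if h.chrom != best.chrom or abs(h.pos - best.pos) > window
        ]
    survivors.sort(key=lambda h: (h.chrom, h.pos))
    logger.info("prune_regions: %d hits in, %d survivors", len(hits), len(survivors))
    return survivors


def _nearby_genes(
    hit: GwasHit, genes: list[GeneInterval], window: int
) -> list[tuple[GeneInterval, int]]:
    out = []
    for g in genes:
        if g.chrom != hit.chrom:
            continue
        d = g.distance_to(hit.pos)
        if d <= window:
            out.append((g, d))
    out.sort(key=lambda gd: (gd[1], gd[0].gene_id))
    return out


def _name_excluded(gene_id: str, patterns: tuple[str, ...]) -> bool:
    return any(fnmatch.fnmatch(gene_id.upper(), p.upper()) for p in patterns)


def annotate_and_filter(
    hits: list[GwasHit],
    genes: list[GeneInterval],
    window: int = DEFAULT_WINDOW,
    name_exclusions: tuple[str, ...] = DEFAULT_NAME_EXCLUSIONS,
    disease_exclusion_list: tuple[str, ...] = (),
    multi_gene: bool = False,
) -> list[CandidateGene]:
    """Assign genes to pruned hits and apply the exclusion filters.

    Hits with no annotated gene within +/-window are dropped as gene
    deserts.  Each survivor is assigned its closest gene (distance 0 when
    intragenic); with ``multi_gene=True`` every gene inside the window is
    kept, so one SNP can anchor several candidate rows.  Genes matching a
    name-exclusion pattern or listed in the disease-exclusion list are
    removed; a hit whose only nearby genes are excluded is dropped.
    """
    if not genes:
        raise InputError("empty gene annotation")
    excluded_names = {g.upper() for g in disease_exclusion_list}
    out: list[CandidateGene] = []
    n_desert = n_excluded_only = 0
    for hit in hits:
        near = _nearby_genes(hit, genes, window)
        if not near:
            n_desert += 1
            logger.info("hit %s: gene desert (no gene within %d bp)", hit.snp_id, window)
            continue
        keep = [
            (g, d) for g, d in near
            if not _name_excluded(g.gene_id, name_exclusions)
            and g.gene_id.upper() not in excluded_names
        ]
        if not keep:
            n_excluded_only += 1
            logger.info("hit %s: all nearby genes excluded by name/disease lists", hit.snp_id)
            continue
        chosen = keep if multi_gene else keep[:1]
        for g, d in chosen:
            out.append(CandidateGene(gene_id=g.gene_id, snp_id=hit.snp_id, distance=d))
    logger.info(
        "annotate_and_filter: %d hits in, %d gene deserts, %d fully excluded, "
        "%d candidate rows out",
        len(hits), n_desert, n_excluded_only, len(out),
    )
    return out


def prioritize(
    candidates: list[CandidateGene],
    criteria: pd.DataFrame,
    require_any_of: tuple[str, ...] = (
        "highly_suggestive_p",
        "hhl_family_similarity",
        "ear_expression_db",
        "pathway_link",
        "suggestive_p",
    ),
) -> list[CandidateGene]:
    """Shortlist candidates: antibody availability is the mandatory gate,
    plus at least one of the configured supporting criteria.

    ``criteria`` is a table with a ``gene_id`` column and boolean columns
    named after the criterion flags; genes absent from the table get all
    flags False.
    """
    if "gene_id" not in criteria.columns:
        raise InputError("criteria table needs a gene_id column")
    table = criteria.set_index("gene_id")
    for cand in candidates:
        flags = {f: False for f in CRITERIA_FLAGS}
        if cand.gene_id in table.index:
            row = table.loc[cand.gene_id]
            for f in CRITERIA_FLAGS:
                if f in table.columns:
                    flags[f] = bool(row[f])
        cand.criteria = flags
        cand.shortlisted = flags["antibody_available"] and any(
            flags[f] for f in require_any_of
        )
    n_short = sum(c.shortlisted for c in candidates)
    logger.info("prioritize: %d candidates in, %d shortlisted", len(candidates), n_short)
    return candidates


def run_candidate_filter(
    hits: list[GwasHit],
    genes: list[GeneInterval],
    criteria: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    name_exclusions: tuple[str, ...] = DEFAULT_NAME_EXCLUSIONS,
    disease_exclusion_list: tuple[str, ...] = (),
    multi_gene: bool = True,
) -> pd.DataFrame:
    """Full funnel: prune -> annotate/filter -> prioritize; returns a table
    mirroring the published candidate-gene listing."""
    pruned = prune_regions(hits, window=window)
    cands = annotate_and_filter(
        pruned, genes, window=window, name_exclusions=name_exclusions,
        disease_exclusion_list=disease_exclusion_list, multi_gene=multi_gene,
    )
    cands = prioritize(cands, criteria)
    rows = []
    for c in cands:
        row = {
            "snp": c.snp_id,
            "gene": c.gene_id,
            "distance_bp": c.distance,
            "intragenic": c.intragenic,
            "shortlisted": c.shortlisted,
        }
        row.update(c.criteria)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["snp", "distance_bp", "gene"]).reset_index(drop=True) if len(df) else df
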