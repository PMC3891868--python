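"""End-to-end orchestration: simulate/load -> QC -> traits -> kinship ->
adjustment -> SNP tests -> gene tests -> replication -> profiles.

One :class:`RunConfig` (usually parsed from YAML) drives the whole run.
Every stage writes its table under the output directory, logs in/out
counts, and the run ends with a manifest (versions, seed, input digests,
stage timings) plus a per-gene summary of the replication outcome.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import GENETIC_MODELS, test_snp_panel, replication_check, AssociationResult
from .candidates import DEFAULT_WINDOW, DEFAULT_NAME_EXCLUSIONS
from .cohort import SimConfig, simulate_cohort, write_cohort
from .genio import (
    InputError,
    load_gene_intervals,
    load_genotypes,
    load_phenotypes,
    qc_filter,
    write_kinship_tsv,
)
from .genetest import run_gene_test
from .mixed import genomic_kinship, grammar_adjust
from .profiles import profile_snp, plot_profile
from .traits import TRAIT_NAMES, derive_all_traits

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "audiogene_run"
    seed: int = 0
    # either a simulation block ...
    simulation: dict | None = None
    # ... or input paths
    genotypes: str | None = None
    genotype_format: str = "auto"
    phenotypes: str | None = None
    genes_bed: str | None = None
    discovery_hits: str | None = None  # TSV: snp, chrom, pos, p, beta, effect_allele
    criteria: str | None = None  # TSV with gene_id + criterion flags
    # analysis options
    traits: list[str] = field(default_factory=lambda: list(TRAIT_NAMES))
    models: list[str] = field(default_factory=lambda: list(GENETIC_MODELS))
    alpha: float = 0.05
    window: int = DEFAULT_WINDOW
    maf_min: float = 0.01
    info_min: float = 0.4
    name_exclusions: tuple[str, ...] = DEFAULT_NAME_EXCLUSIONS
    disease_exclusion_list: tuple[str, ...] = ()
    profile_snps: list[str] = field(default_factory=list)
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must be in (0, 1)")
        unknown = [t for t in self.traits if t not in TRAIT_NAMES]
        if unknown:
            raise InputError(f"unknown traits {unknown}; choose from {TRAIT_NAMES}")
        if self.simulation is None and (self.genotypes is None or self.phenotypes is None):
            raise InputError("config needs either a simulation block or genotype+phenotype paths")
        for attr in ("genotypes", "phenotypes", "genes_bed", "discovery_hits", "criteria"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise InputError(f"{attr} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "audiogene",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "outputs": {},
    }
    t_all = time.perf_counter()

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                manifest["stages"][name] = round(dt, 4)
                if exc is not None:
                    _write_manifest(manifest, out)
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Timer()

    # ---- inputs ---------------------------------------------------------
    with stage("load"):
        if config.simulation is not None:
            sim = dict(config.simulation)
            sim.setdefault("seed", config.seed)
            simcfg = SimConfig.from_dict(sim)
            cohort = simulate_cohort(simcfg)
            paths = write_cohort(cohort, out / "cohort")
            manifest["outputs"].update(paths)
            gm = cohort.genotypes
            pheno = cohort.audiograms
        else:
            gm = load_genotypes(config.genotypes, format=config.genotype_format)
            pheno = load_phenotypes(config.phenotypes)
            manifest["inputs"]["genotypes"] = _digest(config.genotypes)
            manifest["inputs"]["phenotypes"] = _digest(config.phenotypes)
        common = [i for i in gm.individual_ids if i in set(pheno["id"])]
        if len(common) < gm.n_individuals or len(common) < len(pheno):
            logger.warning(
                "restricting to %d individuals present in both genotype and phenotype tables",
                len(common),
            )
        gm = gm.subset_individuals(common)
        pheno = pheno.set_index("id").loc[common].reset_index()

    # ---- QC -------------------------------------------------------------
    with stage("qc"):
        n_before = gm.n_snps
        gm = qc_filter(gm, maf_min=config.maf_min, info_min=config.info_min)
        manifest["qc"] = {"snps_in": n_before, "snps_out": gm.n_snps}

    # ---- traits ---------------------------------------------------------
    with stage("derive_traits"):
        derived = derive_all_traits(pheno)
        derived.table.to_csv(out / "traits.tsv", sep="\t", index=False, float_format="%.6f")
        manifest["outputs"]["traits"] = str(out / "traits.tsv")
        manifest["pc_variance_fractions"] = [round(float(f), 6) for f in derived.variance_fractions]

    # ---- kinship --------------------------------------------------------
    with stage("kinship"):
        K = genomic_kinship(gm)
        write_kinship_tsv(K.ids, K.values, out / "kinship.tsv")
        manifest["outputs"]["kinship"] = str(out / "kinship.tsv")

    # ---- adjustment -----------------------------------------------------
    with stage("adjust"):
        sex = derived.table["sex"].to_numpy(dtype=float)
        age = derived.table["age"].to_numpy(dtype=float)
        adjusted = {}
        adj_frame = pd.DataFrame({"id": K.ids})
        h2_rows = []
        for t in config.traits:
            adj = grammar_adjust(
                derived.table[t].to_numpy(dtype=float), sex, age, K,
                genotypes=gm, trait_name=t,
            )
            adjusted[t] = adj
            adj_frame[t] = adj.residuals
            h2_rows.append({"trait": t, "h2_hat": adj.h2_hat, "gamma": adj.gamma})
        adj_frame.to_csv(out / "adjusted.tsv", sep="\t", index=False, float_format="%.6f")
        pd.DataFrame(h2_rows).to_csv(out / "polygenic.tsv", sep="\t", index=False, float_format="%.6f")
        manifest["outputs"]["adjusted"] = str(out / "adjusted.tsv")

    # ---- SNP tests ------------------------------------------------------
    with stage("assoc_snp"):
        frames = []
        for t in config.traits:
            frames.append(test_snp_panel(adjusted[t], gm, models=tuple(config.models)))
        snp_results = pd.concat(frames, ignore_index=True)
        snp_results.to_csv(out / "assoc_snp.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["outputs"]["assoc_snp"] = str(out / "assoc_snp.tsv")

    # ---- gene tests -----------------------------------------------------
    gene_results = pd.DataFrame()
    if config.genes_bed is not None:
        with stage("assoc_gene"):
            genes = load_gene_intervals(config.genes_bed)
            manifest["inputs"]["genes_bed"] = _digest(config.genes_bed)
            rows = []
            for gene in genes:
                for t in config.traits:
                    r = run_gene_test(adjusted[t], gm, gene)
                    rows.append(
                        {
                            "gene": r.gene_id, "total_n_snps": r.total_n_snps,
                            "n_selected_pcs": r.n_selected_pcs,
                            "variance_explained_pct": round(r.variance_explained, 4),
                            "p_value": r.p_value, "trait": r.trait_name,
                            "strand": r.strand, "untestable": r.untestable,
                        }
                    )
            gene_results = pd.DataFrame(rows)
            gene_results.to_csv(out / "assoc_gene.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["outputs"]["assoc_gene"] = str(out / "assoc_gene.tsv")

    # ---- replication ----------------------------------------------------
    repl = pd.DataFrame()
    if config.discovery_hits is not None:
        with stage("replication"):
            disc = pd.read_csv(config.discovery_hits, sep="\t", dtype={"snp": str})
            manifest["inputs"]["discovery_hits"] = _digest(config.discovery_hits)
            rows = []
            tested = snp_results[~snp_results["untestable"]]
            for _, d in disc.iterrows():
                sub = tested[tested["snp"] == d["snp"]]
                for _, r in sub.iterrows():
                    res = AssociationResult(
                        snp_id=r["snp"], trait_name=r["trait"], model=r["model"],
                        beta=r["beta"], se=r["se"], p_value=r["p"], n_used=int(r["n"]),
                        effect_allele=r["effect_allele"], maf=r["maf"],
                    )
                    dec = replication_check(float(d["beta"]), res, alpha=config.alpha)
                    rows.append(
                        {
                            "snp": dec.snp_id, "trait": r["trait"], "model": r["model"],
                            "discovery_beta": dec.discovery_beta,
                            "replication_beta": dec.replication_beta,
                            "replication_p": dec.replication_p,
                            "same_direction": dec.same_direction,
                            "replicated": dec.replicated,
                        }
                    )
            repl = pd.DataFrame(rows)
            repl.to_csv(out / "replication.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["outputs"]["replication"] = str(out / "replication.tsv")

    # ---- profiles -------------------------------------------------------
    if config.profile_snps:
        with stage("profiles"):
            frames = []
            classifications = {}
            for snp in config.profile_snps:
                prof = profile_snp(pheno, gm, snp)
                frames.append(prof.to_frame())
                classifications[snp] = prof.classification
                if config.make_plots:
                    plot_profile(prof, str(out / f"profile_{snp}.png"))
            pd.concat(frames, ignore_index=True).to_csv(
                out / "profiles.tsv", sep="\t", index=False, float_format="%.4f"
            )
            manifest["outputs"]["profiles"] = str(out / "profiles.tsv")
            manifest["profile_classifications"] = classifications

    # ---- summary --------------------------------------------------------
    with stage("summary"):
        summary: dict = {}
        if len(repl):
            by_snp = repl.groupby("snp")["replicated"].any()
            summary["snp_level_replicated"] = sorted(by_snp[by_snp].index.tolist())
        if len(gene_results):
            ok = gene_results[~gene_results["untestable"]]
            sig = ok[ok["p_value"] < config.alpha]
            summary["gene_level_replicated"] = sorted(sig["gene"].unique().tolist())
        manifest["summary"] = summary

    manifest["total_seconds"] = round(time.perf_counter() - t_all, 4)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
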