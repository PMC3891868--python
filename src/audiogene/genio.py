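"""Genotype, annotation and phenotype I/O plus post-imputation QC.

Genotypes live in a :class:`GenotypeMatrix`: an individuals x SNPs dosage
array (effect-allele copies in [0, 2], NaN = missing) with per-SNP metadata.
Hard calls come from the VCF ``GT`` field; imputed dosages from the ``DS``
field.  All coordinates are 1-based inclusive internally; BED input is
converted on read.  Alleles are taken to be reported on the forward strand of
the reference; the strand column is carried as metadata only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnpMeta",
    "GenotypeMatrix",
    "GeneInterval",
    "load_genotypes",
    "load_gene_intervals",
    "qc_filter",
    "write_vcf",
    "write_dosage_tsv",
    "load_phenotypes",
    "write_kinship_tsv",
    "load_kinship_tsv",
]


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class ParseError(InputError):
    """A file failed to parse; the message names the offending line."""


@dataclass
class SnpMeta:
    """Per-SNP metadata.

    ``maf`` is folded (<= 0.5).  ``info`` is the imputation quality score,
    present iff ``source == "imputed"``.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    strand: str = "+"
    source: str = "genotyped"
    maf: float | None = None
    info: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.snp_id}: strand must be '+' or '-'")
        if self.source not in ("genotyped", "imputed"):
            raise InputError(f"{self.snp_id}: source must be 'genotyped' or 'imputed'")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise InputError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")
        if self.source == "genotyped" and self.info is not None:
            raise InputError(f"{self.snp_id}: info score given for a genotyped SNP")


class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    Dosages count copies of the effect allele, in [0, 2]; NaN marks missing
    genotypes.  SNP ids must be unique.
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        snps: Sequence[SnpMeta],
        dosage: np.ndarray,
    ) -> None:
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(individual_ids), len(snps)):
            raise InputError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(individual_ids)} individuals x {len(snps)} SNPs"
            )
        finite = dosage[np.isfinite(dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise InputError("dosages must lie in [0, 2] (or be NaN)")
        ids = [str(i) for i in individual_ids]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate individual ids")
        snp_ids = [s.snp_id for s in snps]
        if len(set(snp_ids)) != len(snp_ids):
            dup = pd.Series(snp_ids).value_counts()
            raise InputError(f"duplicate SNP id: {dup.index[0]}")
        self.individual_ids: list[str] = ids
        self.snps: list[SnpMeta] = list(snps)
        self.dosage = dosage
        self._index = {s: i for i, s in enumerate(snp_ids)}

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in matrix") from None

    # -- derived quantities ----------------------------------------------
    def effect_allele_freq(self) -> np.ndarray:
        """Sample frequency of the effect allele per SNP (missing skipped)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def computed_maf(self) -> np.ndarray:
        """Folded minor-allele frequency per SNP from the sample."""
        p = self.effect_allele_freq()
        return np.minimum(p, 1.0 - p)

    def fill_maf_from_sample(self, overwrite: bool = False) -> None:
        maf = self.computed_maf()
        for j, s in enumerate(self.snps):
            if s.maf is None or overwrite:
                s.maf = float(maf[j])

    def hard_calls(self) -> np.ndarray:
        """Genotype classes 0/1/2 from dosages (thresholds 0.5 / 1.5)."""
        g = np.full_like(self.dosage, np.nan)
        m = np.isfinite(self.dosage)
        g[m] = np.where(
            self.dosage[m] < 0.5, 0.0, np.where(self.dosage[m] > 1.5, 2.0, 1.0)
        )
        return g

    # -- subsetting -------------------------------------------------------
    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            self.individual_ids,
            [self.snps[j] for j in idx],
            self.dosage[:, idx],
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.individual_ids)}
        rows = [pos[str(i)] for i in ids]
        return GenotypeMatrix(list(ids), self.snps, self.dosage[rows, :])

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_individuals} individuals, {self.n_snps} SNPs)"


@dataclass(frozen=True)
class GeneInterval:
    """Gene span, 1-based inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise InputError(f"{self.gene_id}: start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def distance_to(self, pos: int) -> int:
        """bp gap from a position to the nearest interval edge (0 if inside)."""
        if self.contains(pos):
            return 0
        return self.start - pos if pos < self.start else pos - self.end


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_genotypes(path: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from VCF or from a dosage TSV.

    VCF: hard calls from GT count effect-allele (= first ALT) copies;
    when a ``DS`` FORMAT field is present its dosages are used verbatim and
    the record is treated as imputed (INFO score from the ``INFO=`` or ``R2``
    INFO keys when present).  Multi-allelic records keep the first ALT; the
    rest are dropped with a warning.

    Dosage TSV: rows = individuals (first column ``id``), header = SNP ids;
    metadata comes from a sibling ``<stem>.snps.tsv`` file when present.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "dosage_tsv"
    if format == "vcf":
        return _load_vcf(path)
    if format == "dosage_tsv":
        return _load_dosage_tsv(path)
    raise InputError(f"unknown genotype format {format!r}")


def _load_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise InputError(f"no such file: {path}")
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snps: list[SnpMeta] = []
    cols: list[np.ndarray] = []
    seen: set[str] = set()
    for i, rec in enumerate(vcf):
        if not rec.ALT:
            logger.warning("skipping %s: no ALT allele", rec.ID)
            continue
        if len(rec.ALT) > 1:
            logger.warning(
                "multi-allelic record %s: keeping first ALT, dropping %d others",
                rec.ID, len(rec.ALT) - 1,
            )
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if snp_id in seen:
            raise InputError(f"duplicate SNP id {snp_id!r} in {path}")
        seen.add(snp_id)
        ds = None
        try:
            ds = rec.format("DS")
        except Exception:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
            source = "imputed"
            info = rec.INFO.get("INFO", rec.INFO.get("R2", None))
            info = float(info) if info is not None else None
        else:
            gt = np.asarray(rec.gt_types, dtype=float)  # 0=hom ref,1=het,3=hom alt,2=unknown
            col = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
            source = "genotyped"
            info = None
        maf_raw = rec.INFO.get("MAF", None)
        strand = rec.INFO.get("STR", "+")
        snps.append(
            SnpMeta(
                snp_id=snp_id,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                effect_allele=rec.ALT[0],
                other_allele=rec.REF,
                strand=str(strand),
                source=source,
                maf=float(maf_raw) if maf_raw is not None else None,
                info=info,
            )
        )
        cols.append(col)
    dosage = (
        np.column_stack(cols) if cols else np.empty((len(ids), 0))
    )
    gm = GenotypeMatrix(ids, snps, dosage)
    gm.fill_maf_from_sample()
    return gm


def _load_dosage_tsv(path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "id":
        raise ParseError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    ids = df["id"].tolist()
    snp_ids = list(df.columns[1:])
    dosage = df.iloc[:, 1:].to_numpy(dtype=float)

    meta_path = Path(str(path)[: -len(path.suffix)] + ".snps.tsv")
    meta: dict[str, SnpMeta] = {}
    if meta_path.exists():
        mdf = pd.read_csv(meta_path, sep="\t", dtype={"snp_id": str, "chrom": str})
        for _, r in mdf.iterrows():
            info = r.get("info")
            info = None if pd.isna(info) else float(info)
            maf = r.get("maf")
            maf = None if pd.isna(maf) else float(maf)
            meta[str(r["snp_id"])] = SnpMeta(
                snp_id=str(r["snp_id"]),
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                effect_allele=str(r["effect_allele"]),
                other_allele=str(r["other_allele"]),
                strand=str(r.get("strand", "+")),
                source=str(r.get("source", "genotyped")),
                maf=maf,
                info=info,
            )
    snps = []
    for j, s in enumerate(snp_ids):
        if s in meta:
            snps.append(meta[s])
        else:
            snps.append(
                SnpMeta(snp_id=s, chrom="0", pos=j + 1, effect_allele="A", other_allele="B")
            )
    gm = GenotypeMatrix(ids, snps, dosage)
    gm.fill_maf_from_sample()
    return gm


def load_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Read gene spans from BED (>= 4 columns), converting the half-open
    0-based BED convention to 1-based inclusive.  File order is preserved."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    out: list[GeneInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = re.split(r"\s+", line.strip())
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: BED needs >= 4 columns")
            chrom, start0, end0, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "+"
            try:
                start0_i, end0_i = int(start0), int(end0)
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from None
            if end0_i <= start0_i:
                raise InputError(f"{path}:{ln}: zero- or negative-length interval")
            out.append(
                GeneInterval(gene_id=name, chrom=chrom, start=start0_i + 1, end=end0_i, strand=strand)
            )
    return out


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype TSV (id, sex, age, thr_250 ... thr_8000)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = ["id", "sex", "age"] + [f"thr_{f}" for f in (250, 500, 1000, 2000, 4000, 6000, 8000)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing phenotype columns {missing}")
    return df


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    gm: GenotypeMatrix, maf_min: float = 0.01, info_min: float = 0.4
) -> GenotypeMatrix:
    """Apply the post-imputation exclusion filters.

    SNPs with MAF strictly below ``maf_min`` are removed; imputed SNPs with
    imputation quality strictly below ``info_min`` are removed.  Boundary
    values (MAF == maf_min, info == info_min) are retained.  Survivor order
    is preserved and in/out counts are logged.
    """
    keep: list[int] = []
    n_maf = n_info = 0
    maf_sample = gm.computed_maf()
    for j, s in enumerate(gm.snps):
        maf = s.maf if s.maf is not None else float(maf_sample[j])
        if maf < maf_min:
            n_maf += 1
            continue
        if s.source == "imputed" and s.info is not None and s.info < info_min:
            n_info += 1
            continue
        keep.append(j)
    logger.info(
        "qc_filter: %d SNPs in, %d out (%d MAF < %g, %d Info < %g), %d retained",
        gm.n_snps, n_maf + n_info, n_maf, maf_min, n_info, info_min, len(keep),
    )
    if not keep:
        logger.warning("qc_filter removed every SNP")
    return gm.subset_snps(keep)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT (hard calls) and DS (dosage) fields."""
    path = Path(path)
    hard = gm.hard_calls()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in gm.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality score">\n')
        fh.write('##INFO=<ID=SRC,Number=1,Type=String,Description="genotyped or imputed">\n')
        fh.write('##INFO=<ID=STR,Number=1,Type=String,Description="Strand annotation">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect-allele dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids)
            + "\n"
        )
        # VCF rows must be coordinate-sorted even if columns are not
        row_order = sorted(range(gm.n_snps), key=lambda j: (gm.snps[j].chrom, gm.snps[j].pos))
        for j in row_order:
            s = gm.snps[j]
            info_parts = [f"SRC={s.source}", f"STR={s.strand}"]
            if s.maf is not None:
                info_parts.append(f"MAF={s.maf:.6g}")
            if s.info is not None:
                info_parts.append(f"INFO={s.info:.6g}")
            fmt = "GT:DS" if s.source == "imputed" else "GT"
            fields = [
                s.chrom, str(s.pos), s.snp_id, s.other_allele, s.effect_allele,
                ".", "PASS", ";".join(sorted(info_parts)), fmt,
            ]
            gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            cells = []
            for i in range(gm.n_individuals):
                d = gm.dosage[i, j]
                if not np.isfinite(d):
                    cells.append("./.:." if fmt == "GT:DS" else "./.")
                elif fmt == "GT:DS":
                    cells.append(f"{gt_map[hard[i, j]]}:{d:.6g}")
                else:
                    cells.append(gt_map[hard[i, j]])
            fh.write("\t".join(fields + cells) + "\n")


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages (rows = individuals) plus a ``.snps.tsv`` metadata file."""
    path = Path(path)
    df = pd.DataFrame(gm.dosage, columns=gm.snp_ids)
    df.insert(0, "id", gm.individual_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    meta = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in gm.snps],
            "chrom": [s.chrom for s in gm.snps],
            "pos": [s.pos for s in gm.snps],
            "effect_allele": [s.effect_allele for s in gm.snps],
            "other_allele": [s.other_allele for s in gm.snps],
            "strand": [s.strand for s in gm.snps],
            "source": [s.source for s in gm.snps],
            "maf": [s.maf for s in gm.snps],
            "info": [s.info for s in gm.snps],
        }
    )
    meta_path = Path(str(path)[: -len(path.suffix)] + ".snps.tsv") if path.suffix else Path(str(path) + ".snps.tsv")
    meta.to_csv(meta_path, sep="\t", index=False, float_format="%.8g")


def write_kinship_tsv(ids: Sequence[str], K: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(K, index=list(ids), columns=list(ids))
    df.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def load_kinship_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float)
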