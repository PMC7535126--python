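"""Readers/writers for the standard formats the pipeline touches, and the
post-calling variant filters.

Internal coordinates are uniformly 0-based half-open; VCF (1-based) and GFF3
(1-based closed) are converted on ingest.  BED and bedGraph are consumed as-is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_ALLELE_CHARS = set("ACGTN*")


@dataclass(frozen=True)
class GenomeInterval:
    """A genomic interval, 0-based half-open, optionally stranded and scored."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"coordinate inversion or empty interval: "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_position(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass
class PopulationVariantRecord:
    """One VCF record with the pieces of genotype evidence the filters need.

    ``pos`` is 1-based as printed in the VCF; ``genotypes`` holds one
    (allele_a, allele_b) tuple per sample with ``None`` for a missing call.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    qual: float
    genotypes: list[tuple[int | None, int | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for allele in [self.ref, *self.alts]:
            if not allele or not set(allele) <= VALID_ALLELE_CHARS:
                raise ValueError(f"malformed allele {allele!r} at "
                                 f"{self.chrom}:{self.pos}")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 and a != "*" for a in self.alts)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or any(len(a) != 1 or a == "*" for a in self.alts)

    @property
    def call_rate(self) -> float:
        """Fraction of samples with a complete genotype call."""
        if not self.genotypes:
            return 0.0
        called = sum(1 for a, b in self.genotypes if a is not None and b is not None)
        return called / len(self.genotypes)

    @property
    def alt_allele_count(self) -> int:
        """Number of called alleles that are non-reference (any alt)."""
        return sum(
            int(a is not None and a > 0) + int(b is not None and b > 0)
            for a, b in self.genotypes
        )

    def allele_frequency(self, allele_index: int) -> float:
        """Sample frequency of allele ``allele_index`` among called alleles."""
        called = [x for gt in self.genotypes for x in gt if x is not None]
        if not called:
            raise ValueError(f"no called genotypes at {self.chrom}:{self.pos}")
        return sum(1 for x in called if x == allele_index) / len(called)

    @property
    def contains_n(self) -> bool:
        return any("N" in a for a in [self.ref, *self.alts])


@dataclass
class VariantFilterThresholds:
    """Post-calling variant filters.

    Defaults: site quality strictly > 30, alt-supporting allele count
    strictly > 2, at most 10 alleles, SNPs within 3 bp of an indel removed,
    records with call rate < 0.70 removed, SNPs overlapping the repeat mask
    removed.
    """

    min_quality: float = 30.0
    min_alt_count: int = 2
    max_alleles: int = 10
    indel_window: int = 3
    min_call_rate: float = 0.70
    repeat_mask: Sequence[GenomeInterval] | None = None

    def __post_init__(self) -> None:
        for name in ("min_quality", "min_alt_count", "max_alleles",
                     "indel_window", "min_call_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative threshold {name}")


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA into an ordered name -> uppercase-sequence map.

    Sequence names are the first whitespace-delimited token of each header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_genome(path: str | Path, genome: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_vcf(path: str | Path) -> list[PopulationVariantRecord]:
    """Read a VCF into PopulationVariantRecord objects via cyvcf2."""
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path), gts012=False)
    for v in vcf:
        gts = []
        for gt in v.genotypes:  # [a, b, phased]
            a, b = gt[0], gt[1]
            gts.append((None if a < 0 else int(a), None if b < 0 else int(b)))
        records.append(
            PopulationVariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=list(v.ALT),
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                genotypes=gts,
            )
        )
    return records


def filter_population_variants(
    records: Iterable[PopulationVariantRecord],
    thresholds: VariantFilterThresholds | None = None,
    return_counts: bool = False,
):
    """Apply the post-calling filters; a record is retained iff it passes all.

    SNPs within ``indel_window`` bp of any indel record's reference-span
    boundary are removed (|SNP pos − boundary| ≤ window).  Records with N
    alleles are skipped with a warning rather than raising.

    Returns the retained records, plus a per-reason removal count dict when
    ``return_counts`` is set.
    """
    th = thresholds or VariantFilterThresholds()
    records = list(records)

    usable: list[PopulationVariantRecord] = []
    counts: dict[str, int] = {
        "input": len(records), "n_allele": 0, "quality": 0, "alt_count": 0,
        "max_alleles": 0, "indel_proximity": 0, "call_rate": 0,
        "repeat_mask": 0, "retained": 0,
    }
    for rec in records:
        if rec.contains_n:
            logger.warning("skipping record with N allele at %s:%d",
                           rec.chrom, rec.pos)
            counts["n_allele"] += 1
            continue
        usable.append(rec)

    # indel reference-span boundaries, per chromosome, in 1-based coordinates
    indel_bounds: dict[str, list[tuple[int, int]]] = {}
    for rec in usable:
        if rec.is_indel:
            indel_bounds.setdefault(rec.chrom, []).append(
                (rec.pos, rec.pos + len(rec.ref) - 1)
            )

    def near_indel(rec: PopulationVariantRecord) -> bool:
        for lo, hi in indel_bounds.get(rec.chrom, ()):
            if (abs(rec.pos - lo) <= th.indel_window
                    or abs(rec.pos - hi) <= th.indel_window):
                return True
        return False

    def in_mask(rec: PopulationVariantRecord) -> bool:
        if th.repeat_mask is None:
            return False
        return any(iv.contains_position(rec.chrom, rec.pos0)
                   for iv in th.repeat_mask)

    retained = []
    for rec in usable:
        if not rec.qual > th.min_quality:
            counts["quality"] += 1
        elif not rec.alt_allele_count > th.min_alt_count:
            counts["alt_count"] += 1
        elif rec.n_alleles > th.max_alleles:
            counts["max_alleles"] += 1
        elif rec.is_snp and near_indel(rec):
            counts["indel_proximity"] += 1
        elif rec.call_rate < th.min_call_rate:
            counts["call_rate"] += 1
        elif rec.is_snp and in_mask(rec):
            counts["repeat_mask"] += 1
        else:
            retained.append(rec)
    counts["retained"] = len(retained)
    if return_counts:
        return retained, counts
    return retained


_INTERVAL_FORMATS = {"bed", "gff3", "bedgraph"}


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomeInterval]:
    """Read intervals from BED (0-based half-open), a GFF3 subset (converted
    from 1-based closed), or bedGraph (score payload in column 4)."""
    fmt = format.lower()
    if fmt not in _INTERVAL_FORMATS:
        raise ValueError(f"unknown interval format {format!r}")
    names = {
        "bed": ["chrom", "start", "end", "name", "score", "strand"],
        "bedgraph": ["chrom", "start", "end", "score"],
        "gff3": ["chrom", "source", "type", "start", "end", "score",
                 "strand", "phase", "attributes"],
    }[fmt]
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype=str,
        skip_blank_lines=True, engine="python",
    )
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    for col in names[df.shape[1]:]:
        df[col] = None
    intervals = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if fmt == "gff3":
            start -= 1  # 1-based closed -> 0-based half-open
        kwargs: dict = {"chrom": row.chrom, "start": start, "end": end}
        if fmt == "bed":
            if row.name is not None and not pd.isna(row.name):
                kwargs["name"] = str(row.name)
            if row.strand is not None and not pd.isna(row.strand):
                kwargs["strand"] = str(row.strand)
        elif fmt == "bedgraph":
            kwargs["score"] = float(row.score)
        elif fmt == "gff3":
            if row.strand is not None and not pd.isna(row.strand) \
                    and row.strand in "+-":
                kwargs["strand"] = str(row.strand)
            kwargs["name"] = str(row.type)
        intervals.append(GenomeInterval(**kwargs))
    return intervals


def write_intervals(path: str | Path, intervals: Iterable[GenomeInterval],
                    format: str = "bed") -> None:
    """Write intervals as BED or bedGraph with a commented header line."""
    fmt = format.lower()
    if fmt not in {"bed", "bedgraph"}:
        raise ValueError(f"unsupported output format {format!r}")
    with open(path, "w") as fh:
        if fmt == "bed":
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                         f"{iv.name or '.'}\t"
                         f"{'.' if iv.score is None else iv.score}\t"
                         f"{iv.strand}\n")
        else:
            fh.write("#chrom\tstart\tend\tscore\n")
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                         f"{0.0 if iv.score is None else iv.score}\n")


def write_vcf(path: str | Path, records: Iterable[PopulationVariantRecord],
              contigs: dict[str, int] | None = None,
              sample_names: Sequence[str] | None = None) -> None:
    """Write a minimal VCF v4.2 (with genotypes when records carry them)."""
    records = list(records)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        n_samples = max((len(r.genotypes) for r in records), default=0)
        if n_samples:
            if sample_names is None:
                sample_names = [f"sample{i}" for i in range(n_samples)]
            cols += ["FORMAT", *sample_names]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fields = [r.chrom, str(r.pos), ".", r.ref, ",".join(r.alts),
                      f"{r.qual:g}", ".", "."]
            if n_samples:
                fields.append("GT")
                for a, b in r.genotypes:
                    fields.append("./." if a is None or b is None else f"{a}/{b}")
            fh.write("\t".join(fields) + "\n")
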