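"""Ancestral-allele polarization, derived allele frequency spectra, and
construction of the derived (proxy-benign) variant class.

A derived allele is the one newly arisen on the focal lineage, identified by
mismatch with the inferred ancestral genome.  Spectra shifted toward rare
derived alleles indicate purifying selection; the derived class collects
fixed or near-fixed derived changes, which are depleted of deleterious
variants and serve as the benign proxy in training.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import PopulationVariantRecord

BASES = "ACGT"


class RejectionReason(enum.Enum):
    """Why a site could not be polarized."""

    ANCESTRAL_MISMATCH = "ancestral allele matches neither sampled allele"
    ANCESTRAL_UNKNOWN = "ancestral base is N or out of range"
    ANCESTRAL_LOW_CONFIDENCE = "ancestral base is low-confidence (lowercase/ambiguous)"


@dataclass(frozen=True)
class PolarizedVariant:
    """A bi-allelic SNP with ancestral/derived assignment and DAF."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ancestral: str
    derived: str
    daf: float

    def __post_init__(self) -> None:
        if self.ancestral not in (self.ref, self.alt):
            raise ValueError("ancestral allele must be ref or alt")
        if self.derived == self.ancestral:
            raise ValueError("derived must differ from ancestral")
        if not 0.0 <= self.daf <= 1.0:
            raise ValueError(f"daf out of range: {self.daf}")


@dataclass(frozen=True)
class DerivedSite:
    chrom: str
    pos: int  # 1-based
    ancestral: str
    derived: str
    source: str  # "fixed-difference" | "high-frequency-segregating"


@dataclass
class DerivedVariantSet:
    """The proxy-benign class: fixed differences to the ancestor plus
    segregating sites with derived frequency above 0.90."""

    sites: list[DerivedSite]

    def __len__(self) -> int:
        return len(self.sites)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tancestral\tderived\tsource\n")
            for s in self.sites:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.ancestral}\t{s.derived}\t"
                         f"{s.source}\n")


def polarize(
    record: PopulationVariantRecord,
    ancestral_genome: Mapping[str, str],
) -> PolarizedVariant | RejectionReason:
    """Assign ancestral/derived state to a bi-allelic SNP.

    The ancestral base is read from ``ancestral_genome`` at the record's
    position.  Lowercase bases mean low-confidence inference (Ensembl
    ancestral-FASTA convention) and are rejected with a distinct reason, as
    are N/ambiguous bases and ancestral bases matching neither allele.
    DAF is computed over called genotypes only.
    """
    if len(record.alts) != 1 or not record.is_snp:
        raise ValueError(
            f"polarize requires a bi-allelic SNP, got {record.chrom}:{record.pos} "
            f"ref={record.ref} alts={record.alts}"
        )
    seq = ancestral_genome[record.chrom]
    if not 0 <= record.pos0 < len(seq):
        return RejectionReason.ANCESTRAL_UNKNOWN
    raw = seq[record.pos0]
    if raw in "acgt":
        return RejectionReason.ANCESTRAL_LOW_CONFIDENCE
    if raw not in BASES:
        return RejectionReason.ANCESTRAL_UNKNOWN
    alt = record.alts[0]
    alt_freq = record.allele_frequency(1)
    if raw == record.ref:
        derived, daf = alt, alt_freq
    elif raw == alt:
        derived, daf = record.ref, 1.0 - alt_freq
    else:
        return RejectionReason.ANCESTRAL_MISMATCH
    return PolarizedVariant(
        chrom=record.chrom, pos=record.pos, ref=record.ref, alt=alt,
        ancestral=raw, derived=derived, daf=daf,
    )


def daf_spectrum(
    variants: Sequence[PolarizedVariant] | Sequence[float],
    cutoff: float = 0.10,
    n_bins: int = 10,
) -> dict:
    """Summarize a derived-allele-frequency spectrum.

    Rare means DAF ≤ ``cutoff`` (inclusive).  Returns counts, fractions, and
    a binned histogram over (0, 1].
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    dafs = np.asarray(
        [v.daf if isinstance(v, PolarizedVariant) else float(v) for v in variants],
        dtype=float,
    )
    if dafs.size == 0:
        raise ValueError("empty variant list")
    rare = int(np.sum(dafs <= cutoff))
    common = int(dafs.size - rare)
    counts, edges = np.histogram(dafs, bins=n_bins, range=(0.0, 1.0))
    return {
        "n": int(dafs.size),
        "cutoff": cutoff,
        "rare_count": rare,
        "rare_fraction": rare / dafs.size,
        "common_count": common,
        "common_fraction": common / dafs.size,
        "bin_edges": edges.tolist(),
        "bin_counts": counts.tolist(),
    }


def extract_derived_sites(
    reference: Mapping[str, str],
    ancestor: Mapping[str, str],
    population_records: Iterable[PopulationVariantRecord] = (),
) -> DerivedVariantSet:
    """Build the derived variant class from aligned reference/ancestor pairs
    and population polymorphism.

    Included are (a) every position where reference ≠ ancestor with both
    bases in {A,C,G,T}, unless the ancestral allele still segregates at
    minor allele frequency > 0.05, and (b) segregating sites whose derived
    allele frequency exceeds 0.90.
    """
    by_pos: dict[tuple[str, int], PopulationVariantRecord] = {}
    for rec in population_records:
        by_pos[(rec.chrom, rec.pos)] = rec

    sites: list[DerivedSite] = []
    for chrom, ref_seq in reference.items():
        if chrom not in ancestor:
            continue
        anc_seq = ancestor[chrom].upper()
        if len(anc_seq) != len(ref_seq):
            raise ValueError(
                f"length mismatch on {chrom}: reference {len(ref_seq)} vs "
                f"ancestor {len(anc_seq)}"
            )
        for i, (r, a) in enumerate(zip(ref_seq, anc_seq)):
            if r == a or r not in BASES or a not in BASES:
                continue
            rec = by_pos.get((chrom, i + 1))
            if rec is not None and rec.is_snp and len(rec.alts) == 1:
                # exclude if the ancestral allele still segregates at MAF > 5%
                anc_freq = None
                if rec.ref == a:
                    anc_freq = rec.allele_frequency(0)
                elif rec.alts[0] == a:
                    anc_freq = rec.allele_frequency(1)
                if anc_freq is not None and anc_freq > 0.05:
                    continue
            sites.append(DerivedSite(chrom, i + 1, ancestral=a, derived=r,
                                     source="fixed-difference"))

    seen = {(s.chrom, s.pos) for s in sites}
    for (chrom, pos), rec in sorted(by_pos.items()):
        if (chrom, pos) in seen or not rec.is_snp or len(rec.alts) != 1:
            continue
        if chrom not in ancestor or not 0 <= rec.pos0 < len(ancestor[chrom]):
            continue
        pol = polarize(rec, {c: s.upper() for c, s in ancestor.items()})
        if isinstance(pol, RejectionReason):
            continue
        if pol.daf > 0.90:
            sites.append(DerivedSite(chrom, pos, ancestral=pol.ancestral,
                                     derived=pol.derived,
                                     source="high-frequency-segregating"))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return DerivedVariantSet(sites)


def balance_classes(set_a: list, set_b: list, seed: int = 0) -> tuple[list, list]:
    """Downsample the larger of two variant sets so the classes match in size."""
    rng = np.random.default_rng(seed)
    if len(set_a) > len(set_b):
        idx = rng.choice(len(set_a), size=len(set_b), replace=False)
        return [set_a[i] for i in sorted(idx)], list(set_b)
    if len(set_b) > len(set_a):
        idx = rng.choice(len(set_b), size=len(set_a), replace=False)
        return list(set_a), [set_b[i] for i in sorted(idx)]
    return list(set_a), list(set_b)
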