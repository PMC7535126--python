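"""Windowed derived-substitution-rate estimation and de novo variant
simulation.

The proxy-deleterious class of the training dichotomy is built by simulating
de novo variants from local substitution rates: rates estimated in fixed
windows (default 100 kb) between an inferred ancestor and its descendant
capture regional mutation-rate variation, and new variants drawn from them
are not depleted of deleterious alleles the way fixed derived changes are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GenomeInterval

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SubstitutionRateTable:
    """Per-window 4x4 substitution counts/rates (diagonal unused).

    ``rates[i, j]`` is the probability that an ancestral base ``BASES[i]``
    became ``BASES[j]`` within the window; ``source_counts[i]`` is the number
    of non-N ancestral ``BASES[i]`` positions.  A source row with zero count
    is unavailable and the simulator falls back to coarser rates.
    """

    window: GenomeInterval
    counts: np.ndarray  # (4, 4) substitution counts
    source_counts: np.ndarray  # (4,)
    mismatch_count: int = 0

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.counts / self.source_counts[:, None]
        r[~np.isfinite(r)] = np.nan
        return r

    def row_available(self, base: str) -> bool:
        return self.source_counts[BASE_INDEX[base]] > 0


@dataclass
class SimulatedVariant:
    chrom: str
    pos: int  # 1-based
    ancestral: str
    alt: str


@dataclass
class SimulatedVariantSet:
    variants: list[SimulatedVariant]
    seed: int

    def __len__(self) -> int:
        return len(self.variants)

    def write_vcf(self, path, contigs: Mapping[str, int] | None = None) -> None:
        """Minimal sites-only VCF (ancestral base as REF)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=chcadd-simulator seed={self.seed}\n")
            if contigs:
                for name, length in contigs.items():
                    fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in self.variants:
                fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ancestral}\t{v.alt}"
                         f"\t.\t.\t.\n")


def _count_window(anc: str, der: str, start: int, end: int):
    counts = np.zeros((4, 4), dtype=np.int64)
    source = np.zeros(4, dtype=np.int64)
    mism = 0
    for a, d in zip(anc[start:end], der[start:end]):
        ia = BASE_INDEX.get(a)
        id_ = BASE_INDEX.get(d)
        if ia is None or id_ is None:  # N in either sequence: excluded
            continue
        source[ia] += 1
        if ia != id_:
            counts[ia, id_] += 1
            mism += 1
    return counts, source, mism


def estimate_rates(
    ancestor: Mapping[str, str],
    derived_genome: Mapping[str, str],
    window_size: int = 100_000,
) -> list[SubstitutionRateTable]:
    """Estimate windowed derived substitution rates between aligned genomes.

    rate(X -> Y, w) = (# positions in w with ancestor X, descendant Y) /
    (# ancestor-X positions in w); N positions are excluded from both.
    Windows tile each chromosome without overlap; the final partial window
    is kept.
    """
    if window_size <= 0:
        raise ValueError("window_size must be >= 1")
    tables: list[SubstitutionRateTable] = []
    for chrom, anc in ancestor.items():
        if chrom not in derived_genome:
            continue
        der = derived_genome[chrom]
        if len(der) != len(anc):
            raise ValueError(f"length mismatch on {chrom}")
        anc_u, der_u = anc.upper(), der.upper()
        for start in range(0, len(anc), window_size):
            end = min(start + window_size, len(anc))
            counts, source, mism = _count_window(anc_u, der_u, start, end)
            tables.append(SubstitutionRateTable(
                window=GenomeInterval(chrom, start, end),
                counts=counts, source_counts=source, mismatch_count=mism,
            ))
    return tables


def _aggregate(tables: Sequence[SubstitutionRateTable]):
    counts = sum((t.counts for t in tables), np.zeros((4, 4), dtype=np.int64))
    source = sum((t.source_counts for t in tables), np.zeros(4, dtype=np.int64))
    return counts, source


def _row_probs(counts: np.ndarray, source: np.ndarray, ia: int) -> np.ndarray | None:
    """Normalized alternative-base probabilities for source base index ia,
    or None when no substitutions from that base were observed."""
    if source[ia] == 0:
        return None
    row = counts[ia].astype(float)
    row[ia] = 0.0
    tot = row.sum()
    if tot == 0:
        return None
    return row / tot


def simulate_variants(
    rate_tables: Sequence[SubstitutionRateTable],
    ancestor: Mapping[str, str],
    n_target: int,
    seed: int,
    max_redraws: int = 1_000,
) -> SimulatedVariantSet:
    """Simulate de novo variants from windowed substitution rates.

    Windows are chosen with probability proportional to their observed
    mismatch counts, so simulated density tracks observed derived density;
    within a window a non-N position is drawn uniformly, and the alternative
    base Y is drawn with probability proportional to rate(X -> Y) for
    ancestral base X, falling back window -> chromosome -> genome when a
    row is unavailable.  Duplicate positions are redrawn (no two simulated
    variants share a position); every emitted position has a known ancestral
    base.
    """
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    rng = np.random.default_rng(seed)
    variants: list[SimulatedVariant] = []
    if n_target == 0:
        return SimulatedVariantSet(variants, seed)

    tables = list(rate_tables)
    weights = np.array([t.mismatch_count for t in tables], dtype=float)
    if weights.sum() == 0:
        raise ValueError("all substitution rates are zero; nothing to simulate")

    genome_counts, genome_source = _aggregate(tables)
    by_chrom: dict[str, list[SubstitutionRateTable]] = {}
    for t in tables:
        by_chrom.setdefault(t.window.chrom, []).append(t)
    chrom_agg = {c: _aggregate(ts) for c, ts in by_chrom.items()}

    probs = weights / weights.sum()
    taken: set[tuple[str, int]] = set()
    consecutive_failures = 0
    while len(variants) < n_target:
        if consecutive_failures > max_redraws:
            raise RuntimeError(
                f"position exhaustion after {max_redraws} consecutive redraws "
                f"({len(variants)}/{n_target} simulated)"
            )
        t = tables[int(rng.choice(len(tables), p=probs))]
        chrom = t.window.chrom
        pos0 = int(rng.integers(t.window.start, t.window.end))
        base = ancestor[chrom][pos0].upper()
        ia = BASE_INDEX.get(base)
        if ia is None or (chrom, pos0) in taken:
            consecutive_failures += 1
            continue
        # fallback hierarchy: window -> chromosome -> genome
        p = _row_probs(t.counts, t.source_counts, ia)
        if p is None:
            p = _row_probs(*chrom_agg[chrom], ia)
        if p is None:
            p = _row_probs(genome_counts, genome_source, ia)
        if p is None:
            consecutive_failures += 1
            continue
        alt = BASES[int(rng.choice(4, p=p))]
        taken.add((chrom, pos0))
        consecutive_failures = 0
        variants.append(SimulatedVariant(chrom, pos0 + 1, base, alt))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return SimulatedVariantSet(variants, seed)


def write_rate_tables(path, tables: Sequence[SubstitutionRateTable]) -> None:
    """Rate-table TSV: chrom, window start/end, 12 off-diagonal rate columns."""
    cols = [f"{x}>{y}" for x in BASES for y in BASES if x != y]
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\t" + "\t".join(cols) + "\n")
        for t in tables:
            r = t.rates
            vals = [r[BASE_INDEX[x], BASE_INDEX[y]]
                    for x in BASES for y in BASES if x != y]
            fh.write(f"{t.window.chrom}\t{t.window.start}\t{t.window.end}\t"
                     + "\t".join("NA" if np.isnan(v) else f"{v:.6g}"
                                 for v in vals) + "\n")
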