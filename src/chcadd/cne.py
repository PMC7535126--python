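"""Conserved-element filtering, hierarchical genomic-feature assignment,
CNE definition, SNP density, and windowed density correlation.

A conserved element (CE) is an interval under cross-species constraint,
consumed here as precomputed intervals.  Each CE is assigned to exactly one
genomic feature class using a fixed hierarchy (CDS > 5'UTR > 3'UTR >
promoter > RNA-gene > lncRNA > intronic > intergenic); CEs whose class is
lncRNA, intronic or intergenic are conserved non-protein-coding elements
(CNEs), the rest are conserved coding (CC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import GenomeInterval

HIERARCHY = ("CDS", "5UTR", "3UTR", "promoter", "RNA-gene",
             "lncRNA", "intronic", "intergenic")
CNE_CLASSES = frozenset({"lncRNA", "intronic", "intergenic"})


@dataclass(frozen=True)
class AnnotatedElement:
    interval: GenomeInterval
    assigned_class: str
    is_cne: bool

    def __post_init__(self) -> None:
        if self.assigned_class not in HIERARCHY:
            raise ValueError(f"unknown class {self.assigned_class!r}")


@dataclass(frozen=True)
class GeneModel:
    """Minimal protein-coding gene model for promoter definition."""

    chrom: str
    start: int  # gene body, 0-based half-open
    end: int
    strand: str
    utr5_length: int = 0
    name: str | None = None

    @property
    def tss(self) -> int:
        """0-based transcription start position."""
        return self.start if self.strand == "+" else self.end - 1


def filter_elements(
    elements: Iterable[GenomeInterval],
    gap_intervals: Sequence[GenomeInterval] = (),
    min_len: int = 4,
) -> list[GenomeInterval]:
    """Drop elements shorter than ``min_len`` or overlapping any assembly
    gap by >= 1 bp."""
    gaps = _build_trees(gap_intervals)
    kept = []
    for el in elements:
        if len(el) < min_len:
            continue
        tree = gaps.get(el.chrom)
        if tree is not None and tree.overlaps(el.start, el.end):
            continue
        kept.append(el)
    return kept


def define_promoters(
    gene_models: Iterable[GeneModel],
    chrom_lengths: Mapping[str, int] | None = None,
    promoter_size: int = 2_000,
    min_utr5: int = 15,
) -> list[GenomeInterval]:
    """The 2-kb region upstream of the TSS, emitted only for genes with an
    annotated 5'UTR of at least 15 bp; truncated at chromosome ends."""
    promoters = []
    for g in gene_models:
        if g.strand not in "+-":
            raise ValueError(f"gene {g.name!r} missing strand")
        if g.utr5_length < min_utr5:
            continue
        if g.strand == "+":
            start, end = g.tss - promoter_size, g.tss
        else:
            start, end = g.tss, g.tss + promoter_size
        start = max(0, start)
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[g.chrom])
        if start < end:
            promoters.append(GenomeInterval(g.chrom, start, end,
                                            strand=g.strand, name=g.name))
    return promoters


def _build_trees(intervals: Iterable[GenomeInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


class AnnotationLayers:
    """Per-class interval trees, in hierarchy order."""

    def __init__(self, layers: Mapping[str, Sequence[GenomeInterval]],
                 known_chroms: Iterable[str] | None = None) -> None:
        unknown = set(layers) - set(HIERARCHY)
        if unknown:
            raise ValueError(f"unknown annotation layers: {sorted(unknown)}")
        self.trees = {name: _build_trees(ivs) for name, ivs in layers.items()}
        self.known_chroms = set(known_chroms) if known_chroms is not None else None


def assign_class(element: GenomeInterval, layers: AnnotationLayers) -> AnnotatedElement:
    """Assign the highest-priority class the element overlaps (>= 1 bp).

    Elements overlapping no layer are intergenic.  The CNE flag is set iff
    the class is lncRNA, intronic or intergenic (no exon-associated overlap).
    """
    if layers.known_chroms is not None and element.chrom not in layers.known_chroms:
        raise KeyError(f"element on unknown chromosome {element.chrom!r}")
    assigned = "intergenic"
    for cls in HIERARCHY[:-1]:
        trees = layers.trees.get(cls)
        if trees is None:
            continue
        tree = trees.get(element.chrom)
        if tree is not None and tree.overlaps(element.start, element.end):
            assigned = cls
            break
    return AnnotatedElement(element, assigned, is_cne=assigned in CNE_CLASSES)


def annotate_elements(elements: Iterable[GenomeInterval],
                      layers: AnnotationLayers) -> list[AnnotatedElement]:
    return [assign_class(el, layers) for el in elements]


def merge_intervals(intervals: Iterable[GenomeInterval]) -> dict[str, list[tuple[int, int]]]:
    """Union of intervals per chromosome as sorted disjoint (start, end)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def snp_density(intervals: Sequence[GenomeInterval],
                snps: Iterable[tuple[str, int]]) -> float:
    """SNP count over the interval union divided by the union length in bp.

    ``snps`` are (chrom, 1-based position) pairs; overlapping intervals are
    counted once.
    """
    merged = merge_intervals(intervals)
    total = sum(e - s for spans in merged.values() for s, e in spans)
    if total == 0:
        raise ValueError("interval set has zero total length")
    starts = {c: np.array([s for s, _ in spans]) for c, spans in merged.items()}
    ends = {c: np.array([e for _, e in spans]) for c, spans in merged.items()}
    count = 0
    for chrom, pos in snps:
        if chrom not in starts:
            continue
        pos0 = pos - 1
        i = np.searchsorted(starts[chrom], pos0, side="right") - 1
        if i >= 0 and pos0 < ends[chrom][i]:
            count += 1
    return count / total


def _window_counts(intervals: Sequence[GenomeInterval],
                   chrom_lengths: Mapping[str, int],
                   window_size: int) -> tuple[list[GenomeInterval], np.ndarray]:
    windows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, window_size):
            windows.append(GenomeInterval(chrom, start, min(start + window_size,
                                                            length)))
    trees = _build_trees(intervals)
    counts = np.zeros(len(windows))
    for k, w in enumerate(windows):
        tree = trees.get(w.chrom)
        if tree is not None:
            counts[k] = len(tree.overlap(w.start, w.end))
    return windows, counts


def density_correlation(
    track_a_elements: Sequence[GenomeInterval],
    track_b_elements: Sequence[GenomeInterval],
    chrom_lengths: Mapping[str, int],
    window_size: int = 100_000,
    mode: str = "raw",
    coding_intervals: Sequence[GenomeInterval] = (),
) -> tuple[float, float]:
    """Pearson correlation of two element tracks over a genome tiling.

    mode "raw": per-window element counts; final partial windows dropped.
    mode "scaled": track-a counts divided by (window length minus coding
    bases in the window); partial windows kept, counts scaled by coverage.
    """
    if mode not in {"raw", "scaled"}:
        raise ValueError(f"unknown mode {mode!r}")
    windows, a = _window_counts(track_a_elements, chrom_lengths, window_size)
    _, b = _window_counts(track_b_elements, chrom_lengths, window_size)
    if mode == "raw":
        full = np.array([len(w) == window_size for w in windows])
        a, b = a[full], b[full]
    else:
        coding = merge_intervals(coding_intervals)
        denom = np.empty(len(windows))
        for k, w in enumerate(windows):
            cb = sum(max(0, min(e, w.end) - max(s, w.start))
                     for s, e in coding.get(w.chrom, ()))
            denom[k] = max(1, len(w) - cb)
        a = a / denom
        b = b * (window_size / np.array([len(w) for w in windows]))
    if len(a) < 3:
        raise ValueError("need at least 3 windows")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def write_annotated_bed(path, annotated: Iterable[AnnotatedElement]) -> None:
    """BED with class in column 4 and CC/CNE flag in column 5."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tclass\tflag\n")
        for ae in annotated:
            fh.write(f"{ae.interval.chrom}\t{ae.interval.start}\t"
                     f"{ae.interval.end}\t{ae.assigned_class}\t"
                     f"{'CNE' if ae.is_cne else 'CC'}\n")
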