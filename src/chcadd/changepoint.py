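"""Change-point detection of high-scoring subregions inside conserved
elements.

Each element's per-base score vector (plus 5 bp flanks on both sides, so the
inner region's borders may coincide with the element's borders) is treated
as a series and segmented offline with binary segmentation under a radial
basis function (RBF) kernel cost.  Two change points split the flanked
signal into subregions 1st/2nd/3rd from the 5' end; the element is a
candidate functional subregion when the 2nd (inner) subregion scores
significantly higher than both outer ones (two Welch t-tests, p <= 0.05).

The RBF cost of a segment x[a:b] is

    c(a, b) = (b - a) - (1 / (b - a)) * sum_{a<=i,j<b} K(x_i, x_j),

with K a Gaussian kernel whose bandwidth follows the median heuristic over
the element's pairwise squared distances.  Binary segmentation first finds
the single split minimizing total cost, then searches each side
independently and keeps the second split with the larger cost reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import GenomeInterval

DEFAULT_FLANK = 5
MIN_SEGMENT = 2


@dataclass(eq=False)
class ScoredElement:
    """An element with its flanked per-base score vector.

    ``signal`` covers the element plus ``flank_left``/``flank_right`` bases
    (both 5 unless truncated at a chromosome end, in which case the element
    is flagged truncated).
    """

    interval: GenomeInterval
    signal: np.ndarray
    flank_left: int = DEFAULT_FLANK
    flank_right: int = DEFAULT_FLANK
    truncated: bool = False
    source: str = "max-chCADD-per-site"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        expect = len(self.interval) + self.flank_left + self.flank_right
        if self.signal.size != expect:
            raise ValueError(
                f"signal length {self.signal.size} != element length "
                f"{len(self.interval)} + flanks {self.flank_left}+{self.flank_right}"
            )

    def flanked_to_genome(self, offset: int) -> int:
        """Map a flanked-signal offset to a 0-based genome position."""
        return self.interval.start - self.flank_left + offset


def flank_element(
    element: GenomeInterval,
    score_track: np.ndarray,
    flank: int = DEFAULT_FLANK,
    source: str = "max-chCADD-per-site",
) -> ScoredElement:
    """Cut an element's flanked signal out of a full per-base chromosome
    track, truncating flanks at chromosome ends."""
    lo = element.start - flank
    hi = element.end + flank
    fl, fr = flank, flank
    truncated = False
    if lo < 0:
        fl, lo, truncated = flank + lo, 0, True
    if hi > score_track.size:
        fr = flank - (hi - score_track.size)
        hi, truncated = score_track.size, True
    return ScoredElement(element, score_track[lo:hi], flank_left=fl,
                         flank_right=fr, truncated=truncated, source=source)


# ---------------------------------------------------------------------------
# RBF-cost binary segmentation


def _gram_prefix(signal: np.ndarray) -> np.ndarray:
    """2-D prefix sums of the Gaussian Gram matrix, median-heuristic
    bandwidth (gamma = 1/median pairwise squared distance; 1 if that
    median is zero)."""
    x = signal[:, None]
    d2 = (x - x.T) ** 2
    off = d2[np.triu_indices(d2.shape[0], k=1)]
    med = np.median(off) if off.size else 0.0
    gamma = 1.0 / med if med > 0 else 1.0
    K = np.exp(-gamma * d2)
    P = np.zeros((K.shape[0] + 1, K.shape[1] + 1))
    P[1:, 1:] = np.cumsum(np.cumsum(K, axis=0), axis=1)
    return P


def _segment_cost(P: np.ndarray, a: int, b: int) -> float:
    block = P[b, b] - P[a, b] - P[b, a] + P[a, a]
    n = b - a
    return n - block / n


def _best_split(P: np.ndarray, a: int, b: int,
                min_segment: int) -> tuple[int, float] | None:
    """Split t in (a, b) minimizing c(a,t)+c(t,b); returns (t, gain)."""
    best_t, best_cost = None, math.inf
    for t in range(a + min_segment, b - min_segment + 1):
        c = _segment_cost(P, a, t) + _segment_cost(P, t, b)
        if c < best_cost:
            best_cost, best_t = c, t
    if best_t is None:
        return None
    gain = _segment_cost(P, a, b) - best_cost
    return best_t, gain


@dataclass
class SegmentationResult:
    change_points: list[int]
    degenerate: bool = False


def segment(signal: np.ndarray, n_change_points: int = 2,
            min_segment: int = MIN_SEGMENT) -> SegmentationResult:
    """Binary segmentation with RBF cost.

    Finds the first change point on the whole signal, then searches each
    side independently and keeps splits in decreasing order of cost
    reduction until ``n_change_points`` are placed.  Constant signals are
    returned flagged degenerate (change points at the trisection offsets,
    which carry no information).
    """
    x = np.asarray(signal, dtype=float)
    T = x.size
    if T < (n_change_points + 1) * min_segment:
        raise ValueError(
            f"signal of length {T} too short for {n_change_points} change "
            f"points with min segment {min_segment}")
    if np.allclose(x, x[0]):
        cps = [round(T * (k + 1) / (n_change_points + 1))
               for k in range(n_change_points)]
        return SegmentationResult(cps, degenerate=True)
    P = _gram_prefix(x)
    boundaries = [0, T]
    # candidate best split per open segment
    while len(boundaries) - 2 < n_change_points:
        best = None
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            if b - a < 2 * min_segment:
                continue
            res = _best_split(P, a, b, min_segment)
            if res is not None and (best is None or res[1] > best[1]):
                best = res
        if best is None:
            break
        boundaries.append(best[0])
        boundaries.sort()
    cps = sorted(b for b in boundaries if b not in (0, T))
    return SegmentationResult(cps, degenerate=False)


# ---------------------------------------------------------------------------
# Subregions


@dataclass(eq=False)
class SubregionPartition:
    """An element's flanked signal split into three subregions by two change
    points (offsets on the flanked signal, 1 <= cp1 < cp2 < length)."""

    element: ScoredElement
    cp1: int
    cp2: int
    degenerate: bool = False
    p_first_vs_inner: float | None = None
    p_third_vs_inner: float | None = None
    verdict: str = "untested"  # "pass" | "fail" | "untestable" | "untested"

    def __post_init__(self) -> None:
        L = self.element.signal.size
        if not (1 <= self.cp1 < self.cp2 < L):
            raise ValueError(f"need 1 <= cp1 < cp2 < {L}, got "
                             f"({self.cp1}, {self.cp2})")

    @property
    def subregions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s = self.element.signal
        return s[: self.cp1], s[self.cp1 : self.cp2], s[self.cp2 :]

    @property
    def means(self) -> tuple[float, float, float]:
        return tuple(float(np.mean(r)) for r in self.subregions)

    @property
    def sds(self) -> tuple[float, float, float]:
        return tuple(float(np.std(r, ddof=1)) if r.size > 1 else float("nan")
                     for r in self.subregions)

    @property
    def lengths(self) -> tuple[int, int, int]:
        return tuple(int(r.size) for r in self.subregions)

    @property
    def inner_outer_difference(self) -> float:
        """mean(2nd) minus the mean of the pooled outer subregions."""
        first, inner, third = self.subregions
        return float(np.mean(inner) - np.mean(np.concatenate([first, third])))


def partition_element(element: ScoredElement,
                      result: SegmentationResult) -> SubregionPartition:
    cp1, cp2 = result.change_points
    return SubregionPartition(element, cp1, cp2, degenerate=result.degenerate)


def test_subregions(partition: SubregionPartition,
                    alpha: float = 0.05) -> SubregionPartition:
    """Welch two-sample t-tests of 1st-vs-2nd and 3rd-vs-2nd subregions.

    The element passes iff both p-values are <= ``alpha`` and the inner
    subregion's mean exceeds both outer means; subregions with fewer than
    2 points make the element untestable.
    """
    first, inner, third = partition.subregions
    if min(first.size, inner.size, third.size) < 2:
        partition.verdict = "untestable"
        return partition
    p1 = stats.ttest_ind(first, inner, equal_var=False).pvalue
    p3 = stats.ttest_ind(third, inner, equal_var=False).pvalue
    partition.p_first_vs_inner = float(p1)
    partition.p_third_vs_inner = float(p3)
    m1, m2, m3 = partition.means
    ok = p1 <= alpha and p3 <= alpha and m2 > m1 and m2 > m3
    partition.verdict = "pass" if ok else "fail"
    return partition


def rank_elements(partitions: list[SubregionPartition]) -> list[SubregionPartition]:
    """Passing elements sorted by decreasing inner-minus-outer mean
    difference; ties broken by genomic coordinate."""
    passing = [p for p in partitions if p.verdict == "pass"]
    return sorted(
        passing,
        key=lambda p: (-p.inner_outer_difference,
                       p.element.interval.chrom, p.element.interval.start),
    )


def cohens_d(group_a, group_b) -> float:
    """Absolute standardized mean difference with pooled standard deviation.

    Zero pooled sd with equal means is 0.0 by convention; with distinct
    means the statistic is undefined and NaN is returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    na, nb = a.size, b.size
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                       / (na + nb - 2))
    diff = abs(float(a.mean() - b.mean()))
    if pooled == 0:
        return 0.0 if diff == 0 else float("nan")
    return diff / pooled


def subregion_snp_density(
    partition: SubregionPartition,
    snps,
) -> dict[str, float]:
    """SNP density per section: 5bp-up, 1st, 2nd, 3rd, 5bp-down.

    Sections are the flanks plus the intersections of the three subregions
    with the element body, mapped back to genome coordinates; zero-length
    sections are reported as NaN.  ``snps`` are (chrom, 1-based pos) pairs.
    """
    el = partition.element
    L = el.signal.size
    fl, fr = el.flank_left, el.flank_right
    body_lo, body_hi = fl, L - fr
    sections = {
        "5bp-up": (0, fl),
        "1st": (body_lo, min(partition.cp1, body_hi)),
        "2nd": (max(partition.cp1, body_lo), min(partition.cp2, body_hi)),
        "3rd": (max(partition.cp2, body_lo), body_hi),
        "5bp-down": (L - fr, L),
    }
    out = {}
    for name, (a, b) in sections.items():
        if b <= a:
            out[name] = float("nan")
            continue
        iv = GenomeInterval(el.interval.chrom,
                            el.flanked_to_genome(a), el.flanked_to_genome(b))
        from .cne import snp_density
        out[name] = snp_density([iv], snps)
    return out


def write_partition_tsv(path, partitions: list[SubregionPartition]) -> None:
    """Per-element TSV: coordinates, change points (flanked and genomic),
    subregion statistics, p-values, difference and verdict."""
    ranked = {id(p): i + 1 for i, p in enumerate(rank_elements(partitions))}
    cols = ["chrom", "start", "end", "cp1", "cp2", "cp1_genome", "cp2_genome",
            "mean1", "mean2", "mean3", "sd1", "sd2", "sd3",
            "len1", "len2", "len3", "p_1st_vs_2nd", "p_3rd_vs_2nd",
            "inner_outer_diff", "verdict", "rank"]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for p in partitions:
            iv = p.element.interval
            m, s, ln = p.means, p.sds, p.lengths
            row = [iv.chrom, iv.start, iv.end, p.cp1, p.cp2,
                   p.element.flanked_to_genome(p.cp1),
                   p.element.flanked_to_genome(p.cp2),
                   *[f"{v:.6g}" for v in m], *[f"{v:.6g}" for v in s], *ln,
                   p.p_first_vs_inner, p.p_third_vs_inner,
                   f"{p.inner_outer_difference:.6g}", p.verdict,
                   ranked.get(id(p), "NA")]
            fh.write("\t".join(str(v) for v in row) + "\n")
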