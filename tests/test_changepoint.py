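import itertools
import math

import numpy as np
import pytest

from chcadd.changepoint import (
    ScoredElement,
    SubregionPartition,
    cohens_d,
    flank_element,
    partition_element,
    rank_elements,
    segment,
    subregion_snp_density,
)
from chcadd.changepoint import test_subregions as evaluate_subregions
from chcadd.io_formats import GenomeInterval
from chcadd.synthetic import make_step_signals

# ---------------------------------------------------------------------------
# independent oracle: exhaustive two-change-point search over the same
# RBF cost definition, computed directly from the Gram matrix


def rbf_cost_matrix(signal):
    x = np.asarray(signal, float)[:, None]
    d2 = (x - x.T) ** 2
    off = d2[np.triu_indices(len(x), k=1)]
    med = np.median(off) if off.size else 0.0
    gamma = 1.0 / med if med > 0 else 1.0
    return np.exp(-gamma * d2)


def exhaustive_two_changepoints(signal, min_segment=2):
    K = rbf_cost_matrix(signal)

    def cost(a, b):
        return (b - a) - K[a:b, a:b].sum() / (b - a)

    T = len(signal)
    best, best_cost = None, math.inf
    for c1 in range(min_segment, T - 2 * min_segment + 1):
        for c2 in range(c1 + min_segment, T - min_segment + 1):
            c = cost(0, c1) + cost(c1, c2) + cost(c2, T)
            if c < best_cost:
                best_cost, best = c, (c1, c2)
    return list(best)


def make_partition(first, inner, third, flank=0):
    signal = np.concatenate([first, inner, third]).astype(float)
    iv = GenomeInterval("chr1", 100 + flank, 100 + len(signal) - flank)
    el = ScoredElement(iv, signal, flank_left=flank, flank_right=flank)
    return SubregionPartition(el, cp1=len(first),
                              cp2=len(first) + len(inner))


class TestSegment:
    def test_noiseless_two_step_matches_exhaustive_oracle(self):
        signal = np.concatenate([np.zeros(20), np.full(20, 10.0),
                                 np.zeros(20)])
        res = segment(signal)
        assert res.change_points == [20, 40]
        assert res.change_points == exhaustive_two_changepoints(signal)

    def test_recovers_noisy_changepoints_within_one_position(self):
        elements, truth = make_step_signals(30, step_heights=10.0,
                                            noise_sd=1.0, seed=2)
        hits = 0
        for el, (c1, c2) in zip(elements, truth):
            got = segment(el.signal).change_points
            hits += abs(got[0] - c1) <= 1 and abs(got[1] - c2) <= 1
        assert hits >= 27

    def test_constant_signal_flagged_degenerate(self):
        res = segment(np.ones(60))
        assert res.degenerate

    def test_single_step_first_changepoint_at_step(self):
        signal = np.concatenate([np.zeros(30), np.full(30, 10.0)])
        res = segment(signal)
        assert 30 in res.change_points
        # the second split is cost-neutral inside a constant run, so compare
        # total cost against the exhaustive optimum instead of positions
        K = rbf_cost_matrix(signal)

        def total(cps):
            bounds = [0, *cps, len(signal)]
            return sum((b - a) - K[a:b, a:b].sum() / (b - a)
                       for a, b in zip(bounds[:-1], bounds[1:]))

        oracle = exhaustive_two_changepoints(signal)
        assert total(res.change_points) == pytest.approx(total(oracle))

    def test_too_short_signal_errors(self):
        with pytest.raises(ValueError):
            segment(np.arange(5.0))

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        signal = np.concatenate([rng.normal(0, 1, 20),
                                 rng.normal(6, 1, 20),
                                 rng.normal(0, 1, 20)])
        assert segment(signal).change_points == \
            segment(signal + 123.4).change_points

    def test_planted_signals_recovered_exactly_without_noise(self):
        elements, truth = make_step_signals(20, noise_sd=0.0, seed=6)
        for el, (c1, c2) in zip(elements, truth):
            assert segment(el.signal).change_points == [c1, c2]


class TestSubregionTests:
    def test_elevated_inner_passes(self):
        rng = np.random.default_rng(0)
        p = make_partition(rng.normal(0, 1, 20), rng.normal(10, 1, 20),
                           rng.normal(0, 1, 20))
        p = evaluate_subregions(p)
        assert p.verdict == "pass"
        assert p.p_first_vs_inner < 0.05 and p.p_third_vs_inner < 0.05
        # closed-form Welch check on the first comparison
        first, inner, _ = p.subregions
        se = math.sqrt(first.var(ddof=1) / 20 + inner.var(ddof=1) / 20)
        t_stat = (first.mean() - inner.mean()) / se
        from scipy import stats
        df = (first.var(ddof=1) / 20 + inner.var(ddof=1) / 20) ** 2 / (
            (first.var(ddof=1) / 20) ** 2 / 19
            + (inner.var(ddof=1) / 20) ** 2 / 19)
        expected_p = 2 * stats.t.sf(abs(t_stat), df)
        assert p.p_first_vs_inner == pytest.approx(expected_p)

    def test_depressed_inner_fails_regardless_of_p(self):
        rng = np.random.default_rng(1)
        p = make_partition(rng.normal(10, 1, 20), rng.normal(0, 1, 20),
                           rng.normal(10, 1, 20))
        assert evaluate_subregions(p).verdict == "fail"

    def test_tiny_subregion_untestable(self):
        p = make_partition(np.array([1.0]), np.full(10, 5.0), np.zeros(10))
        assert evaluate_subregions(p).verdict == "untestable"

    def test_null_welch_rejection_rate_near_alpha(self):
        """On randomly partitioned null signals the two-sided Welch test
        rejects at about the nominal 5% rate."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            p = make_partition(rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                               rng.normal(0, 1, 20))
            p = evaluate_subregions(p)
            rejections += p.p_first_vs_inner <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_three_subregions_reconstruct_flanked_length(self):
        p = make_partition(np.zeros(12), np.ones(9), np.zeros(14), flank=5)
        assert sum(p.lengths) == p.element.signal.size
        assert sum(p.lengths) == len(p.element.interval) + 10


class TestRankElements:
    def _passing(self, inner_mean, start=100):
        rng = np.random.default_rng(start)
        p = make_partition(rng.normal(0, 1, 20),
                           rng.normal(inner_mean, 1, 20),
                           rng.normal(0, 1, 20))
        p.element.interval = GenomeInterval("chr1", start, start + 60)
        return evaluate_subregions(p)

    def test_sorted_by_decreasing_difference(self):
        small, large = self._passing(5.0, 100), self._passing(10.0, 500)
        ranked = rank_elements([small, large])
        assert ranked[0] is large and ranked[1] is small

    def test_non_passing_excluded(self):
        rng = np.random.default_rng(3)
        null = evaluate_subregions(make_partition(
            rng.normal(0, 1, 20), rng.normal(0.1, 1, 20),
            rng.normal(0, 1, 20)))
        good = self._passing(8.0)
        ranked = rank_elements([null, good])
        assert all(r is not null for r in ranked)

    def test_tie_broken_by_coordinate(self):
        a = self._passing(8.0, 500)
        b = self._passing(8.0, 100)
        b.element.signal = a.element.signal.copy()  # identical difference
        ranked = rank_elements([a, b])
        assert ranked[0].element.interval.start == 100


class TestCohensD:
    def test_hand_computed_value(self):
        # pooled sd of {1,2,3} vs {3,4,5} is 1, |mean diff| = 2
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(2.0)

    def test_identical_groups_zero(self):
        assert cohens_d([2, 3, 4], [2, 3, 4]) == 0.0

    def test_zero_variance_equal_means_zero(self):
        assert cohens_d([5, 5, 5], [5, 5, 5]) == 0.0

    def test_zero_variance_distinct_means_nan(self):
        assert math.isnan(cohens_d([5, 5], [7, 7]))

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1, 2, 3])


class TestSubregionSnpDensity:
    def test_inner_density_arithmetic(self):
        p = make_partition(np.zeros(15), np.ones(10), np.zeros(15), flank=5)
        # inner subregion spans flanked offsets [15, 25) -> genome coords
        inner_start = p.element.flanked_to_genome(15)
        snps = [("chr1", inner_start + 3)]  # 1-based pos inside inner
        d = subregion_snp_density(p, snps)
        assert d["2nd"] == pytest.approx(0.1)

    def test_empty_section_is_nan(self):
        # cp1 inside the left flank leaves no 1st-section body
        signal = np.zeros(40)
        signal[3:] += 5.0
        el = ScoredElement(GenomeInterval("chr1", 105, 135), signal,
                           flank_left=5, flank_right=5)
        p = SubregionPartition(el, cp1=3, cp2=20)
        d = subregion_snp_density(p, [])
        assert math.isnan(d["1st"])

    def test_planted_suppression_detected(self):
        """With polymorphism suppressed 5-fold inside the inner subregion,
        inner SNP density is lowest in nearly all simulated elements."""
        rng = np.random.default_rng(9)
        wins = 0
        n_rep = 200
        for k in range(n_rep):
            p = make_partition(np.zeros(60), np.ones(60), np.zeros(60))
            start = p.element.interval.start
            snps = []
            for off in range(180):
                rate = 0.3 if (off < 60 or off >= 120) else 0.06
                if rng.random() < rate:
                    snps.append(("chr1", start + off + 1))
            d = subregion_snp_density(p, snps)
            if d["2nd"] < d["1st"] and d["2nd"] < d["3rd"]:
                wins += 1
        assert wins / n_rep >= 0.95


class TestFlankElement:
    def test_flanks_cut_from_track(self):
        track = np.arange(100.0)
        el = flank_element(GenomeInterval("chr1", 40, 60), track)
        assert el.signal[0] == 35.0 and el.signal[-1] == 64.0
        assert el.signal.size == 30 and not el.truncated

    def test_truncated_at_chromosome_start(self):
        track = np.arange(50.0)
        el = flank_element(GenomeInterval("chr1", 2, 20), track)
        assert el.truncated and el.flank_left == 2
        assert el.signal.size == 18 + 2 + 5
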