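"""IFF computation, threshold scanning, filtering/merging, and rate smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aplysia_swallow.core import Burst, SpikeTrain, ThresholdSpec
from aplysia_swallow.bursts import (DEFAULT_THRESHOLDS, combine_b3_b6b9, compute_iff,
                                    filter_and_merge, find_candidate_bursts,
                                    mean_burst_rate, smooth_rate)


def oracle_candidates(times, f_start, f_end):
    """Independent formulation of the scan rule: within each maximal run of
    consecutive ISIs with IFF >= f_end, a candidate starts at the first ISI
    whose IFF reaches f_start and spans to the run's last spike."""
    times = np.asarray(times, dtype=float)
    iff = 1.0 / np.diff(times)
    ok = iff >= f_end
    runs, i = [], 0
    while i < len(iff):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < len(iff) and ok[j]:
            j += 1
        runs.append((i, j))
        i = j
    out = []
    for a, b in runs:
        starts = [k for k in range(a, b) if iff[k] >= f_start]
        if starts:
            out.append((times[starts[0]], times[b]))
    return out


class TestIFF:
    def test_reciprocal_isis(self):
        s = compute_iff(SpikeTrain("u", [0.0, 0.1, 0.3]))
        np.testing.assert_allclose(s.rates, [10.0, 5.0])
        np.testing.assert_allclose(s.times, [0.0, 0.1])

    def test_constant_train(self):
        s = compute_iff(SpikeTrain("u", np.arange(11) * 0.1))
        np.testing.assert_allclose(s.rates, 10.0)
        assert len(s) == 10

    def test_fewer_than_two_spikes_empty(self):
        assert len(compute_iff(SpikeTrain("u", [1.0]))) == 0


class TestCandidateScan:
    def test_constant_10hz_single_candidate(self):
        spec = ThresholdSpec("B6/B9", 10.0, 5.0)
        cands = find_candidate_bursts(SpikeTrain("B6/B9", np.arange(7) * 0.1), spec)
        assert len(cands) == 1
        b = cands[0]
        assert (b.start, b.end, b.n_spikes) == (0.0, pytest.approx(0.6), 7)

    def test_scan_ends_at_end_threshold_drop(self):
        """Hand-traced scan for the B3 thresholds (8/2 Hz)."""
        spec = ThresholdSpec("B3", 8.0, 2.0)
        cands = find_candidate_bursts(SpikeTrain("B3", [0.0, 0.1, 0.2, 0.8, 1.3]), spec)
        assert len(cands) == 1
        assert cands[0].start == 0.0
        assert cands[0].end == pytest.approx(0.2)

    def test_never_reaching_start_threshold(self):
        spec = ThresholdSpec("u", 10.0, 5.0)
        assert find_candidate_bursts(SpikeTrain("u", np.arange(5) * 0.5), spec) == []

    @settings(max_examples=150, deadline=None)
    @given(st.lists(st.integers(1, 400), min_size=1, max_size=19),
           st.sampled_from([(10.0, 5.0), (8.0, 2.0), (3.0, 3.0)]))
    def test_matches_maximal_run_oracle(self, gaps, spec_vals):
        times = np.cumsum(np.asarray(gaps, dtype=float)) / 100.0
        times = np.concatenate(([0.0], times))
        spec = ThresholdSpec("u", *spec_vals)
        got = [(b.start, b.end) for b in find_candidate_bursts(SpikeTrain("u", times), spec)]
        expected = oracle_candidates(times, *spec_vals)
        assert got == pytest.approx(expected)

    def test_translation_equivariance(self):
        spec = ThresholdSpec("u", 8.0, 2.0)
        t = np.array([0.0, 0.1, 0.2, 0.35, 0.5, 1.2, 1.3, 1.4])
        base = find_candidate_bursts(SpikeTrain("u", t), spec)
        shifted = find_candidate_bursts(SpikeTrain("u", t + 11.7), spec)
        for b, s in zip(base, shifted):
            assert s.start == pytest.approx(b.start + 11.7)
            assert s.end == pytest.approx(b.end + 11.7)


class TestFilterAndMerge:
    def test_short_candidate_discarded(self):
        c = [Burst("u", 0.0, 0.3, 4)]
        assert filter_and_merge(c) is None

    def test_sparse_candidate_discarded(self):
        c = [Burst("u", 0.0, 0.6, 2)]
        assert filter_and_merge(c) is None

    def test_survivors_merged_spanning_all_spikes(self):
        times = np.concatenate([np.arange(7) * 0.1, 1.0 + np.arange(8) * 0.1])
        train = SpikeTrain("u", times)
        c = [Burst.from_spikes("u", times[:7]), Burst.from_spikes("u", times[7:])]
        merged = filter_and_merge(c, train)
        assert (merged.start, merged.end) == (0.0, pytest.approx(1.7))
        assert merged.n_spikes == 15
        assert merged.mean_rate == pytest.approx(14 / 1.7)

    def test_final_bursts_satisfy_rules(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = np.unique(np.cumsum(rng.uniform(0.01, 0.5, 25)))
            b = filter_and_merge(find_candidate_bursts(
                SpikeTrain("u", t), ThresholdSpec("u", 8.0, 2.0)), SpikeTrain("u", t))
            if b is not None:
                assert b.duration >= 0.5 and b.n_spikes >= 3

    def test_merge_then_discard_alternative_order(self):
        c = [Burst("u", 0.0, 0.3, 2), Burst("u", 0.5, 0.8, 2)]
        assert filter_and_merge(c, order="discard-then-merge") is None
        merged = filter_and_merge(c, order="merge-then-discard")
        assert merged is not None and merged.duration == pytest.approx(0.8)


class TestCombineRetractors:
    def test_identity_when_one_absent(self):
        b = Burst("B6/B9", 1.0, 3.0, 21)
        combined = combine_b3_b6b9(None, b)
        assert (combined.start, combined.end) == (1.0, 3.0)
        assert combined.unit == "B3/B6/B9"
        assert combine_b3_b6b9(None, None) is None

    def test_min_max_span(self):
        c = combine_b3_b6b9(Burst("B3", 1.5, 3.2, 10), Burst("B6/B9", 1.0, 3.0, 30))
        assert (c.start, c.end) == (1.0, 3.2)
        assert c.n_spikes == 40

    def test_union_count_with_trains(self):
        b3t = SpikeTrain("B3", [1.5, 2.0, 2.5, 3.2])
        b69t = SpikeTrain("B6/B9", [1.0, 1.6, 2.2, 3.0])
        c = combine_b3_b6b9(Burst.from_spikes("B3", b3t.times),
                            Burst.from_spikes("B6/B9", b69t.times), b3t, b69t)
        assert c.n_spikes == 8
        assert c.mean_rate == pytest.approx(7 / 2.2)


class TestRates:
    @pytest.mark.parametrize("n,dur", [(31, 3.0), (7, 0.6)])
    def test_mean_burst_rate_convention(self, n, dur):
        assert mean_burst_rate(Burst("u", 0.0, dur, n)) == pytest.approx(10.0)

    def test_single_spike_peak_height(self):
        sm = smooth_rate(SpikeTrain("u", [1.0]), t_start=0.0, t_stop=2.0)
        peak = sm.rates.max()
        assert peak == pytest.approx(1.0 / (0.2 * np.sqrt(2 * np.pi)), rel=1e-3)
        assert sm.times[np.argmax(sm.rates)] == pytest.approx(1.0, abs=0.011)

    def test_empty_train_zero_trace(self):
        sm = smooth_rate(SpikeTrain("u", []), t_start=0.0, t_stop=1.0)
        assert np.all(sm.rates == 0.0)

    def test_integral_conserves_spike_count(self, rng):
        t = np.unique(np.cumsum(rng.uniform(0.02, 0.2, 100)))
        sm = smooth_rate(SpikeTrain("u", t))
        assert sm.integral() == pytest.approx(len(t), rel=0.01)
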