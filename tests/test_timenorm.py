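"""Piecewise-linear warping and cross-swallow aggregation."""

import numpy as np
import pytest

from aplysia_swallow.core import Burst, ForceSegmentation, SwallowAnnotation
from aplysia_swallow.timenorm import (WarpMap, aggregate, apply_warp,
                                      build_warp_loaded, build_warp_unloaded,
                                      median_stage_durations, target_boundaries_loaded)


def seg_from_durations(durs, start=0.0):
    b = start + np.concatenate(([0.0], np.cumsum(durs)))
    return ForceSegmentation(e1=b[0], e2=b[1], e3=b[2], e4=b[3], e5=b[4], v_end=b[5])


class TestLoadedWarp:
    def test_worked_example_halves_II_triples_IV(self):
        """Stage durations (1,2,2,1,1) onto targets (1,1,2,3,1)."""
        seg = seg_from_durations([1, 2, 2, 1, 1])
        target = target_boundaries_loaded(dict(zip("I II III IV V".split(),
                                                   [1, 1, 2, 3, 1])))
        warp = build_warp_loaded(seg, target)
        np.testing.assert_allclose(warp(seg.boundaries()), target)  # exact boundaries
        # stage II midpoint: source [1,3] -> target [1,2], scale 1/2
        assert warp(2.0) == pytest.approx(1.5)
        assert warp(1.5) - warp(1.0) == pytest.approx(0.25)
        # stage IV: source [5,6] -> target [4,7], scale 3
        assert warp(5.5) == pytest.approx(5.5)
        assert warp(5.9) - warp(5.5) == pytest.approx(1.2)

    def test_identity_when_source_equals_target(self):
        seg = seg_from_durations([1, 1, 2, 3, 1])
        warp = build_warp_loaded(seg, target_boundaries_loaded(
            dict(zip("I II III IV V".split(), [1, 1, 2, 3, 1]))))
        t = np.linspace(0, 8, 50)
        np.testing.assert_allclose(warp(t), t, atol=1e-12)

    def test_undefined_stage_one_domain_starts_at_e3(self):
        seg = ForceSegmentation(e3=2.0, e4=4.0, e5=5.0, v_end=6.0)
        target = target_boundaries_loaded(dict(zip("I II III IV V".split(),
                                                   [1, 1, 2, 3, 1])))
        warp = build_warp_loaded(seg, target)
        assert warp.domain[0] == pytest.approx(2.0)
        assert warp(2.0) == pytest.approx(2.0)  # maps onto the stage III boundary
        # a burst entirely before e3 is dropped from aggregation
        bursts, _ = apply_warp(warp, {"B38": Burst("B38", 0.5, 1.5, 10)})
        assert bursts["B38"] is None

    def test_zero_duration_stage_rejected(self):
        # zero-duration stages are rejected at segmentation construction
        with pytest.raises(ValueError):
            ForceSegmentation(e1=0.0, e2=1.0, e3=1.0, e4=3.0, e5=4.0, v_end=5.0)
        # and degenerate targets are rejected when building the warp
        with pytest.raises(ValueError):
            target_boundaries_loaded(dict(zip("I II III IV V".split(),
                                              [1, 0, 2, 3, 1])))


class TestUnloadedWarp:
    def test_two_second_inward_halved(self):
        ann = SwallowAnnotation("a", "unloaded", (0.0, 6.0), (1.0, 3.0))
        warp = build_warp_unloaded(ann, (1.0, 2.0))
        # uniform scale 1/2: total duration halves
        assert warp(6.0) - warp(0.0) == pytest.approx(3.0)
        assert warp(1.0) == pytest.approx(1.0) and warp(3.0) == pytest.approx(2.0)

    def test_identity_when_source_equals_target(self):
        ann = SwallowAnnotation("a", "unloaded", (0.0, 6.0), (1.0, 3.0))
        warp = build_warp_unloaded(ann, (1.0, 3.0))
        t = np.linspace(0, 6, 20)
        np.testing.assert_allclose(warp(t), t, atol=1e-12)

    def test_inward_midpoint_maps_to_target_midpoint(self):
        ann = SwallowAnnotation("a", "unloaded", (0.0, 6.0), (1.0, 3.0))
        warp = build_warp_unloaded(ann, (0.0, 4.0))
        assert warp(2.0) == pytest.approx(2.0)  # midpoint -> midpoint

    def test_missing_inward_movement_errors(self):
        ann = SwallowAnnotation("a", "unloaded", (0.0, 6.0), None)
        with pytest.raises(ValueError):
            build_warp_unloaded(ann, (0.0, 1.0))


class TestApplyWarp:
    def test_monotone_in_monotone_out(self):
        warp = WarpMap([0.0, 1.0, 4.0], [0.0, 2.0, 5.0])
        t = np.sort(np.random.default_rng(1).uniform(0, 4, 100))
        wt = warp(t)
        assert np.all(np.diff(wt) >= 0)

    def test_series_resampled_onto_grid(self):
        warp = WarpMap([0.0, 2.0], [0.0, 1.0])
        t = np.linspace(0, 2, 21)
        grid = np.linspace(0, 1, 11)
        _, series = apply_warp(warp, series={"f": (t, t**2)}, grid=grid)
        gt, gv = series["f"]
        np.testing.assert_allclose(gv, (2 * grid) ** 2, atol=0.02)

    def test_burst_boundaries_map_to_analytic_images(self):
        warp = WarpMap([0.0, 1.0, 3.0], [0.0, 2.0, 3.0])
        bursts, _ = apply_warp(warp, {"u": Burst("u", 0.5, 2.0, 10)})
        assert bursts["u"].start == pytest.approx(1.0)
        assert bursts["u"].end == pytest.approx(2.5)


class TestAggregate:
    def test_identical_swallows_are_a_fixed_point(self):
        grid = np.linspace(0, 1, 101)
        trace = np.sin(2 * np.pi * grid)
        swallow = ({"u": Burst("u", 0.2, 0.8, 10)}, {"f": (grid, trace)})
        agg = aggregate([swallow] * 5, grid)
        np.testing.assert_allclose(agg.traces["f"]["median"], trace)
        np.testing.assert_allclose(agg.traces["f"]["q1"], trace)
        np.testing.assert_allclose(agg.traces["f"]["q3"], trace)
        assert agg.burst_timing["u"]["start_median"] == pytest.approx(0.2)
        assert agg.burst_timing["u"]["start_q1"] == pytest.approx(0.2)

    def test_constant_trace_quartiles(self):
        grid = np.linspace(0, 1, 11)
        swallows = [({}, {"f": (grid, np.full_like(grid, v))}) for v in (1.0, 2.0, 3.0)]
        agg = aggregate(swallows, grid)
        np.testing.assert_allclose(agg.traces["f"]["median"], 2.0)
        np.testing.assert_allclose(agg.traces["f"]["q1"], 1.5)
        np.testing.assert_allclose(agg.traces["f"]["q3"], 2.5)

    def test_quartile_band_ordering(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(0, 1, 51)
        swallows = [({}, {"f": (grid, rng.normal(size=51))}) for _ in range(9)]
        agg = aggregate(swallows, grid)
        tr = agg.traces["f"]
        assert np.all(tr["q1"] <= tr["median"] + 1e-12)
        assert np.all(tr["median"] <= tr["q3"] + 1e-12)

    def test_median_stage_durations_skip_undefined(self):
        segs = [seg_from_durations([1, 1, 2, 3, 1]),
                ForceSegmentation(e3=2.0, e4=4.0, e5=7.0, v_end=8.0)]
        med = median_stage_durations(segs)
        assert med["I"] == pytest.approx(1.0)   # only the defined swallow counts
        assert med["III"] == pytest.approx(2.0)
        assert med["IV"] == pytest.approx(3.0)

    def test_dropped_pre_rise_accounting(self, loaded_session):
        from aplysia_swallow.pipeline import aggregate_loaded_session
        rec, gt, ann = loaded_session
        agg = aggregate_loaded_session(rec, ann)
        assert agg.n_dropped_pre_rise == sum(not g.stage_I_defined for g in gt)
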