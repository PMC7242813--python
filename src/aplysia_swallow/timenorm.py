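"""Piecewise-linear time normalization and cross-swallow aggregation.

Loaded swallows are warped stage-by-stage so all swallows align at every
stage boundary; unloaded swallows (which have no force record) are rescaled
uniformly so the inward-movement interval aligns. After warping, pointwise
medians and quartiles of force and firing-rate traces and of burst start and
stop times can be computed; the aggregate timeline is finally rescaled so
each stage has the median duration observed across swallows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Burst, ForceSegmentation, SwallowAnnotation


@dataclass
class WarpMap:
    """Monotone piecewise-linear map between two sets of boundaries.

    The map is exact at the boundaries (``map(src[i]) == dst[i]``). Inside
    the domain it interpolates linearly; with ``extrapolate=True`` (used for
    the uniform unloaded rescale) the end segments extend affinely.
    """

    src: np.ndarray
    dst: np.ndarray
    extrapolate: bool = False

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=float)
        self.dst = np.asarray(self.dst, dtype=float)
        if self.src.shape != self.dst.shape or self.src.ndim != 1 or len(self.src) < 2:
            raise ValueError("src and dst must be matching 1-D boundary arrays (>= 2 points)")
        if not (np.all(np.diff(self.src) > 0) and np.all(np.diff(self.dst) > 0)):
            raise ValueError("boundaries must be strictly increasing in both frames")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.src[0]), float(self.src[-1])

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        out = np.interp(t_arr, self.src, self.dst)
        if self.extrapolate:
            lo_slope = (self.dst[1] - self.dst[0]) / (self.src[1] - self.src[0])
            hi_slope = (self.dst[-1] - self.dst[-2]) / (self.src[-1] - self.src[-2])
            out = np.where(t_arr < self.src[0], self.dst[0] + (t_arr - self.src[0]) * lo_slope, out)
            out = np.where(t_arr > self.src[-1], self.dst[-1] + (t_arr - self.src[-1]) * hi_slope, out)
        return float(out) if np.isscalar(t) else out

    def contains(self, t: float) -> bool:
        lo, hi = self.domain
        return bool(self.extrapolate or (lo <= t <= hi))


def target_boundaries_loaded(stage_durations: dict[str, float]) -> np.ndarray:
    """Cumulative boundaries [e1, e2, e3, e4, e5, v_end] of the target
    timeline, starting at 0, from per-stage target durations I..V."""
    durs = [stage_durations[s] for s in ("I", "II", "III", "IV", "V")]
    if min(durs) <= 0:
        raise ValueError("target stage durations must be positive")
    return np.concatenate(([0.0], np.cumsum(durs)))


def build_warp_loaded(seg: ForceSegmentation,
                      target: dict[str, float] | np.ndarray) -> WarpMap:
    """Warp one loaded swallow onto the target stage timeline.

    Each defined stage is linearly stretched or compressed by its
    target/source duration ratio. A swallow with an undefined stage I has no
    boundary before event 3; its warp domain starts at e3 (mapping onto the
    target timeline from the stage III boundary on), and anything earlier is
    dropped from aggregation.
    """
    tgt = target if isinstance(target, np.ndarray) else target_boundaries_loaded(target)
    if len(tgt) != 6:
        raise ValueError("target must provide 6 boundaries (e1, e2, e3, e4, e5, v_end)")
    src = seg.boundaries()
    if np.any(np.diff(src) <= 0):
        raise ValueError("zero-duration stage in source segmentation")
    if seg.v_end is None:
        tgt_used = tgt[:-1]
    else:
        tgt_used = tgt
    if not seg.stage_I_defined:
        tgt_used = tgt_used[2:]
    if len(src) != len(tgt_used):
        raise ValueError("segmentation boundaries do not match target boundaries")
    return WarpMap(src, tgt_used)


def build_warp_unloaded(annotation: SwallowAnnotation,
                        target_inward: tuple[float, float]) -> WarpMap:
    """Uniform rescale aligning the inward-movement interval with the target.

    A single scale factor (target duration / source duration) applies to the
    whole swallow, so a 2 s inward movement matched to a 1 s target halves
    the swallow's total duration.
    """
    if annotation.inward_movement is None:
        raise ValueError("annotation has no inward-movement interval")
    i0, i1 = annotation.inward_movement
    t0, t1 = target_inward
    if not (i1 > i0 and t1 > t0):
        raise ValueError("inward intervals must have positive duration")
    return WarpMap(np.array([i0, i1]), np.array([t0, t1]), extrapolate=True)


def apply_warp(warp: WarpMap,
               bursts: dict[str, Burst | None] | None = None,
               series: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
               grid: np.ndarray | None = None,
               drop_outside: bool = True):
    """Warp burst intervals and time series.

    Bursts fully outside the warp domain are dropped (set to None) when
    ``drop_outside`` — the fate of bursts preceding event 3 in swallows with
    an undefined stage I — and otherwise raise. Series sample times are
    mapped through the warp and linearly resampled onto ``grid``; grid
    points outside the warped extent become NaN so they are ignored by the
    aggregation step.

    Returns ``(warped_bursts, warped_series)``.
    """
    warped_bursts: dict[str, Burst | None] = {}
    for unit, b in (bursts or {}).items():
        if b is None:
            warped_bursts[unit] = None
            continue
        if not (warp.contains(b.start) and warp.contains(b.end)):
            if drop_outside:
                warped_bursts[unit] = None
                continue
            raise ValueError(f"burst of {unit} lies outside the warp domain")
        warped_bursts[unit] = Burst(b.unit, float(warp(b.start)), float(warp(b.end)),
                                    b.n_spikes)
    warped_series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, (t, v) in (series or {}).items():
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if not warp.extrapolate:
            lo, hi = warp.domain
            m = (t >= lo) & (t <= hi)
            t, v = t[m], v[m]
        wt = np.asarray(warp(t), dtype=float)
        if grid is None:
            warped_series[name] = (wt, v)
        else:
            out = np.interp(grid, wt, v, left=np.nan, right=np.nan) if len(wt) else \
                np.full_like(grid, np.nan)
            warped_series[name] = (grid, out)
    return warped_bursts, warped_series


@dataclass
class AggregateTraces:
    """Median and quartile traces on a common grid plus burst-timing
    summaries, after the final rescale to the median stage durations."""

    grid: np.ndarray
    traces: dict[str, dict[str, np.ndarray]]  # name -> {median, q1, q3}
    burst_timing: dict[str, dict[str, float]]  # unit -> {start_median, ...}
    n_swallows: int
    n_dropped_pre_rise: int = 0


def _quartiles(stack: np.ndarray, axis: int = 0):
    # linear-interpolation quartiles (the common "type 7" convention);
    # grid points where no swallow contributes stay NaN silently
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        q1 = np.nanpercentile(stack, 25, axis=axis)
        q2 = np.nanpercentile(stack, 50, axis=axis)
        q3 = np.nanpercentile(stack, 75, axis=axis)
    return q1, q2, q3


def aggregate(warped: list[tuple[dict[str, Burst | None], dict[str, tuple[np.ndarray, np.ndarray]]]],
              grid: np.ndarray,
              target_boundaries: np.ndarray | None = None,
              median_boundaries: np.ndarray | None = None,
              n_dropped_pre_rise: int = 0) -> AggregateTraces:
    """Pointwise median/quartiles over warped swallows, then rescale the
    timeline so each stage has the median duration observed in all swallows.

    ``warped`` holds the outputs of :func:`apply_warp` (series already on
    ``grid``). ``target_boundaries``/``median_boundaries`` define the final
    rescale; omitting them skips it (identity timeline).
    """
    if not warped:
        raise ValueError("need at least one swallow")
    names = sorted({k for _, series in warped for k in series})
    traces: dict[str, dict[str, np.ndarray]] = {}
    for name in names:
        stack = np.vstack([series[name][1] if name in series else np.full_like(grid, np.nan)
                           for _, series in warped])
        q1, q2, q3 = _quartiles(stack)
        traces[name] = {"median": q2, "q1": q1, "q3": q3}

    units = sorted({u for bursts, _ in warped for u in bursts})
    burst_timing: dict[str, dict[str, float]] = {}
    for u in units:
        starts = np.array([bursts[u].start for bursts, _ in warped
                           if bursts.get(u) is not None])
        ends = np.array([bursts[u].end for bursts, _ in warped
                         if bursts.get(u) is not None])
        if len(starts) == 0:
            continue
        s1, s2, s3 = np.percentile(starts, [25, 50, 75])
        e1, e2, e3 = np.percentile(ends, [25, 50, 75])
        burst_timing[u] = {"start_q1": s1, "start_median": s2, "start_q3": s3,
                           "end_q1": e1, "end_median": e2, "end_q3": e3,
                           "n": float(len(starts))}

    out_grid = grid
    if target_boundaries is not None and median_boundaries is not None:
        rescale = WarpMap(np.asarray(target_boundaries, float),
                          np.asarray(median_boundaries, float), extrapolate=True)
        out_grid = np.asarray(rescale(grid), dtype=float)
        for u in burst_timing:
            burst_timing[u] = {k: (v if k == "n" else float(rescale(v)))
                               for k, v in burst_timing[u].items()}
    return AggregateTraces(out_grid, traces, burst_timing,
                           n_swallows=len(warped),
                           n_dropped_pre_rise=n_dropped_pre_rise)


def median_stage_durations(segs: list[ForceSegmentation]) -> dict[str, float]:
    """Median observed duration of each stage across swallows (stage I and II
    medians use only swallows where they are defined; stage V needs v_end)."""
    out: dict[str, float] = {}
    for stage in ("I", "II", "III", "IV", "V"):
        durs = [s.stages[stage][1] - s.stages[stage][0]
                for s in segs if s.stages[stage] is not None]
        if durs:
            out[stage] = float(np.median(durs))
    return out
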