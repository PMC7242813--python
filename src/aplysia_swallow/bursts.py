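"""Burst identification from instantaneous firing frequency (IFF) thresholds.

The IFF is the reciprocal of each interspike interval, assigned to that
interval. A candidate burst begins at the first spike of the first ISI whose
IFF reaches the unit's start threshold and ends at the later spike of the
last ISI whose IFF is still at or above the end threshold; candidates
shorter than 0.5 s or with fewer than three spikes are discarded, and the
survivors within one swallow cycle are merged into a single burst spanning
the entire set of spikes. The muscles in this system behave as low-pass
filters, so brief or slow firing that would produce no measurable force is
deliberately excluded by these rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Burst, SpikeTrain, ThresholdSpec

#: Default start/end IFF thresholds (Hz) per identified unit.
DEFAULT_THRESHOLDS: dict[str, ThresholdSpec] = {
    "B38": ThresholdSpec("B38", 8.0, 5.0),
    "I2": ThresholdSpec("I2", 10.0, 5.0),
    "B8a/b": ThresholdSpec("B8a/b", 3.0, 3.0),
    "B6/B9": ThresholdSpec("B6/B9", 10.0, 5.0),
    "B3": ThresholdSpec("B3", 8.0, 2.0),
    "B4/B5": ThresholdSpec("B4/B5", 3.0, 3.0),
}

MIN_BURST_DURATION_S = 0.5
MIN_BURST_SPIKES = 3


@dataclass
class IFFSeries:
    """Instantaneous firing frequency, one value per interspike interval.

    ``times`` holds the first spike of each ISI; ``rates`` its reciprocal
    duration in Hz.
    """

    times: np.ndarray
    rates: np.ndarray

    def __len__(self) -> int:
        return len(self.rates)


@dataclass
class SmoothedRate:
    """Gaussian-smoothed firing-rate estimate on a uniform grid (σ = 200 ms
    by default); the integral over the grid approximates the spike count."""

    times: np.ndarray
    rates: np.ndarray
    sigma: float

    def integral(self) -> float:
        return float(np.trapezoid(self.rates, self.times))


def compute_iff(train: SpikeTrain) -> IFFSeries:
    """IFF series of a spike train; fewer than two spikes yields an empty series."""
    t = train.times
    if len(t) < 2:
        return IFFSeries(np.array([]), np.array([]))
    isi = np.diff(t)
    return IFFSeries(t[:-1], 1.0 / isi)


def find_candidate_bursts(train: SpikeTrain, spec: ThresholdSpec) -> list[Burst]:
    """Scan the IFF series for candidate bursts.

    A candidate begins at the first spike of the first ISI with
    IFF >= f_start and ends at the later spike of the last consecutive ISI
    with IFF >= f_end (boundary equality stays in-burst); scanning resumes
    after each candidate. Candidates may violate the final duration/count
    rules — filtering is a separate step.
    """
    t = train.times
    iff = compute_iff(train).rates
    candidates: list[Burst] = []
    i = 0
    n_isi = len(iff)
    while i < n_isi:
        if iff[i] < spec.f_start:
            i += 1
            continue
        j = i
        while j < n_isi and iff[j] >= spec.f_end:
            j += 1
        # ISIs i..j-1 are in-burst: spikes i..j inclusive
        candidates.append(Burst.from_spikes(train.unit, t[i:j + 1]))
        i = j + 1
    return candidates


def filter_and_merge(candidates: list[Burst], train: SpikeTrain | None = None,
                     min_duration: float = MIN_BURST_DURATION_S,
                     min_spikes: int = MIN_BURST_SPIKES,
                     order: str = "discard-then-merge") -> Burst | None:
    """Discard too-short/too-sparse candidates, then merge survivors.

    The default order applies the <0.5 s / <3 spikes discard rules to the
    raw candidates and merges the survivors into one burst spanning the
    entire set of spikes (the span from the first survivor's start to the
    last survivor's end, counting every spike of the train inside it).
    ``order="merge-then-discard"`` is available for sensitivity analysis.
    Candidates must come from a single unit within one analysis window
    (the annotated swallow cycle), so at most one burst results.
    """
    if order not in ("discard-then-merge", "merge-then-discard"):
        raise ValueError(f"unknown order {order!r}")

    def _span(bs: list[Burst]) -> Burst:
        start = min(b.start for b in bs)
        end = max(b.end for b in bs)
        if train is not None:
            n = int(np.sum((train.times >= start) & (train.times <= end)))
        else:
            n = sum(b.n_spikes for b in bs)
        return Burst(bs[0].unit, start, end, n)

    def _passes(b: Burst) -> bool:
        return b.duration >= min_duration and b.n_spikes >= min_spikes

    if not candidates:
        return None
    if order == "discard-then-merge":
        survivors = [b for b in candidates if _passes(b)]
        return _span(survivors) if survivors else None
    merged = _span(candidates)
    return merged if _passes(merged) else None


def bursts_from_train(train: SpikeTrain, spec: ThresholdSpec,
                      window: tuple[float, float] | None = None,
                      **filter_kwargs) -> Burst | None:
    """Full per-cycle burst extraction: restrict to the analysis window,
    scan for candidates, filter and merge."""
    sub = train if window is None else train.in_window(*window)
    return filter_and_merge(find_candidate_bursts(sub, spec), sub, **filter_kwargs)


def combine_b3_b6b9(b3: Burst | None, b6b9: Burst | None,
                    b3_train: SpikeTrain | None = None,
                    b6b9_train: SpikeTrain | None = None) -> Burst | None:
    """Combined retractor-pool burst: bursting when either B3 or B6/B9 is,
    spanning from the earlier start to the later end.

    When the member spike trains are supplied, the spike count is the union
    of both trains' spikes within the span; otherwise the member counts are
    summed (exact whenever each member's spikes lie within its own burst).
    """
    members = [b for b in (b3, b6b9) if b is not None]
    if not members:
        return None
    start = min(b.start for b in members)
    end = max(b.end for b in members)
    trains = [tr for tr in (b3_train, b6b9_train) if tr is not None]
    if trains:
        pooled = np.unique(np.concatenate([tr.times for tr in trains]))
        n = int(np.sum((pooled >= start) & (pooled <= end)))
    else:
        n = sum(b.n_spikes for b in members)
    return Burst("B3/B6/B9", start, end, n)


def mean_burst_rate(burst: Burst) -> float:
    """Mean firing rate during a burst: (n_spikes - 1) / duration."""
    if burst.n_spikes < 2 or burst.duration <= 0:
        raise ValueError("mean rate needs >= 2 spikes and positive duration")
    return (burst.n_spikes - 1) / burst.duration


def smooth_rate(train: SpikeTrain, t_start: float | None = None,
                t_stop: float | None = None, grid_rate: float = 100.0,
                sigma: float = 0.2, truncate: float = 5.0) -> SmoothedRate:
    """Sum of unit-mass Gaussian kernels (SD ``sigma``) centered on each spike,
    evaluated on a uniform grid; kernels are truncated at ±``truncate``·σ
    (mass loss < 1e-6 at the default). With no spikes the trace is zero."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = train.times
    if t_start is None:
        t_start = (t[0] if len(t) else 0.0) - truncate * sigma
    if t_stop is None:
        t_stop = (t[-1] if len(t) else 1.0) + truncate * sigma
    grid = np.arange(t_start, t_stop + 0.5 / grid_rate, 1.0 / grid_rate)
    rate = np.zeros_like(grid)
    if len(t):
        norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
        half = truncate * sigma
        lo = np.searchsorted(grid, t - half, side="left")
        hi = np.searchsorted(grid, t + half, side="right")
        for ti, a, b in zip(t, lo, hi):
            rate[a:b] += norm * np.exp(-0.5 * ((grid[a:b] - ti) / sigma) ** 2)
    return SmoothedRate(grid, rate, sigma)


def thresholds_from_config(entries: dict[str, dict | list | tuple]) -> dict[str, ThresholdSpec]:
    """Per-unit threshold overrides from config, e.g. {"B3": [8, 2]} or
    {"B3": {"f_start": 8, "f_end": 2}} — allows the per-animal exceptions
    the original analysis required for unusually slow units."""
    specs = dict(DEFAULT_THRESHOLDS)
    for unit, val in entries.items():
        if isinstance(val, dict):
            specs[unit] = ThresholdSpec(unit, float(val["f_start"]), float(val["f_end"]))
        else:
            f_start, f_end = val
            specs[unit] = ThresholdSpec(unit, float(f_start), float(f_end))
    return specs
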