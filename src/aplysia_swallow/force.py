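"""Five-event segmentation of the force record of loaded swallows.

Events: (1) end of the rapid force decrease of the preceding swallow, at a
temporarily stable intermediate level; (2) start of the final drop to the
force minimum; (3) start of the rapid force rise at the beginning of
retraction; (4) start of force deceleration approaching the maximum;
(5) start of the rapid force decrease ending retraction. Stages I-V lie
between consecutive events, stage V spanning event 5 to event 1 of the next
cycle. When the force decays to its minimum without an intermediate plateau,
events 1 and 2 are indistinct and stage I is undefined.

The original study placed these events manually; the automatic detector here
is a documented slope-classification heuristic whose thresholds are
fractions of the cycle's force range, with manual annotations always taking
precedence when supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ForceSegmentation
from .io import read_manual_events


class SegmentationError(ValueError):
    """Raised when an expected force event cannot be located; the message
    names the event that failed."""


@dataclass(frozen=True)
class EventDetectorParams:
    """Tunables of the automatic event detector.

    smooth_width
        Moving-average width (s) applied to the force before differentiation.
    rapid_slope_frac
        Slope magnitude, as a fraction of the cycle's force range per second,
        above which force is classified as rapidly rising/falling.
    plateau_level_frac
        Minimum level above the cycle minimum, as a fraction of the range,
        for a plateau to count as the *intermediate* stage-I plateau (the
        flat spell at the force minimum is not stage I).
    intermediate_max_frac
        Maximum level (fraction of range above the minimum) of the stage-I
        plateau; a pause near the peak during the preceding force drop is
        not an intermediate plateau.
    min_stage
        Minimum duration (s) of a classified run; shorter runs are demoted
        to plateau.
    min_stage_one
        Minimum duration (s) of a plateau accepted as stage I; brief pauses
        inside the force drop are not a maintained intermediate level.
    """

    smooth_width: float = 0.1
    rapid_slope_frac: float = 0.18
    plateau_level_frac: float = 0.15
    intermediate_max_frac: float = 0.6
    min_stage: float = 0.15
    min_stage_one: float = 0.4

    def __post_init__(self) -> None:
        if min(self.smooth_width, self.rapid_slope_frac,
               self.plateau_level_frac, self.min_stage) <= 0:
            raise ValueError("all detector parameters must be positive")


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(label, start_idx, stop_idx_exclusive) for each maximal constant run."""
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate(([0], change, [len(labels)]))
    return [(int(labels[a]), int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def _absorb_short_runs(runs: list[tuple[int, int, int]], min_len: int) -> list[tuple[int, int, int]]:
    """Demote runs shorter than min_len to plateau (noise-driven slope
    excursions are not stage transitions), then coalesce equal neighbors.
    Rise/fall run boundaries therefore stay at genuine threshold crossings."""
    out: list[list[int]] = []
    for label, a, b in runs:
        if b - a < min_len:
            label = 0
        if out and out[-1][0] == label:
            out[-1][2] = b
        else:
            out.append([label, a, b])
    return [(label, a, b) for label, a, b in out]


def segment_force(force: np.ndarray, sample_rate: float,
                  cycle_window: tuple[float, float],
                  params: EventDetectorParams | None = None,
                  t0: float = 0.0) -> ForceSegmentation:
    """Locate events 1-5 in one swallow's analysis window.

    The window should start inside the preceding swallow's rapid force drop
    and end at (or just past) event 1 of the following cycle so that every
    stage boundary is visible. Raises SegmentationError naming the event
    that could not be found.
    """
    params = params or EventDetectorParams()
    force = np.asarray(force, dtype=float)
    a = int(np.ceil((cycle_window[0] - t0) * sample_rate))
    b = int(np.floor((cycle_window[1] - t0) * sample_rate)) + 1
    a, b = max(a, 0), min(b, len(force))
    if b - a < 2:
        raise SegmentationError("cycle window does not cover the force record")
    seg = force[a:b]
    t = t0 + np.arange(a, b) / sample_rate

    w = max(1, int(round(params.smooth_width * sample_rate)))
    kernel = np.ones(w) / w
    smooth = np.convolve(seg, kernel, mode="same")
    frange = float(np.ptp(smooth))
    if frange <= 0:
        raise SegmentationError("event 3: flat force record, no rise found")
    slope = np.gradient(smooth) * sample_rate
    thr = params.rapid_slope_frac * frange

    labels = np.zeros(len(seg), dtype=int)
    labels[slope > thr] = 1
    labels[slope < -thr] = -1
    runs = _absorb_short_runs(_runs(labels), max(1, int(round(params.min_stage * sample_rate))))

    # Main rise: the rise run with the largest force gain -> events 3 and 4.
    rises = [(smooth[bb - 1] - smooth[aa], aa, bb) for label, aa, bb in runs if label == 1]
    if not rises:
        raise SegmentationError("event 3: no rapid force rise in window")
    _, i3, i4 = max(rises)
    e3, e4 = t[i3], t[min(i4, len(t) - 1)]

    # Event 5: start of the first rapid fall after the maintenance stage.
    falls_after = [(aa, bb) for label, aa, bb in runs if label == -1 and aa >= i4]
    if not falls_after:
        raise SegmentationError("event 5: no rapid force decrease after maintenance")
    i5, iv_end = falls_after[0]
    e5 = t[i5]
    v_end = t[min(iv_end, len(t) - 1)] if iv_end < len(seg) else None

    # Events 1-2: first *intermediate-level* plateau before the rise.
    fmin = float(np.min(smooth[:i3 + 1]))
    level_floor = fmin + params.plateau_level_frac * frange
    level_ceil = fmin + params.intermediate_max_frac * frange
    min_plateau = int(round(params.min_stage_one * sample_rate))
    e1 = e2 = None
    for label, aa, bb in runs:
        if bb > i3:
            break
        level = float(np.mean(smooth[aa:bb]))
        if label == 0 and bb - aa >= min_plateau and level_floor <= level <= level_ceil:
            # require a preceding fall: the plateau must terminate a rapid drop
            prior = [lab for lab, pa, pb in runs if pb <= aa and lab == -1]
            if prior:
                e1, e2 = t[aa], t[min(bb, len(t) - 1)]
                break
    if e2 is not None and e2 >= e3:
        e2 = e3 - 1.0 / sample_rate
    return ForceSegmentation(e3=float(e3), e4=float(e4), e5=float(e5),
                             e1=None if e1 is None else float(e1),
                             e2=None if e2 is None else float(e2),
                             v_end=None if v_end is None else float(v_end))


def segment_session(force: np.ndarray, sample_rate: float,
                    cycle_windows: list[tuple[float, float]],
                    params: EventDetectorParams | None = None,
                    t0: float = 0.0) -> list[ForceSegmentation]:
    """Segment every swallow of a session; each swallow's stage V is closed
    by the following swallow's event 1 when that swallow defines one."""
    segs = [segment_force(force, sample_rate, win, params, t0) for win in cycle_windows]
    for cur, nxt in zip(segs[:-1], segs[1:]):
        if nxt.e1 is not None:
            cur.v_end = nxt.e1
    return segs


def load_manual_events(path: str | Path) -> list[tuple[str, int, ForceSegmentation]]:
    """Load manually annotated events (the authoritative source in the
    original analysis); stage intervals derive from them identically to the
    automatic path. Validation of event ordering happens on construction."""
    return read_manual_events(path)
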