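"""Domain types shared by all pipeline stages.

Conventions: all times are seconds from recording start, all intervals are
closed ``[start, end]``, and a spike falling exactly on a burst boundary
belongs to the burst. Signals are uniformly sampled float arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNEL_ROLES = ("nerve", "emg", "force")

#: Canonical unit labels used throughout; user-defined labels are also accepted.
KNOWN_UNITS = ("B38", "I2", "B8a/b", "B6/B9", "B3", "B4/B5", "B3/B6/B9")


class FormatError(ValueError):
    """Raised when an on-disk file does not match the expected schema."""


@dataclass
class Channel:
    """One recorded channel: a named signal with a physiological role."""

    name: str
    role: str
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        self.data = np.asarray(self.data, dtype=float)


@dataclass
class Recording:
    """Multichannel, uniformly sampled recording.

    Parameters
    ----------
    channels
        Channels in a fixed order; all must have the same length.
    sample_rate
        Sampling rate in Hz (the study digitized at 5000 Hz).
    t0
        Time of the first sample in seconds (default 0).
    """

    channels: list[Channel]
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lengths = {len(c.data) for c in self.channels}
        if len(lengths) > 1:
            raise FormatError(f"ragged channels: lengths {sorted(lengths)}")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names: {names}")

    @property
    def n_samples(self) -> int:
        return len(self.channels[0].data) if self.channels else 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> Channel:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"no channel named {name!r}")

    def force_channel(self) -> Channel:
        force = [c for c in self.channels if c.role == "force"]
        if len(force) != 1:
            raise ValueError(
                f"force analysis requires exactly one force channel, found {len(force)}"
            )
        return force[0]


@dataclass
class SpikeTrain:
    """Ordered spike times (s) of one identified unit."""

    unit: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def in_window(self, start: float, end: float) -> "SpikeTrain":
        """Spikes inside the closed interval [start, end]."""
        m = (self.times >= start) & (self.times <= end)
        return SpikeTrain(self.unit, self.times[m])


@dataclass
class Burst:
    """A burst of one unit: closed interval [start, end] with its spike count.

    ``mean_rate`` follows the (n_spikes - 1) / duration convention. Candidate
    bursts from threshold scanning may be shorter than 0.5 s or have fewer
    than three spikes; those constraints are enforced by the filtering step,
    not by this container.
    """

    unit: str
    start: float
    end: float
    n_spikes: int
    mean_rate: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("burst must have end > start")
        if self.mean_rate is None:
            self.mean_rate = (self.n_spikes - 1) / self.duration

    @property
    def duration(self) -> float:
        return self.end - self.start

    @classmethod
    def from_spikes(cls, unit: str, times: np.ndarray) -> "Burst":
        times = np.asarray(times, dtype=float)
        if len(times) < 2:
            raise ValueError("a burst needs at least two spikes")
        return cls(unit, float(times[0]), float(times[-1]), len(times))


@dataclass(frozen=True)
class ThresholdSpec:
    """IFF thresholds (Hz) bounding a unit's burst: start >= end > 0."""

    unit: str
    f_start: float
    f_end: float

    def __post_init__(self) -> None:
        if not (self.f_start >= self.f_end > 0):
            raise ValueError("thresholds must satisfy f_start >= f_end > 0")


@dataclass
class SwallowAnnotation:
    """Behavioral annotation of one swallow cycle."""

    animal: str
    condition: str
    cycle_window: tuple[float, float]
    inward_movement: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("unloaded", "loaded"):
            raise ValueError(f"condition must be unloaded/loaded, got {self.condition!r}")
        a, b = self.cycle_window
        if not b > a:
            raise ValueError("cycle_window must be a nonempty interval")
        if self.inward_movement is not None:
            i, j = self.inward_movement
            if not (a <= i < j <= b):
                raise ValueError("inward_movement must lie within cycle_window")


# Stage names in event order; stage V spans event 5 to event 1 of the next cycle.
STAGE_NAMES = ("I", "II", "III", "IV", "V")
STAGE_DESCRIPTIONS = {
    "I": "partial force maintenance",
    "II": "force dip",
    "III": "force rise",
    "IV": "force maintenance",
    "V": "major force drop",
}


@dataclass
class ForceSegmentation:
    """Events 1-5 in the force record of one loaded swallow and stages I-V.

    Events 1 and 2 are absent when the force decays to its minimum without an
    intermediate plateau; stage I (and stage II's start) are then undefined
    and the defined portion of the swallow begins at event 3. ``v_end`` is
    event 1 of the following cycle (or the end of the detected force drop),
    closing stage V.
    """

    e3: float
    e4: float
    e5: float
    e1: float | None = None
    e2: float | None = None
    v_end: float | None = None

    def __post_init__(self) -> None:
        events = [e for e in (self.e1, self.e2, self.e3, self.e4, self.e5, self.v_end)
                  if e is not None]
        if (self.e1 is None) != (self.e2 is None):
            raise ValueError("events 1 and 2 must be defined together")
        if not np.all(np.diff(events) > 0):
            raise ValueError(f"defined events must be strictly increasing, got {events}")

    @property
    def stage_I_defined(self) -> bool:
        return self.e1 is not None

    @property
    def stages(self) -> dict[str, tuple[float, float] | None]:
        return {
            "I": (self.e1, self.e2) if self.stage_I_defined else None,
            "II": (self.e2, self.e3) if self.stage_I_defined else None,
            "III": (self.e3, self.e4),
            "IV": (self.e4, self.e5),
            "V": (self.e5, self.v_end) if self.v_end is not None else None,
        }

    def boundaries(self) -> np.ndarray:
        """Defined stage boundaries in time order (starting at e1, or e3)."""
        events = [self.e1, self.e2, self.e3, self.e4, self.e5, self.v_end]
        return np.array([e for e in events if e is not None], dtype=float)


@dataclass
class PairedAnimalTable:
    """Per-animal, per-condition means of one measure (the shape of the
    study's summary tables): one row per animal with the unloaded mean, the
    loaded mean, and the per-condition numbers of swallows."""

    measure: str
    data: pd.DataFrame  # columns: animal, unloaded, loaded, n_unloaded, n_loaded

    REQUIRED = ("animal", "unloaded", "loaded", "n_unloaded", "n_loaded")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
        if self.data["animal"].duplicated().any():
            raise ValueError("one row per animal required")
        if (self.data[["n_unloaded", "n_loaded"]] < 1).any().any():
            raise ValueError("per-condition n must be >= 1")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_rows(cls, measure: str, rows: list[tuple]) -> "PairedAnimalTable":
        df = pd.DataFrame(rows, columns=list(cls.REQUIRED))
        return cls(measure, df)

    @property
    def n_animals(self) -> int:
        return len(self.data)

    def differences(self) -> np.ndarray:
        """Per-animal loaded - unloaded differences."""
        return (self.data["loaded"] - self.data["unloaded"]).to_numpy(dtype=float)

    def condition_means(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.data["unloaded"].to_numpy(dtype=float),
                self.data["loaded"].to_numpy(dtype=float))
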