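"""Window-discriminator spike detection.

A window discriminator captures signal peaks on one channel whose amplitude
falls inside a closed amplitude range and whose time falls inside a closed
time window — the standard manual unit-sorting procedure for extracellular
nerve recordings in this system. The I2 EMG channel is low-pass filtered at
100 Hz before peak detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Recording, SpikeTrain

#: Neighborhood (s) within which only the largest extremum is kept.
PEAK_REFRACTORY_S = 1e-3

#: Default cutoff (Hz) of the EMG pre-filter.
I2_LOWPASS_HZ = 100.0


@dataclass(frozen=True)
class WindowDiscriminator:
    """Amplitude/time window selecting the peaks of one unit on one channel.

    ``amp_lo``/``amp_hi`` are measured in the polarity direction (a negative
    polarity discriminator matches troughs of depth ``amp_lo``..``amp_hi``).
    Both windows are closed intervals.
    """

    unit: str
    channel: str
    amp_lo: float
    amp_hi: float
    t_lo: float = -np.inf
    t_hi: float = np.inf
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if not self.amp_lo < self.amp_hi:
            raise ValueError("amplitude window requires amp_lo < amp_hi")
        if not self.t_lo < self.t_hi:
            raise ValueError("time window requires t_lo < t_hi")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")

    @property
    def amp_center(self) -> float:
        return 0.5 * (self.amp_lo + self.amp_hi)


def lowpass(x: np.ndarray, sample_rate: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass with -3 dB at ``cutoff``.

    The filter is applied forward and backward (``filtfilt``) so peak timing
    is preserved; the design cutoff is pre-warped so that the *combined*
    two-pass response is -3 dB at the requested frequency.
    """
    nyquist = sample_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    # |H|^2(cutoff) = 1/sqrt(2)  =>  fc = cutoff / (sqrt(2)-1)^(1/(2*order))
    fc = cutoff / (np.sqrt(2.0) - 1.0) ** (1.0 / (2 * order))
    if fc >= nyquist:
        raise ValueError(f"adjusted cutoff {fc:.1f} Hz exceeds Nyquist {nyquist} Hz")
    sos = sps.butter(order, fc, btype="low", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def _find_extrema(x: np.ndarray, sample_rate: float, polarity: str,
                  height: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Indices and signed-by-polarity amplitudes of local extrema separated by
    at least the refractory neighborhood; plateau ties break to the earliest
    sample. ``height`` prunes sub-threshold peaks early."""
    y = x if polarity == "positive" else -x
    distance = max(1, int(round(PEAK_REFRACTORY_S * sample_rate)))
    idx, props = sps.find_peaks(y, distance=distance, plateau_size=1, height=height)
    left = props.get("left_edges")
    if left is not None:
        idx = left  # earliest sample of a flat-topped peak
    return idx, y[idx]


def detect_spikes(recording: Recording, disc: WindowDiscriminator,
                  prefiltered: np.ndarray | None = None) -> SpikeTrain:
    """Apply one window discriminator, returning the unit's spike train."""
    data = prefiltered if prefiltered is not None else recording.channel(disc.channel).data
    idx, amps = _find_extrema(data, recording.sample_rate, disc.polarity)
    t = recording.t0 + idx / recording.sample_rate
    keep = (amps >= disc.amp_lo) & (amps <= disc.amp_hi) & (t >= disc.t_lo) & (t <= disc.t_hi)
    return SpikeTrain(disc.unit, t[keep])


def apply_discriminator_set(recording: Recording,
                            discriminators: list[WindowDiscriminator],
                            i2_prefilter: bool = True,
                            i2_channel: str = "I2") -> dict[str, SpikeTrain]:
    """Run a full discriminator set, one spike train per unit.

    Several discriminators may target the same unit (OR-combined amplitude
    windows, accommodating collision-driven amplitude variability of B8a/b
    and B4/B5). A peak matching the windows of more than one unit is assigned
    to the unit whose amplitude-window center is nearest, with a warning.
    When ``i2_prefilter`` is set, the EMG channel is low-passed at 100 Hz
    before detection.
    """
    units = list(dict.fromkeys(d.unit for d in discriminators))
    by_channel: dict[tuple[str, str], list[WindowDiscriminator]] = {}
    for d in discriminators:
        by_channel.setdefault((d.channel, d.polarity), []).append(d)

    cache: dict[str, np.ndarray] = {}
    spikes: dict[str, list[np.ndarray]] = {u: [] for u in units}
    ambiguous = 0
    for (channel, polarity), group in by_channel.items():
        data = recording.channel(channel).data
        if i2_prefilter and recording.channel(channel).role == "emg" and channel == i2_channel:
            if channel not in cache:
                cache[channel] = lowpass(data, recording.sample_rate, I2_LOWPASS_HZ)
            data = cache[channel]
        floor = min(d.amp_lo for d in group)
        idx, amps = _find_extrema(data, recording.sample_rate, polarity, height=floor)
        t = recording.t0 + idx / recording.sample_rate
        # (n_disc, n_peaks) window-membership masks, resolved by amplitude-center distance
        match = np.array([(amps >= d.amp_lo) & (amps <= d.amp_hi)
                          & (t >= d.t_lo) & (t <= d.t_hi) for d in group])
        unit_hit = np.zeros((len(units), match.shape[1]), dtype=bool)
        for gi, d in enumerate(group):
            unit_hit[units.index(d.unit)] |= match[gi]
        ambiguous += int(np.sum(unit_hit.sum(axis=0) > 1))
        dist = np.abs(amps[None, :] - np.array([[d.amp_center] for d in group]))
        dist[~match] = np.inf
        best = np.argmin(dist, axis=0)
        hit = match.any(axis=0)
        for gi, d in enumerate(group):
            sel = hit & (best == gi)
            if sel.any():
                spikes[d.unit].append(t[sel])
    if ambiguous:
        warnings.warn(f"{ambiguous} peaks matched windows of more than one unit; "
                      "each was assigned to the nearest amplitude-window center",
                      stacklevel=2)
    return {u: SpikeTrain(u, np.unique(np.concatenate(ts)) if ts else np.array([]))
            for u, ts in spikes.items()}


def discriminators_from_config(entries: list[dict]) -> list[WindowDiscriminator]:
    """Build discriminators from config mappings with keys unit, channel,
    amp_lo, amp_hi and optional t_lo, t_hi, polarity."""
    out = []
    for e in entries:
        out.append(WindowDiscriminator(
            unit=e["unit"], channel=e["channel"],
            amp_lo=float(e["amp_lo"]), amp_hi=float(e["amp_hi"]),
            t_lo=float(e.get("t_lo", -np.inf)), t_hi=float(e.get("t_hi", np.inf)),
            polarity=e.get("polarity", "positive")))
    return out
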