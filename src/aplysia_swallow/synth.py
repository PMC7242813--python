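"""Synthetic swallowing sessions with known ground truth.

Each session emulates a feeding bout: per-cycle stage structure (partial
force maintenance, force dip, force rise, force maintenance, major force
drop), per-unit bursts anchored to stages with unit-specific amplitudes on
shared nerve channels, a piecewise-linear five-stage force waveform for
loaded swallows, and condition effects (burst prolongation and firing-rate
increase of the retraction units under load). The generator is seeded and
bit-reproducible; its purpose is ground truth for the analysis pipeline,
not biophysical realism (see the methods note for what it does not model).

Spikes are rendered as a fixed-shape biphasic waveform (2 ms for nerve
units, wider for the EMG) scaled by the unit amplitude. Spikes of different
units on the same channel are nudged apart to at least 2.4 ms so their
waveforms never merge; overlap decomposition is outside the scope of the
detection stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Burst, Channel, Recording, SwallowAnnotation

#: Default per-stage durations (s), stages I..V. Loaded cycles run ~7 s and
#: unloaded ~5.4 s with ~2 s of inward movement, matching the study's
#: behavioral summary ranges. Unloaded swallows have no force record; their
#: stage frame is latent and only delimits burst anchors and annotations.
STAGE_DURATIONS = {
    "loaded": (1.2, 0.8, 1.5, 2.0, 1.5),
    "unloaded": (1.2, 0.8, 1.0, 1.0, 1.4),
}

#: Channel layout: three nerves, one EMG, one force channel (loaded only).
CHANNELS = (("RN", "nerve"), ("BN2", "nerve"), ("BN3", "nerve"), ("I2", "emg"))
FORCE_CHANNEL = ("Force", "force")

DEFAULT_NOISE = {"nerve": 0.02, "emg": 0.02, "force": 0.5}

#: Minimum separation (s) enforced between spikes of different units sharing
#: a channel; just beyond the 2 ms waveform support.
CROSS_UNIT_SEPARATION_S = 2.4e-3


class GenerationError(ValueError):
    """Raised when a template configuration cannot be realized."""


@dataclass
class UnitTemplate:
    """Generative description of one unit's burst per swallow cycle.

    The burst is anchored to a stage boundary frame: with ``align="start"``
    it begins at ``anchor_frac`` through stage ``anchor_stage`` (0-based,
    stages I..V); with ``align="end"`` it *ends* there and extends backward,
    which keeps retraction bursts from outlasting the force drop. Under the
    loaded condition ``d_duration`` (s) and ``d_rate`` (Hz) are added.
    Templates sharing ``sync_group`` share one realized span per cycle (the
    functionally grouped retractor pool fires together).
    """

    unit: str
    channel: str
    amplitude: float
    anchor_stage: int
    anchor_frac: float
    duration_mean: float
    duration_sd: float
    rate_mean: float
    rate_sd: float
    d_duration: float = 0.0
    d_rate: float = 0.0
    align: str = "start"
    profile: np.ndarray | None = None
    width_ms: float = 2.0
    sync_group: str | None = None

    def __post_init__(self) -> None:
        if self.duration_mean <= 0 or self.rate_mean < 0:
            raise ValueError("durations must be positive and rates nonnegative")
        if self.align not in ("start", "end"):
            raise ValueError("align must be 'start' or 'end'")
        if not 0 <= self.anchor_stage <= 4:
            raise ValueError("anchor_stage indexes stages I..V (0..4)")


def default_unit_templates() -> list[UnitTemplate]:
    """Study-shaped defaults: protraction units (B38, I2) unchanged by load;
    retraction units prolonged by ~1 s; retractor-pool rate raised by 6 Hz
    (3 Hz per member). Amplitudes separate the three BN2 units."""
    return [
        UnitTemplate("B38", "BN2", 0.30, 0, 0.00, 1.3, 0.20, 10.0, 1.0),
        UnitTemplate("I2", "I2", 1.00, 0, 0.05, 1.5, 0.15, 14.0, 1.0, width_ms=12.0),
        UnitTemplate("B8a/b", "RN", 1.00, 3, 0.95, 2.6, 0.25, 15.0, 1.0,
                     d_duration=1.0, d_rate=1.0, align="end"),
        UnitTemplate("B4/B5", "BN3", 1.00, 3, 0.50, 1.8, 0.25, 12.0, 1.0,
                     d_duration=0.8, d_rate=2.0, align="end"),
        UnitTemplate("B6/B9", "BN2", 0.55, 3, 0.90, 1.7, 0.20, 25.0, 1.0,
                     d_duration=1.0, d_rate=3.0, align="end", sync_group="retractor_pool"),
        UnitTemplate("B3", "BN2", 1.00, 3, 0.90, 1.7, 0.20, 20.0, 1.0,
                     d_duration=1.0, d_rate=3.0, align="end", sync_group="retractor_pool"),
    ]


@dataclass
class SwallowGroundTruth:
    """Bookkeeping for one generated swallow cycle."""

    index: int
    condition: str
    boundaries: np.ndarray            # latent stage frame [e1..e5, v_end]
    cycle_window: tuple[float, float]
    inward_movement: tuple[float, float]
    stage_I_defined: bool
    events: dict[str, float | None] = field(default_factory=dict)
    bursts: dict[str, Burst] = field(default_factory=dict)
    spike_times: dict[str, np.ndarray] = field(default_factory=dict)


def generate_undefined_stage1(fraction: float, n_swallows: int, seed: int) -> np.ndarray:
    """Deterministically flag round(fraction * n) swallows as lacking the
    intermediate force plateau (no events 1-2, stage I undefined)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(round(fraction * n_swallows))
    flags = np.zeros(n_swallows, dtype=bool)
    if k:
        flags[rng.choice(n_swallows, size=k, replace=False)] = True
    return flags


def _spike_times(start: float, duration: float, rate: float, jitter: float,
                 profile: np.ndarray | None, rng: np.random.Generator) -> np.ndarray:
    """Quasi-regular spikes pinned to both burst boundaries.

    N = round(rate * duration) intervals; interior spikes jittered uniformly
    by up to ``jitter`` of the mean interval (time-rescaled through the rate
    profile when one is given), so the realized span is exactly ``duration``
    and the realized mean burst rate is N / duration.
    """
    n_int = max(2, int(round(rate * duration)))
    u = np.linspace(0.0, 1.0, n_int + 1)
    if n_int > 1:
        u[1:-1] += rng.uniform(-jitter, jitter, n_int - 1) / n_int
    if profile is not None:
        p = np.asarray(profile, dtype=float)
        grid = np.linspace(0.0, 1.0, len(p))
        cdf = np.concatenate(([0.0], np.cumsum((p[1:] + p[:-1]) / 2 * np.diff(grid))))
        cdf /= cdf[-1]
        u = np.interp(u, cdf, grid)
    return start + duration * u


def _biphasic(width_ms: float, sample_rate: float) -> np.ndarray:
    """Fixed-shape waveform with its positive peak exactly at the center
    sample and shallow negative side lobes."""
    half = max(2, int(round(width_ms / 2 * 1e-3 * sample_rate)))
    tau = np.arange(-half, half + 1) / half
    return (1.0 - tau ** 2) * np.cos(np.pi * tau * 0.75)


def _nudge_cross_unit(per_unit: dict[str, np.ndarray],
                      min_sep: float = CROSS_UNIT_SEPARATION_S) -> dict[str, np.ndarray]:
    """Shift near-coincident spikes of *different* units on one channel apart."""
    if len(per_unit) < 2:
        return per_unit
    units = list(per_unit)
    times = np.concatenate([per_unit[u] for u in units])
    owner = np.concatenate([np.full(len(per_unit[u]), i) for i, u in enumerate(units)])
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    for i in range(1, len(t_sorted)):
        if t_sorted[i] - t_sorted[i - 1] < min_sep:
            t_sorted[i] = t_sorted[i - 1] + min_sep
    times[order] = t_sorted
    return {u: np.sort(times[owner == i]) for i, u in enumerate(units)}


def generate_session(n_swallows: int, condition: str,
                     templates: list[UnitTemplate] | None = None,
                     noise: dict[str, float] | None = None,
                     seed: int = 0,
                     sample_rate: float = 5000.0,
                     stage_durations: tuple[float, ...] | None = None,
                     stage_jitter_sd: float = 0.06,
                     spike_jitter: float = 0.15,
                     undefined_stage1_fraction: float | None = None,
                     animal: str = "A1",
                     f_max: float = 100.0, f_int: float = 30.0, f_min: float = 2.0,
                     ) -> tuple[Recording, list[SwallowGroundTruth], list[SwallowAnnotation]]:
    """Generate one recording session of ``n_swallows`` cycles.

    Returns the rendered multichannel recording (force channel only for the
    loaded condition), per-swallow ground truth, and behavioral annotations.
    The same seed reproduces the output bit for bit. Stage durations are
    jittered log-normally per cycle; unit bursts are placed from the
    templates. ``undefined_stage1_fraction`` defaults to the study's
    observed 7/39 for loaded sessions and 0 otherwise.
    """
    if n_swallows < 1:
        raise ValueError("n_swallows must be >= 1")
    if condition not in ("unloaded", "loaded"):
        raise ValueError(f"condition must be unloaded/loaded, got {condition!r}")
    templates = templates if templates is not None else default_unit_templates()
    noise_cfg = dict(DEFAULT_NOISE)
    noise_cfg.update(noise or {})
    rng = np.random.default_rng(seed)
    base = np.array(stage_durations if stage_durations is not None
                    else STAGE_DURATIONS[condition], dtype=float)
    loaded = condition == "loaded"
    if undefined_stage1_fraction is None:
        undefined_stage1_fraction = 7.0 / 39.0 if loaded else 0.0
    undefined = generate_undefined_stage1(undefined_stage1_fraction, n_swallows,
                                          seed=int(rng.integers(2 ** 31)))

    lead_flat, lead_fall = 0.25, 0.55
    tail = 0.8
    # latent stage frames: boundaries[k] = [e1, e2, e3, e4, e5, v_end]
    frames = []
    cursor = lead_flat + lead_fall
    for k in range(n_swallows):
        durs = base * np.exp(rng.normal(0.0, stage_jitter_sd, 5))
        bounds = cursor + np.concatenate(([0.0], np.cumsum(durs)))
        frames.append(bounds)
        cursor = bounds[-1]
    total = cursor + tail
    n_samples = int(round(total * sample_rate))
    t_axis = np.arange(n_samples) / sample_rate

    # ---------------------------------------------------------------- spikes
    spike_trains: dict[str, list[np.ndarray]] = {tpl.unit: [] for tpl in templates}
    gt: list[SwallowGroundTruth] = []
    annotations: list[SwallowAnnotation] = []
    for k, b in enumerate(frames):
        # analysis windows start inside the preceding force drop and run just
        # past the stage-V close so every boundary is visible to segmentation
        win_start = frames[k - 1][4] if k > 0 else lead_flat
        win_end = b[5] + 0.25
        inward = (float(b[2]), float(b[4]))
        spans: dict[str, tuple[float, float]] = {}
        cycle_bursts: dict[str, tuple[np.ndarray, float]] = {}
        for tpl in templates:
            if tpl.sync_group is not None and tpl.sync_group in spans:
                start, dur = spans[tpl.sync_group]
            else:
                anchor = b[tpl.anchor_stage] + tpl.anchor_frac * (b[tpl.anchor_stage + 1]
                                                                  - b[tpl.anchor_stage])
                dur = tpl.duration_mean + (tpl.d_duration if loaded else 0.0) \
                    + rng.normal(0.0, tpl.duration_sd)
                dur = float(np.clip(dur, 0.3, None))
                start = anchor - dur if tpl.align == "end" else anchor
                if start < win_start or start + dur > win_end:
                    raise GenerationError(
                        f"{tpl.unit} burst [{start:.2f}, {start + dur:.2f}] leaves "
                        f"cycle window [{win_start:.2f}, {win_end:.2f}] of swallow {k}")
                if tpl.sync_group is not None:
                    spans[tpl.sync_group] = (start, dur)
            rate = tpl.rate_mean + (tpl.d_rate if loaded else 0.0) \
                + rng.normal(0.0, tpl.rate_sd)
            rate = float(np.clip(rate, 2.0, None))
            times = _spike_times(start, dur, rate, spike_jitter, tpl.profile, rng)
            cycle_bursts[tpl.unit] = (times, rate)

        # same-channel cross-unit separation, then ground truth from the
        # realized (possibly nudged) spike times
        by_channel: dict[str, dict[str, np.ndarray]] = {}
        for tpl in templates:
            by_channel.setdefault(tpl.channel, {})[tpl.unit] = cycle_bursts[tpl.unit][0]
        bursts: dict[str, Burst] = {}
        cycle_times: dict[str, np.ndarray] = {}
        for channel, per_unit in by_channel.items():
            for unit, times in _nudge_cross_unit(per_unit).items():
                spike_trains[unit].append(times)
                bursts[unit] = Burst.from_spikes(unit, times)
                cycle_times[unit] = times

        stage_defined = not undefined[k]
        events = {"e1": float(b[0]) if stage_defined else None,
                  "e2": float(b[1]) if stage_defined else None,
                  "e3": float(b[2]), "e4": float(b[3]), "e5": float(b[4]),
                  "v_end": None}
        if loaded:
            next_defined = (k + 1 < n_swallows and not undefined[k + 1]) or k + 1 == n_swallows
            events["v_end"] = float(b[5]) if next_defined else None
        gt.append(SwallowGroundTruth(k, condition, b, (float(win_start), float(win_end)),
                                     inward, stage_defined, events, bursts, cycle_times))
        annotations.append(SwallowAnnotation(animal, condition,
                                             (float(win_start), float(win_end)), inward))

    # ---------------------------------------------------------------- render
    channels: list[Channel] = []
    width_by_unit = {tpl.unit: tpl.width_ms for tpl in templates}
    amp_by_unit = {tpl.unit: tpl.amplitude for tpl in templates}
    chan_units: dict[str, list[str]] = {}
    for tpl in templates:
        chan_units.setdefault(tpl.channel, []).append(tpl.unit)
    layout = list(CHANNELS)
    for name, role in layout:
        sig = rng.normal(0.0, noise_cfg[role], n_samples)
        for unit in chan_units.get(name, []):
            wave = _biphasic(width_by_unit[unit], sample_rate) * amp_by_unit[unit]
            half = len(wave) // 2
            all_times = np.concatenate(spike_trains[unit]) if spike_trains[unit] else np.array([])
            centers = np.round(all_times * sample_rate).astype(int)
            centers = centers[(centers >= half) & (centers < n_samples - half)]
            offsets = np.arange(-half, half + 1)
            np.add.at(sig, (centers[:, None] + offsets[None, :]).ravel(),
                      np.tile(wave, len(centers)))
        channels.append(Channel(name, role, sig))
    if loaded:
        force = _render_force(t_axis, gt, lead_flat, rng,
                              noise_cfg["force"], f_max, f_int, f_min)
        channels.append(Channel(FORCE_CHANNEL[0], FORCE_CHANNEL[1], force))
    rec = Recording(channels, sample_rate=sample_rate, t0=0.0)
    return rec, gt, annotations


def _render_force(t_axis: np.ndarray, gt: list[SwallowGroundTruth],
                  lead_flat: float, rng: np.random.Generator, noise_sd: float,
                  f_max: float, f_int: float, f_min: float) -> np.ndarray:
    """Piecewise-linear force through the five-stage keypoints of each cycle."""
    pts_t: list[float] = [0.0, lead_flat]
    start_level = 0.8 * f_max
    pts_f: list[float] = [start_level, start_level]
    fall_anchor = lead_flat
    for g in gt:
        e1, e2, e3, e4, e5, v_end = g.boundaries
        fmax_k = f_max * float(np.exp(rng.normal(0.0, 0.05)))
        fint_k = f_int * float(np.exp(rng.normal(0.0, 0.08)))
        if g.stage_I_defined:
            pts_t += [e1, e2, e2 + 0.6 * (e3 - e2), e3]
            pts_f += [fint_k, 0.93 * fint_k, f_min, f_min]
        else:
            # smooth decay straight to the minimum: no intermediate plateau
            t_min = fall_anchor + 0.6 * (e3 - fall_anchor)
            pts_t += [t_min, e3]
            pts_f += [f_min, f_min]
        pts_t += [e4, e4 + 0.4 * (e5 - e4), e5]
        pts_f += [0.92 * fmax_k, fmax_k, 0.98 * fmax_k]
        fall_anchor = e5
        last = (e5, 0.98 * fmax_k, fint_k, v_end)
    # close the final drop
    e5, level, fint_k, v_end = last
    end_t = float(t_axis[-1])
    vb = v_end if v_end is not None else gt[-1].boundaries[5]
    pts_t += [vb, end_t]
    pts_f += [fint_k, 0.95 * fint_k]
    force = np.interp(t_axis, np.array(pts_t), np.array(pts_f))
    return force + rng.normal(0.0, noise_sd, len(t_axis))


def generate_paired_table(n_animals: int, base_mean: float, effect: float,
                          between_sd: float, within_sem: float, seed: int,
                          measure: str = "measure", n_per_condition: int = 5):
    """Paired per-animal table with a configured loaded-condition effect.

    Animal baselines vary with SD ``between_sd``; each condition mean adds
    independent noise with SD ``within_sem`` (the sampling error of a
    per-animal mean). Zero noise recovers the effect exactly.
    """
    from .core import PairedAnimalTable

    if n_animals < 2:
        raise ValueError("need at least two animals")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_animals):
        baseline = base_mean + rng.normal(0.0, between_sd)
        u = baseline + rng.normal(0.0, within_sem)
        load = baseline + effect + rng.normal(0.0, within_sem)
        rows.append((str(i + 1), u, load, n_per_condition, n_per_condition))
    return PairedAnimalTable.from_rows(measure, rows)


def perturb_templates(templates: list[UnitTemplate], rng: np.random.Generator,
                      duration_base_sd: float = 0.25, rate_base_sd_frac: float = 0.15,
                      duration_effect_sd: float = 0.40, rate_effect_sd: float = 1.65,
                      ) -> list[UnitTemplate]:
    """Animal-level template variation: baseline offsets plus per-animal
    variation of the load effects. Offsets are shared within a sync group so
    pooled units keep a common span; effect SDs default to the spread implied
    by the study's between-animal difference SEMs."""
    shared: dict[str, tuple[float, float, float]] = {}
    out = []
    for tpl in templates:
        key = tpl.sync_group
        if key is not None and key in shared:
            d_base, d_eff, r_eff = shared[key]
        else:
            d_base = rng.normal(0.0, duration_base_sd)
            d_eff = rng.normal(0.0, duration_effect_sd) if tpl.d_duration else 0.0
            r_eff = rng.normal(0.0, rate_effect_sd) if tpl.d_rate else 0.0
            if key is not None:
                shared[key] = (d_base, d_eff, r_eff)
        r_base = rng.normal(0.0, rate_base_sd_frac * tpl.rate_mean)
        out.append(replace(
            tpl,
            duration_mean=float(np.clip(tpl.duration_mean + d_base, 0.5, None)),
            rate_mean=float(np.clip(tpl.rate_mean + r_base, 4.0, None)),
            d_duration=tpl.d_duration + d_eff,
            d_rate=tpl.d_rate + r_eff,
        ))
    return out
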