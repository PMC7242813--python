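"""Reference per-animal summary data from the loaded-swallowing study.

Five *Aplysia californica* swallowed free (unloaded) and anchored,
unbreakable (loaded) seaweed strips while nerve, EMG, and force signals were
recorded. Each entry is the per-animal mean of a behavioral or burst measure
under each condition, with the per-condition number of swallows — the input
shape of the paired statistical battery. Values are as published (rounded to
two decimals), so statistics recomputed from them can differ from the
originals, which used unrounded per-swallow data, in the last digit or by a
fraction of a percent.

Units: durations in seconds, firing frequencies in hertz.
"""

from __future__ import annotations

from .core import PairedAnimalTable

# measure -> list of (animal, unloaded mean, loaded mean, n_unloaded, n_loaded)
_BEHAVIOR = {
    "total cycle time": [
        ("1", 5.45, 6.91, 4, 4),
        ("2", 5.97, 7.48, 4, 12),
        ("3", 4.76, 7.80, 4, 4),
        ("4", 4.65, 6.39, 3, 7),
        ("5", 6.48, 6.99, 6, 4),
    ],
    "inward movement duration": [
        ("1", 1.35, 3.00, 4, 5),
        ("2", 2.83, 3.55, 4, 15),
        ("3", 2.02, 2.80, 4, 5),
        ("4", 1.95, 2.75, 4, 9),
        ("5", 1.56, 2.68, 7, 5),
    ],
    "between inward movements duration": [
        ("1", 4.10, 3.83, 4, 4),
        ("2", 3.15, 3.80, 4, 12),
        ("3", 2.74, 5.05, 4, 4),
        ("4", 2.78, 3.51, 3, 7),
        ("5", 4.89, 4.66, 6, 4),
    ],
}

_DURATION = {
    "B38 duration": [
        ("1", 1.44, 1.72, 10, 5),
        ("2", 1.92, 1.81, 6, 15),
        ("3", 0.50, 0.49, 6, 5),
        ("4", 0.94, 1.51, 6, 9),
        ("5", 1.45, 1.24, 11, 5),
    ],
    "I2 duration": [
        ("1", 1.46, 1.12, 10, 5),
        ("2", 1.63, 1.83, 6, 15),
        ("3", 1.61, 1.36, 6, 5),
        ("4", 1.58, 1.16, 6, 9),
        ("5", 1.68, 1.12, 11, 5),
    ],
    "B8a/b duration": [
        ("1", 3.13, 3.99, 10, 5),
        ("2", 3.58, 4.31, 6, 15),
        ("3", 2.73, 4.31, 6, 5),
        ("4", 2.86, 4.07, 6, 9),
        ("5", 3.34, 3.70, 11, 5),
    ],
    "B3/B6/B9 duration": [
        ("1", 1.87, 2.77, 10, 5),
        ("2", 1.66, 2.71, 6, 15),
        ("3", 1.38, 3.14, 6, 5),
        ("4", 1.72, 2.98, 6, 9),
        ("5", 2.01, 2.67, 11, 5),
    ],
    "B4/B5 duration": [
        ("1", 1.58, 1.84, 10, 5),
        ("2", 2.07, 3.09, 6, 15),
        ("3", 0.00, 0.65, 6, 5),
        ("4", 1.79, 3.25, 6, 9),
        ("5", 2.85, 3.36, 11, 5),
    ],
}

_FREQUENCY = {
    "B38 frequency": [
        ("1", 10.95, 10.57, 10, 5),
        ("2", 10.44, 11.40, 6, 15),
        ("3", 4.50, 3.35, 6, 5),
        ("4", 11.88, 13.57, 6, 9),
        ("5", 7.41, 9.04, 11, 5),
    ],
    "I2 frequency": [
        ("1", 15.17, 15.71, 10, 5),
        ("2", 12.33, 12.43, 6, 15),
        ("3", 12.80, 15.66, 6, 5),
        ("4", 15.37, 16.15, 6, 9),
        ("5", 12.92, 14.68, 11, 5),
    ],
    "B8a/b frequency": [
        ("1", 12.00, 12.20, 10, 5),
        ("2", 18.22, 22.91, 6, 15),
        ("3", 21.61, 23.40, 6, 5),
        ("4", 22.20, 21.46, 6, 9),
        ("5", 10.32, 12.32, 11, 5),
    ],
    "B3/B6/B9 frequency": [
        ("1", 38.99, 42.27, 10, 5),
        ("2", 14.79, 16.59, 6, 15),
        ("3", 27.85, 37.90, 6, 5),
        ("4", 30.40, 37.87, 6, 9),
        ("5", 9.12, 15.66, 11, 5),
    ],
    "B4/B5 frequency": [
        ("1", 21.29, 17.57, 10, 5),
        ("2", 7.43, 9.27, 6, 15),
        ("3", 0.00, 3.44, 6, 5),
        ("4", 10.47, 13.81, 6, 9),
        ("5", 13.97, 17.85, 11, 5),
    ],
}

#: Published difference-column means (loaded - unloaded, mean over animals),
#: on the published rounding; used by validation checks.
PUBLISHED_DIFFERENCES = {
    "total cycle time": 1.65,
    "inward movement duration": 1.01,
    "between inward movements duration": 0.64,
    "B38 duration": 0.11,
    "I2 duration": -0.28,
    "B8a/b duration": 0.95,
    "B3/B6/B9 duration": 1.12,
    "B4/B5 duration": 0.78,
    "B38 frequency": 0.55,
    "I2 frequency": 1.21,
    "B8a/b frequency": 1.59,
    "B3/B6/B9 frequency": 5.82,
    "B4/B5 frequency": 1.75,
}


def _tables(raw: dict) -> dict[str, PairedAnimalTable]:
    return {m: PairedAnimalTable.from_rows(m, rows) for m, rows in raw.items()}


def behavioral_durations() -> dict[str, PairedAnimalTable]:
    """Cycle time, inward-movement, and between-inward-movement durations (s)."""
    return _tables(_BEHAVIOR)


def burst_durations() -> dict[str, PairedAnimalTable]:
    """Per-unit burst durations (s)."""
    return _tables(_DURATION)


def burst_frequencies() -> dict[str, PairedAnimalTable]:
    """Per-unit mean firing frequencies during bursts (Hz)."""
    return _tables(_FREQUENCY)


def all_tables() -> dict[str, PairedAnimalTable]:
    return {**behavioral_durations(), **burst_durations(), **burst_frequencies()}
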