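"""Force-to-tone mapping and the feedback-gain uncertainty ladder.

Subjects track a constant 20 N target by listening to a tracking tone whose
frequency and/or intensity deviate from a fixed reference tone (1000 Hz,
70 dB) in proportion to the force error.  The proportionality constant — the
feedback gain — sets how perceptible a given force error is: a large gain
makes errors salient (low uncertainty), a small gain hides them (high
uncertainty).  Four gains per channel span the ladder from the
just-noticeable-difference baseline to the gain giving maximum performance,
in equal log-scale increments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

#: Feedback modes: frequency only, intensity only, both.
MODES = ("F", "I", "FI")

#: Uncertainty levels, from low (largest gain) to high (baseline gain).
UNCERTAINTY_LEVELS = ("L", "ML", "MH", "H")

#: Frequency-modulation gains (Hz/N) per uncertainty level.
DEFAULT_FREQ_GAINS: Mapping[str, float] = {"L": 300.0, "ML": 86.0, "MH": 24.0, "H": 7.0}

#: Intensity-modulation gains (dB/N) per uncertainty level.  Stored verbatim;
#: unlike the frequency ladder these are not exactly log-uniform.
DEFAULT_INTENSITY_GAINS: Mapping[str, float] = {"L": 7.5, "ML": 3.0, "MH": 1.2, "H": 0.7}


@dataclass(frozen=True)
class ConditionSpec:
    """One feedback condition: mode, uncertainty level and tone parameters.

    Parameters
    ----------
    mode
        ``"F"`` (frequency), ``"I"`` (intensity) or ``"FI"`` (both).
    uncertainty
        ``"L"``, ``"ML"``, ``"MH"`` or ``"H"``.
    freq_gain
        Frequency-modulation gain in Hz/N; required when mode uses frequency.
    intensity_gain
        Intensity-modulation gain in dB/N; required when mode uses intensity.
    target_force
        Reference force f_T in newtons (default 20).
    reference_freq, reference_level
        Parameters of the reference tone (default 1000 Hz, 70 dB).
    """

    mode: str
    uncertainty: str
    freq_gain: float | None = None
    intensity_gain: float | None = None
    target_force: float = 20.0
    reference_freq: float = 1000.0
    reference_level: float = 70.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown feedback mode {self.mode!r}; expected one of {MODES}")
        if self.uncertainty not in UNCERTAINTY_LEVELS:
            raise ValueError(
                f"unknown uncertainty level {self.uncertainty!r}; "
                f"expected one of {UNCERTAINTY_LEVELS}"
            )
        if self.uses_frequency:
            if self.freq_gain is None:
                raise ValueError(f"mode {self.mode!r} requires freq_gain")
            if self.freq_gain <= 0:
                raise ValueError("freq_gain must be strictly positive")
        if self.uses_intensity:
            if self.intensity_gain is None:
                raise ValueError(f"mode {self.mode!r} requires intensity_gain")
            if self.intensity_gain <= 0:
                raise ValueError("intensity_gain must be strictly positive")

    @property
    def uses_frequency(self) -> bool:
        return self.mode in ("F", "FI")

    @property
    def uses_intensity(self) -> bool:
        return self.mode in ("I", "FI")


def force_to_tone(force: float, cond: ConditionSpec) -> tuple[float, float]:
    """Map a produced force to the tracking-tone ``(frequency, level)``.

    Each modulated channel is affine in the force deviation from the target:
    frequency = reference + gain_f * (force - f_T) and analogously for the
    level in dB.  Unmodulated channels stay at the reference tone, so at
    ``force == target_force`` the tracking tone equals the reference tone in
    every mode.
    """
    if not np.isfinite(force):
        raise ValueError("force must be finite")
    deviation = force - cond.target_force
    freq = cond.reference_freq
    level = cond.reference_level
    if cond.uses_frequency:
        if cond.freq_gain is None:  # defensive; normally caught at construction
            raise ValueError(f"mode {cond.mode!r} requires freq_gain")
        freq = freq + cond.freq_gain * deviation
    if cond.uses_intensity:
        if cond.intensity_gain is None:
            raise ValueError(f"mode {cond.mode!r} requires intensity_gain")
        level = level + cond.intensity_gain * deviation
    return freq, level


def log_spaced_gains(baseline: float, maximum: float, n_levels: int) -> np.ndarray:
    """Gain ladder with equal increments in log scale.

    Returns ``g_k = baseline * (maximum / baseline) ** (k / (n_levels - 1))``
    for ``k = 0 .. n_levels - 1``, ascending.  The frequency ladder of the
    default catalogue is this rule applied to (7, 300) Hz/N over four levels,
    rounded to integers.
    """
    if not (0 < baseline < maximum):
        raise ValueError("require 0 < baseline < maximum")
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    return np.geomspace(baseline, maximum, n_levels)


def condition_catalogue(
    freq_gains: Mapping[str, float] | None = None,
    intensity_gains: Mapping[str, float] | None = None,
    target_force: float = 20.0,
    reference_freq: float = 1000.0,
    reference_level: float = 70.0,
) -> dict[tuple[str, str], ConditionSpec]:
    """Full 3 mode x 4 uncertainty-level condition catalogue.

    Uncertainty maps to descending gain: ``L`` gets the largest gain of each
    ladder, ``H`` the baseline, because a larger gain makes a given force
    error more perceptible.
    """
    freq_gains = dict(DEFAULT_FREQ_GAINS if freq_gains is None else freq_gains)
    intensity_gains = dict(
        DEFAULT_INTENSITY_GAINS if intensity_gains is None else intensity_gains
    )
    catalogue: dict[tuple[str, str], ConditionSpec] = {}
    for mode in MODES:
        for level in UNCERTAINTY_LEVELS:
            catalogue[(mode, level)] = ConditionSpec(
                mode=mode,
                uncertainty=level,
                freq_gain=freq_gains[level] if mode in ("F", "FI") else None,
                intensity_gain=intensity_gains[level] if mode in ("I", "FI") else None,
                target_force=target_force,
                reference_freq=reference_freq,
                reference_level=reference_level,
            )
    return catalogue


def catalogue_to_dict(catalogue: Mapping[tuple[str, str], ConditionSpec]) -> dict:
    """Serialise a condition catalogue to plain nested dicts (YAML/JSON safe)."""
    out: dict = {}
    for (mode, level), cond in catalogue.items():
        out.setdefault(mode, {})[level] = {
            "freq_gain": cond.freq_gain,
            "intensity_gain": cond.intensity_gain,
            "target_force": cond.target_force,
            "reference_freq": cond.reference_freq,
            "reference_level": cond.reference_level,
        }
    return out


def catalogue_from_dict(data: Mapping) -> dict[tuple[str, str], ConditionSpec]:
    """Inverse of :func:`catalogue_to_dict`."""
    catalogue: dict[tuple[str, str], ConditionSpec] = {}
    for mode, levels in data.items():
        for level, kw in levels.items():
            catalogue[(mode, level)] = ConditionSpec(mode=mode, uncertainty=level, **kw)
    return catalogue
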