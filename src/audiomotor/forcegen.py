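"""Synthetic multi-finger force trials with controlled error structure.

Trials are generated by the same three-component model the decomposition in
:mod:`audiomotor.hvd` assumes: a constant per-finger mean profile, a
per-trial Gaussian offset vector (the offline, trial-to-trial error, with a
configurable 4x4 covariance) and band-limited Gaussian noise within the
trial (the online error, with its own 4x4 covariance).  Negative
off-diagonal covariance entries produce synergistic finger covariation that
attenuates the virtual-finger error, as observed in real multi-finger
pressing.

The online noise is white Gaussian noise coloured by a second-order low-pass
Butterworth filter (default cutoff 8 Hz, the physiological force-tremor
band), then demeaned and rescaled per column to unit sample variance before
mixing through a factor of the target covariance — so the empirical
within-trial covariance converges to the requested matrix and per-finger
variances are matched essentially exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from audiomotor.feedback import ConditionSpec
from audiomotor.hvd import TrialRecording

_PSD_TOL = 1e-10


def _check_cov(cov: np.ndarray, name: str) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    scale = max(abs(eigvals).max(), 1.0)
    if eigvals.min() < -_PSD_TOL * scale:
        raise ValueError(f"{name} must be positive semi-definite")
    return cov


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Matrix A with A @ A.T == cov; Cholesky with an eigendecomposition
    fallback for PSD-but-singular matrices."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one subject-by-condition trial set.

    Parameters
    ----------
    finger_means
        Per-finger mean forces in N; their sum is the mean VF force, so a
        sum different from the 20 N target induces a systematic error.
    offline_cov, online_cov
        4x4 symmetric PSD covariance matrices (N^2) of the between-trial
        offset vectors and of the within-trial noise.
    noise_cutoff
        Low-pass cutoff of the online noise in Hz (must be below Nyquist).
    n_trials, duration, sample_rate
        Trial-set geometry; ``duration * sample_rate`` must be a positive
        integer number of samples.
    seed
        Non-negative integer; the single source of randomness.  Per-trial
        substreams are derived from ``(seed, trial_index)`` so increasing
        ``n_trials`` never perturbs earlier trials.
    """

    finger_means: np.ndarray
    offline_cov: np.ndarray
    online_cov: np.ndarray
    noise_cutoff: float = 8.0
    n_trials: int = 5
    duration: float = 20.0
    sample_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.atleast_1d(np.asarray(self.finger_means, dtype=float))
        if means.ndim != 1:
            raise ValueError("finger_means must be a 1-D vector")
        k = means.size
        off = _check_cov(self.offline_cov, "offline_cov")
        on = _check_cov(self.online_cov, "online_cov")
        if off.shape != (k, k) or on.shape != (k, k):
            raise ValueError("covariance shapes must match the finger count")
        if not 0 < self.noise_cutoff < self.sample_rate / 2:
            raise ValueError("noise_cutoff must lie in (0, sample_rate / 2)")
        if self.n_trials < 2:
            raise ValueError("n_trials must be at least 2")
        n = self.duration * self.sample_rate
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("duration * sample_rate must be a positive integer")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        object.__setattr__(self, "finger_means", means)
        object.__setattr__(self, "offline_cov", off)
        object.__setattr__(self, "online_cov", on)

    @property
    def n_fingers(self) -> int:
        return self.finger_means.size

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


def make_band_limited_noise(
    n_samples: int,
    sample_rate: float,
    cutoff: float,
    cov: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean band-limited Gaussian noise with target covariance ``cov``.

    White Gaussian columns are low-pass filtered (second-order Butterworth,
    zero phase), demeaned, rescaled to unit sample variance, and mixed
    through a factor of ``cov``.  Per-column sample variances therefore hit
    the diagonal of ``cov`` exactly; cross-covariances converge to the
    off-diagonal entries as ``n_samples`` grows.  Deterministic given the
    generator state.
    """
    cov = _check_cov(cov, "cov")
    if not 0 < cutoff < sample_rate / 2:
        raise ValueError("cutoff must lie in (0, sample_rate / 2)")
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    k = cov.shape[0]
    white = rng.standard_normal((n_samples, k))
    if not np.any(cov):
        return np.zeros((n_samples, k))
    sos = signal.butter(2, cutoff, fs=sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, white, axis=0)
    filtered = filtered - filtered.mean(axis=0)
    std = filtered.std(axis=0)
    std[std == 0] = 1.0  # degenerate column: leave at zero
    z = filtered / std
    return z @ _cov_factor(cov).T


def simulate_trial(
    spec: SyntheticSpec,
    trial_offsets: np.ndarray,
    rng: np.random.Generator,
    subject_id: str | None = None,
    condition: ConditionSpec | None = None,
) -> TrialRecording:
    """One trial: finger means + the trial's offset vector + online noise."""
    trial_offsets = np.asarray(trial_offsets, dtype=float)
    if trial_offsets.shape != (spec.n_fingers,):
        raise ValueError("trial_offsets must be one value per finger")
    noise = make_band_limited_noise(
        spec.n_samples, spec.sample_rate, spec.noise_cutoff, spec.online_cov, rng
    )
    forces = spec.finger_means + trial_offsets + noise
    return TrialRecording(
        forces=forces,
        sample_rate=spec.sample_rate,
        t0=0.0,
        subject_id=subject_id,
        condition=condition,
    )


def simulate_trial_set(
    spec: SyntheticSpec,
    subject_id: str | None = None,
    condition: ConditionSpec | None = None,
) -> list[TrialRecording]:
    """Generate ``spec.n_trials`` trials with correlated per-trial offsets.

    Offset vectors are drawn from a zero-mean Gaussian with covariance
    ``spec.offline_cov``.  Trial *k* consumes only the substream seeded by
    ``(spec.seed, k)``, so trial sets are bit-reproducible and extending the
    set leaves existing trials untouched.
    """
    offline_factor = _cov_factor(spec.offline_cov)
    trials = []
    for k in range(spec.n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, k]))
        offsets = offline_factor @ rng.standard_normal(spec.n_fingers)
        trials.append(simulate_trial(spec, offsets, rng, subject_id, condition))
    return trials
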