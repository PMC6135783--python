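"""Hierarchical variability decomposition (HVD) of multi-finger force error.

The virtual-finger (VF) force of trial *i* — the sum of the individual-finger
(IF) forces — is modelled as

    y_i(t) = X_i(t) + E_i + m

where ``m`` is the grand-mean VF force over all samples of all trials,
``E_i`` is the deviation of trial *i*'s mean from ``m`` (the offline,
trial-to-trial error) and ``X_i(t)`` is the within-trial demeaned trace (the
online, moment-to-moment error).  The overall mean-squared error against the
target force f_T then splits exactly into

    OMSE = SE + VE_ON + VE_OFF,
    SE     = (f_T - m)^2              (squared bias),
    VE_ON  = mean_i Var_t[X_i(t)]     (online variable error),
    VE_OFF = Var_i[E_i]               (offline variable error),

and each variable error splits at the IF level into the sum of per-finger
variances plus the sum of between-finger covariances over ordered pairs:

    VE_ON  = Var_ON + Cov_ON,   VE_OFF = Var_OFF + Cov_OFF.

Negative covariance terms indicate error-attenuating finger covariation
(motor synergy); positive terms amplify the VF error.  The covariance
indices are algebraically equivalent to uncontrolled-manifold (UCM) synergy
indices for this task.

All moments are population moments (divide by the count, not count - 1):
that convention is what makes the decomposition an exact finite-sample
identity rather than an asymptotic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from audiomotor.feedback import ConditionSpec

#: Default analysis window (seconds): skips initial force stabilisation and
#: premature release at the trial end.
DEFAULT_WINDOW = (6.0, 15.0)


@dataclass(frozen=True)
class TrialRecording:
    """One trial's finger-force time series.

    Parameters
    ----------
    forces
        ``(n_samples, n_fingers)`` array of forces in newtons; columns are
        index, middle, ring, little by convention.
    sample_rate
        Sampling rate in Hz.
    t0
        Time of the first sample relative to trial onset, in seconds.
    subject_id, condition
        Optional provenance labels.
    """

    forces: np.ndarray
    sample_rate: float
    t0: float = 0.0
    subject_id: str | None = None
    condition: ConditionSpec | None = None

    def __post_init__(self) -> None:
        forces = np.asarray(self.forces, dtype=float)
        if forces.ndim != 2:
            raise ValueError("forces must be a 2-D (samples x fingers) array")
        if forces.shape[0] < 2:
            raise ValueError("a trial needs at least 2 samples")
        if not np.all(np.isfinite(forces)):
            raise ValueError("forces must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "forces", forces)

    @property
    def n_samples(self) -> int:
        return self.forces.shape[0]

    @property
    def n_fingers(self) -> int:
        return self.forces.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds (sample count / rate)."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds, relative to trial onset."""
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class HVDResult:
    """Full error decomposition of one subject-by-condition trial set.

    All error components are in N^2; ``grand_mean`` and ``bias`` in N.
    ``trial_offsets`` holds the per-trial offline errors E_i in trial order.
    """

    omse: float
    ve: float
    se: float
    ve_on: float
    ve_off: float
    var_on: float
    cov_on: float
    var_off: float
    cov_off: float
    grand_mean: float
    bias: float
    trial_offsets: np.ndarray = field(repr=False)
    n_trials: int = 0
    n_fingers: int = 0


def vf_force(trial: TrialRecording) -> np.ndarray:
    """Virtual-finger force: the row-wise sum of the IF forces."""
    return trial.forces.sum(axis=1)


def extract_window(
    trial: TrialRecording,
    start: float = DEFAULT_WINDOW[0],
    end: float = DEFAULT_WINDOW[1],
) -> TrialRecording:
    """Half-open time window ``[start, end)`` of a trial.

    The default window keeps the 9 s from 6 to 15 s of a 20-s trial (9000
    samples at 1 kHz), the steadiest stretch of a constant-force trial.
    """
    if start >= end:
        raise ValueError(f"empty window: start {start} >= end {end}")
    eps = 1e-9 * trial.sample_rate
    i0 = int(np.ceil((start - trial.t0) * trial.sample_rate - eps))
    i1 = int(np.ceil((end - trial.t0) * trial.sample_rate - eps))
    if i0 < 0 or i1 > trial.n_samples:
        raise ValueError(
            f"window [{start}, {end}) s outside recording "
            f"[{trial.t0}, {trial.t0 + trial.duration}) s"
        )
    return replace(
        trial,
        forces=trial.forces[i0:i1],
        t0=trial.t0 + i0 / trial.sample_rate,
    )


def _stack(trials: Sequence[TrialRecording]) -> np.ndarray:
    if len(trials) < 2:
        raise ValueError("decomposition needs at least 2 trials")
    shapes = {t.forces.shape for t in trials}
    if len(shapes) != 1:
        raise ValueError(f"trials have inconsistent shapes: {sorted(shapes)}")
    return np.stack([t.forces for t in trials])  # (n_trials, n_samples, n_fingers)


def omse_direct(trials: Sequence[TrialRecording], f_T: float = 20.0) -> float:
    """Brute-force OMSE: mean of ``(f_T - y)^2`` over every sample of every trial.

    Computed straight from the definition, independently of the hierarchical
    decomposition; serves as the oracle for the conservation identity.
    """
    forces = _stack(trials)
    y = forces.sum(axis=2)
    return float(((f_T - y) ** 2).mean())


def decompose(trials: Sequence[TrialRecording], f_T: float = 20.0) -> HVDResult:
    """Hierarchical variability decomposition of a trial set.

    Every component is evaluated from its own definition (no component is
    derived as a residual of another), so the identities
    ``omse == se + ve_on + ve_off``, ``ve_on == var_on + cov_on`` and
    ``ve_off == var_off + cov_off`` are genuine floating-point checks.
    Requires equally long trials with equal finger counts.
    """
    forces = _stack(trials)  # (n_trials, n_samples, n_fingers)
    n_trials, n_samples, n_fingers = forces.shape

    y = forces.sum(axis=2)  # VF force, (n_trials, n_samples)
    trial_means = y.mean(axis=1)
    m = float(trial_means.mean())
    offsets = trial_means - m  # E_i
    x_vf = y - trial_means[:, None]  # X_i(t)

    ve_on = float((x_vf**2).mean(axis=1).mean())
    ve_off = float((offsets**2).mean())
    bias = f_T - m
    se = bias**2
    omse = float(((f_T - y) ** 2).mean())

    # IF level, online: within-trial demeaned finger traces.
    finger_trial_means = forces.mean(axis=1)  # (n_trials, n_fingers)
    x_if = forces - finger_trial_means[:, None, :]
    var_on_per_trial = (x_if**2).mean(axis=1)  # (n_trials, n_fingers)
    var_on = float(var_on_per_trial.sum(axis=1).mean())
    # Ordered-pair covariance sum per trial: full Gram sum minus the diagonal.
    gram_on = np.einsum("tsi,tsj->tij", x_if, x_if) / n_samples
    cov_on = float(
        (gram_on.sum(axis=(1, 2)) - np.trace(gram_on, axis1=1, axis2=2)).mean()
    )

    # IF level, offline: per-trial finger means about the finger grand means.
    e_if = finger_trial_means - finger_trial_means.mean(axis=0)  # (n_trials, n_fingers)
    cov_off_mat = e_if.T @ e_if / n_trials
    var_off = float(np.trace(cov_off_mat))
    cov_off = float(cov_off_mat.sum() - np.trace(cov_off_mat))

    return HVDResult(
        omse=omse,
        ve=ve_on + ve_off,
        se=se,
        ve_on=ve_on,
        ve_off=ve_off,
        var_on=var_on,
        cov_on=cov_on,
        var_off=var_off,
        cov_off=cov_off,
        grand_mean=m,
        bias=bias,
        trial_offsets=offsets,
        n_trials=n_trials,
        n_fingers=n_fingers,
    )
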