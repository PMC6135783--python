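"""Study orchestration: window, decompose, predict, compare, summarise.

A *study* is a mapping ``(subject, mode, uncertainty) -> list of trials``
with modes F, I, FI and uncertainty levels L, ML, MH, H.  The pipeline
windows each trial, runs the hierarchical variability decomposition per
subject-by-condition cell, feeds the unimodal (F, I) results to the
cue-integration model, and tests observed FI performance against the
prediction with a paired bootstrap per uncertainty level and component.

Transforms (log / log-modulus) are applied only when summarising across
subjects; the integration model always operates on raw variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from audiomotor import io as amio
from audiomotor.bayes import UnimodalEstimate, predict_omse
from audiomotor.feedback import (
    MODES,
    UNCERTAINTY_LEVELS,
    condition_catalogue,
)
from audiomotor.forcegen import SyntheticSpec, simulate_trial_set
from audiomotor.hvd import DEFAULT_WINDOW, TrialRecording, decompose, extract_window
from audiomotor.resample import (
    PairedSample,
    bootstrap_paired_test,
    log_modulus,
    log_transform,
)

#: HVD components that are strictly positive and log-transformed in summaries.
LOG_COMPONENTS = ("omse", "ve", "se", "ve_on", "ve_off", "var_on", "var_off")
#: Signed synergy indices, summarised after the log-modulus transform.
LOG_MODULUS_COMPONENTS = ("cov_on", "cov_off")
ALL_COMPONENTS = LOG_COMPONENTS + LOG_MODULUS_COMPONENTS

TrialSets = Mapping[tuple[str, str, str], Sequence[TrialRecording]]


@dataclass(frozen=True)
class StudyLayout:
    """Geometry of a study on disk or in memory."""

    subjects: tuple[str, ...]
    modes: tuple[str, ...] = MODES
    uncertainties: tuple[str, ...] = UNCERTAINTY_LEVELS
    trials_per_condition: int = 5
    window: tuple[float, float] | None = DEFAULT_WINDOW
    f_T: float = 20.0

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("a study needs at least one subject")


@dataclass(frozen=True)
class StudyResult:
    """Tidy outputs of a full study run."""

    hvd: pd.DataFrame
    comparison: pd.DataFrame
    summary: pd.DataFrame


def load_study(root: str | Path, layout: StudyLayout) -> dict[tuple[str, str, str], list[TrialRecording]]:
    """Read every subject-by-condition trial directory under ``root``."""
    root = Path(root)
    catalogue = condition_catalogue(target_force=layout.f_T)
    trialsets: dict[tuple[str, str, str], list[TrialRecording]] = {}
    for subject in layout.subjects:
        for mode in layout.modes:
            for level in layout.uncertainties:
                directory = root / subject / amio.condition_dirname(mode, level)
                trials = amio.read_condition_dir(
                    directory, subject_id=subject, condition=catalogue.get((mode, level))
                )
                if len(trials) != layout.trials_per_condition:
                    raise ValueError(
                        f"{directory}: expected {layout.trials_per_condition} trials, "
                        f"found {len(trials)}"
                    )
                trialsets[(subject, mode, level)] = trials
    return trialsets


def decompose_study(
    trialsets: TrialSets,
    window: tuple[float, float] | None = DEFAULT_WINDOW,
    f_T: float = 20.0,
) -> pd.DataFrame:
    """One HVD row per subject-by-condition cell (after windowing)."""
    if not trialsets:
        raise ValueError("empty study: no trial sets")
    rows = []
    for (subject, mode, level), trials in sorted(trialsets.items()):
        if window is not None:
            trials = [extract_window(t, *window) for t in trials]
        res = decompose(trials, f_T=f_T)
        rows.append(
            {
                "subject": subject,
                "mode": mode,
                "uncertainty": level,
                **{c: getattr(res, c) for c in ALL_COMPONENTS},
                "grand_mean": res.grand_mean,
                "bias": res.bias,
                "n_trials": res.n_trials,
                "n_fingers": res.n_fingers,
            }
        )
    frame = pd.DataFrame(rows)
    order = {u: k for k, u in enumerate(UNCERTAINTY_LEVELS)}
    return frame.sort_values(
        ["subject", "uncertainty", "mode"],
        key=lambda s: s.map(order) if s.name == "uncertainty" else s,
        ignore_index=True,
    )


def _predicted_components(row_f: pd.Series, row_i: pd.Series) -> dict[str, float]:
    f = UnimodalEstimate(variance=row_f["ve"], bias=row_f["bias"], label="F")
    i = UnimodalEstimate(variance=row_i["ve"], bias=row_i["bias"], label="I")
    pred = predict_omse(f, i)
    return {"omse": pred.omse, "ve": pred.variance, "se": pred.bias**2}


def bayes_compare(
    hvd_table: pd.DataFrame,
    components: Sequence[str] = ("omse", "ve", "se"),
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "studentized",
) -> pd.DataFrame:
    """Observed FI vs. Bayesian-predicted components, per uncertainty level.

    The unimodal variance fed to the model is each subject's total variable
    error (VE = VE_ON + VE_OFF) and the bias is f_T minus the subject's
    grand-mean force, both taken from the F and I rows of ``hvd_table``.
    Predictions are made per subject, then compared with that subject's
    observed FI values by a paired bootstrap.  Bootstrap seeds are derived
    deterministically from ``seed`` per (uncertainty, component) cell.
    """
    unknown = set(components) - {"omse", "ve", "se"}
    if unknown:
        raise ValueError(f"unknown comparison components: {sorted(unknown)}")
    levels = [u for u in UNCERTAINTY_LEVELS if u in set(hvd_table["uncertainty"])]
    rows = []
    child_seeds = iter(
        int(s.generate_state(1)[0] & 0x7FFFFFFF)
        for s in np.random.SeedSequence(seed).spawn(len(levels) * len(components))
    )
    for level in levels:
        sub = hvd_table[hvd_table["uncertainty"] == level]
        by_mode = {
            mode: sub[sub["mode"] == mode].set_index("subject") for mode in MODES
        }
        subjects = sorted(
            set(by_mode["F"].index) & set(by_mode["I"].index) & set(by_mode["FI"].index)
        )
        if len(subjects) < 2:
            raise ValueError(
                f"uncertainty level {level!r}: need >= 2 subjects with all of F, I, FI"
            )
        observed = {c: [] for c in components}
        predicted = {c: [] for c in components}
        for subject in subjects:
            pred = _predicted_components(
                by_mode["F"].loc[subject], by_mode["I"].loc[subject]
            )
            for c in components:
                observed[c].append(by_mode["FI"].loc[subject, c])
                predicted[c].append(pred[c])
        for c in components:
            pair = PairedSample(observed[c], predicted[c], label=c.upper())
            res = bootstrap_paired_test(
                pair, n_boot=n_boot, seed=next(child_seeds), method=method
            )
            rows.append(
                {
                    "uncertainty": level,
                    "component": c,
                    "n_subjects": len(subjects),
                    "observed_mean": float(np.mean(observed[c])),
                    "predicted_mean": float(np.mean(predicted[c])),
                    "mean_difference": res.mean_difference,
                    "p_value": res.p_value,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n_boot": res.n_boot,
                    "seed": res.seed,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)


def summarize(
    hvd_table: pd.DataFrame,
    transform: bool = True,
    base: float = 10.0,
    components: Sequence[str] = ALL_COMPONENTS,
) -> pd.DataFrame:
    """Across-subject mean and SEM per mode-by-uncertainty cell.

    With ``transform=True`` the strictly positive components are
    log-transformed and the signed covariance indices log-modulus
    transformed before averaging, as is standard for these skewed
    quantities.  SEM is the sample standard deviation over subjects divided
    by sqrt(n); at least two subjects are required.
    """
    rows = []
    for (mode, level), cell in hvd_table.groupby(["mode", "uncertainty"]):
        n = cell["subject"].nunique()
        if n < 2:
            raise ValueError("SEM is undefined with fewer than 2 subjects")
        for c in components:
            values = cell[c].to_numpy(dtype=float)
            if transform:
                if c in LOG_MODULUS_COMPONENTS:
                    values = log_modulus(values, base=base)
                else:
                    values = log_transform(values, base=base)
            rows.append(
                {
                    "mode": mode,
                    "uncertainty": level,
                    "component": c,
                    "mean": float(np.mean(values)),
                    "sem": float(np.std(values, ddof=1) / np.sqrt(n)),
                    "n_subjects": int(n),
                    "transformed": bool(transform),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic studies


def correlated_cov(variance: float, correlation: float, n_fingers: int = 4) -> np.ndarray:
    """Equicorrelated covariance matrix (requires correlation >= -1/(n-1))."""
    if correlation < -1.0 / (n_fingers - 1) or correlation > 1.0:
        raise ValueError("correlation outside the positive semi-definite range")
    cov = np.full((n_fingers, n_fingers), correlation * variance)
    np.fill_diagonal(cov, variance)
    return cov


#: Mean finger-force profile (N); index and middle carry more load.
DEFAULT_FINGER_MEANS = np.array([6.0, 6.0, 4.0, 4.0])
#: Online (within-trial) noise covariance: 0.5 N s.d. per finger with
#: synergistic (negative) coupling, giving a VF online variance of 0.25 N^2.
DEFAULT_ONLINE_COV = correlated_cov(0.25, -0.25)
#: Offline (trial-to-trial) offset covariance: 0.3 N s.d. per finger, same
#: coupling, giving a VF offline variance of 0.09 N^2.
DEFAULT_OFFLINE_COV = correlated_cov(0.09, -0.25)
#: Noise magnitude multiplier per uncertainty level (error grows with
#: uncertainty; monotone by construction, no quantitative law implied).
UNCERTAINTY_SCALE = {"L": 0.6, "ML": 0.8, "MH": 1.0, "H": 1.4}
#: Mild F/I asymmetry so the two unimodal conditions are distinguishable.
UNIMODAL_VE_SCALE = {"F": 1.1, "I": 0.9}


def make_synthetic_study(
    n_subjects: int = 10,
    uncertainties: Sequence[str] = UNCERTAINTY_LEVELS,
    n_trials: int = 5,
    duration: float = 20.0,
    sample_rate: float = 1000.0,
    seed: int = 0,
    fi_ve_scale: float = 1.0,
    online_cov: np.ndarray | None = None,
    offline_cov: np.ndarray | None = None,
    noise_cutoff: float = 8.0,
    f_T: float = 20.0,
    bias_sd: float = 0.25,
    subject_sd: float = 0.15,
) -> dict[tuple[str, str, str], list[TrialRecording]]:
    """Generate a full 3-mode synthetic study.

    Per subject and uncertainty level, the F and I conditions scale the base
    covariances by the level's noise multiplier (times a lognormal
    per-subject factor and a mild F/I asymmetry).  The FI condition's total
    VF variance is set to ``fi_ve_scale`` times the cue-integration
    prediction from the true F and I variances, and its mean-force bias to
    the precision-weighted average of the F and I biases — so
    ``fi_ve_scale=1`` builds an exactly Bayes-optimal integrator (a null
    study) and e.g. ``0.7`` builds a super-optimal one.  Condition biases
    are drawn per subject from N(0, bias_sd^2) scaled with the level.
    Fully deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    online_cov = DEFAULT_ONLINE_COV if online_cov is None else np.asarray(online_cov)
    offline_cov = DEFAULT_OFFLINE_COV if offline_cov is None else np.asarray(offline_cov)
    ones = np.ones(len(DEFAULT_FINGER_MEANS))
    base_ve = float(ones @ (online_cov + offline_cov) @ ones)  # VF variance of base
    catalogue = condition_catalogue(target_force=f_T)

    trialsets: dict[tuple[str, str, str], list[TrialRecording]] = {}
    for si in range(n_subjects):
        subject = f"S{si + 1:02d}"
        sub_rng = np.random.default_rng(np.random.SeedSequence([seed, si, 10_001]))
        subject_factor = float(np.exp(sub_rng.normal(0.0, subject_sd)))
        for ui, level in enumerate(uncertainties):
            scale = UNCERTAINTY_SCALE[level] * subject_factor
            cond_rng = np.random.default_rng(
                np.random.SeedSequence([seed, si, ui, 10_002])
            )
            bias = {
                mode: float(cond_rng.normal(0.0, bias_sd * np.sqrt(UNCERTAINTY_SCALE[level])))
                for mode in ("F", "I")
            }
            ve = {mode: UNIMODAL_VE_SCALE[mode] * scale * base_ve for mode in ("F", "I")}
            w_f = ve["I"] / (ve["F"] + ve["I"])
            bias["FI"] = w_f * bias["F"] + (1.0 - w_f) * bias["I"]
            ve_fi = fi_ve_scale * ve["F"] * ve["I"] / (ve["F"] + ve["I"])
            cov_scale = {
                "F": UNIMODAL_VE_SCALE["F"] * scale,
                "I": UNIMODAL_VE_SCALE["I"] * scale,
                "FI": ve_fi / base_ve,
            }
            for mi, mode in enumerate(MODES):
                spec_seed = int(
                    np.random.SeedSequence([seed, si, ui, mi, 10_003]).generate_state(1)[0]
                    & 0x7FFFFFFF
                )
                spec = SyntheticSpec(
                    finger_means=DEFAULT_FINGER_MEANS * (f_T - bias[mode]) / f_T,
                    offline_cov=cov_scale[mode] * offline_cov,
                    online_cov=cov_scale[mode] * online_cov,
                    noise_cutoff=noise_cutoff,
                    n_trials=n_trials,
                    duration=duration,
                    sample_rate=sample_rate,
                    seed=spec_seed,
                )
                trialsets[(subject, mode, level)] = simulate_trial_set(
                    spec, subject_id=subject, condition=catalogue[(mode, level)]
                )
    return trialsets


def run_study(
    trialsets: TrialSets,
    window: tuple[float, float] | None = DEFAULT_WINDOW,
    f_T: float = 20.0,
    components: Sequence[str] = ("omse", "ve", "se"),
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "studentized",
    transform: bool = True,
) -> StudyResult:
    """Full pipeline: window, decompose, model comparison, summary.

    Deterministic given the trial sets and ``seed``; repeated runs produce
    byte-identical tables.
    """
    hvd_table = decompose_study(trialsets, window=window, f_T=f_T)
    comparison = bayes_compare(
        hvd_table, components=components, n_boot=n_boot, seed=seed, method=method
    )
    summary = summarize(hvd_table, transform=transform)
    return StudyResult(hvd=hvd_table, comparison=comparison, summary=summary)
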