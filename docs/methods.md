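# Methods

## Trial model and decomposition

A trial set is `n` trials of the four-finger force matrix sampled at rate
`fs`. The virtual-finger (VF) force is the row sum of the individual-finger
(IF) forces. Writing y_i(t) for trial *i*'s VF force, the model is

    y_i(t) = X_i(t) + E_i + m

with `m` the grand mean over all samples of all trials, `E_i` the deviation
of trial *i*'s mean from `m`, and `X_i(t)` the within-trial demeaned trace.
The decomposition (`audiomotor.hvd.decompose`) computes, against the target
force f_T:

- `omse` — mean of (f_T − y)² over every sample of every trial;
- `se` — (f_T − m)², with `bias = f_T − m`;
- `ve_on` — trial-averaged within-trial variance of X_i(t);
- `ve_off` — variance of {E_i};
- `var_on` / `cov_on` — trial-averaged sums of within-trial IF variances and
  of ordered-pair IF covariances (each unordered pair counted twice, so
  variance-of-sum = Σ variances + Σ covariances exactly);
- `var_off` / `cov_off` — the same partition applied to the per-trial finger
  means about the finger grand means.

**Moment convention.** All moments are population moments (divide by the
count). This is forced by the conservation identities: with sample
(n−1) normalisation, OMSE = SE + VE_ON + VE_OFF holds only asymptotically;
with population moments it is an exact finite-sample identity, which the
test suite checks to 1e−9 relative on random data. A consequence worth
knowing: the expectation of `ve_off` estimated from n trials is
(n−1)/n times the generative between-trial variance (20% shrinkage at the
5-trial study size). The shrinkage affects observed and predicted values
alike in the model comparison, so the null comparison stays centred; tests
that check absolute offline-moment recovery use 50 trials, where the
shrinkage is 2%.

Every component is computed from its own definition — no component is
derived as the residual of another — so the identities are genuine
floating-point checks, with `omse_direct` as an independent brute-force
oracle.

**Windowing.** The analysis window is half-open `[start, end)` on sample
timestamps (default 6–15 s of a 20-s trial, i.e. 9000 samples at 1 kHz),
skipping initial force stabilisation and end-of-trial release. Half-open
bounds partition samples without duplication. All quantities, including the
trial offsets E_i, are defined on the windowed data.

## Cue-integration model

`audiomotor.bayes` implements pure likelihood (precision-weighted) fusion of
the unimodal frequency (F) and intensity (I) estimates — no prior over
force, no mechanism for super-optimality; the package only measures
deviation from the optimal prediction. Predictions are made **per subject**:
each subject's unimodal variance is their total variable error
(VE = VE_ON + VE_OFF) and their bias is f_T minus their grand-mean force,
both from the F and I conditions at the same uncertainty level; predictions
are then compared with that subject's observed FI values. The per-subject
route (rather than predicting from group means) is what a paired test
requires. The model is not applied separately to online/offline components,
which it does not define; VE feeds the variance slot, and the OMSE
prediction is σ²FI + b²FI.

Transforms are never applied inside the model — it operates on raw
variances; the log scale enters only in across-subject summaries.

## Bootstrap paired comparison

`bootstrap_paired_test` resamples subjects' observed-minus-predicted
differences with replacement (default B = 10,000, seeded). Two null
constructions are provided:

- `studentized` (default): equal-tail bootstrap-t. The null distribution is
  t\* = (mean\* − mean)/se\*; the two-sided p-value is
  2·min(P(t\* ≤ t₀), P(t\* ≥ t₀)) with a +1 continuity correction. This is
  the resampling analogue of a paired t-test; a design-time calibration
  study (n = 10 pairs, B = 2000, Gaussian nulls) put its type-I error at
  ≈ 0.049 at α = 0.05.
- `percentile`: the bootstrap distribution of the mean difference recentred
  at zero, two-sided tail probability read directly. Simpler, but the same
  calibration study put its type-I error at ≈ 0.086 with 10 subjects —
  anti-conservative at this n, which is why it is not the default.

The percentile 95% CI of the mean difference is reported in both cases.
Zero-spread differences short-circuit: p = 1 for all-zero differences
(zero-width CI), p = 1/(B+1) for a constant non-zero difference.
Significance threshold throughout: α = 0.05, two-sided.

**Transforms.** Group summaries use log₁₀ for the strictly positive
components (OMSE, VE, SE, VE_ON, VE_OFF, Var_ON, Var_OFF) and the
log-modulus transform T(x) = sign(x)·log₁₀(|x|+1) for the signed covariance
indices. Base 10 is conventional for the log-modulus transform and no
identity in the package depends on the base.

## Feedback mapping and the gain ladder

The force-to-tone map is signed affine per channel: frequency =
1000 Hz + g_f·(force − 20 N) and level = 70 dB + g_i·(force − 20 N), with
positive deviation raising frequency/intensity; this is the simplest form
consistent with gains quoted in Hz/N and dB/N, and intensity is additive in
dB (not pascals) for the same reason. No output clamping is applied — audio
rendering is out of scope. The gain ladder g_k = g₀·(g_max/g₀)^(k/(K−1))
realises equal log-scale increments; applied to (7, 300) Hz/N over four
levels it rounds to the catalogue's 7/24/86/300. The default intensity
ladder (0.7, 1.2, 3, 7.5 dB/N) is stored verbatim in the catalogue: its
consecutive ratios (1.71, 2.5, 2.5) are not exactly log-uniform, so the
package does not regenerate it from the ladder rule. Uncertainty labels map
to descending gain (L → largest gain: errors most perceptible).

## Synthetic data generator

`forcegen` inverts the trial model: per-finger means (default (6,6,4,4) N,
summing to the 20 N target), per-trial Gaussian offset vectors with a 4×4
offline covariance, and band-limited Gaussian online noise with its own 4×4
covariance — 5 trials of 20 s at 1 kHz by default, matching the study
geometry.

Numerical choices:

- **Noise colouring.** White Gaussian noise is low-pass filtered with a
  second-order Butterworth filter applied forward-backward (zero phase),
  default cutoff 8 Hz — the physiological force-tremor band. The spectrum is
  a free modelling choice; nothing downstream depends on its exact shape,
  and the cutoff is exposed on the spec.
- **Post-filter rescaling.** Filtering changes variance, so each filtered
  column is demeaned and rescaled to unit sample variance before mixing
  through a factor A of the target covariance (A Aᵀ = C; Cholesky with an
  eigendecomposition fallback for PSD-but-singular C). Per-finger sample
  variances therefore match the diagonal essentially exactly and the
  empirical covariance converges to C, which makes moment-recovery tests
  well-posed.
- **Reproducibility.** Trial *k* consumes only the substream seeded by
  (seed, k), so trial sets are bit-reproducible and extending a set never
  perturbs existing trials.

Default magnitudes (chosen once as a realistic constant-force regime, since
no empirical noise spectrum or magnitude was available to fit): per-finger
online variance 0.25 N² and offline variance 0.09 N², both with pairwise
correlation −0.25 — strong error-attenuating synergy, near the −1/3
equicorrelation limit for four fingers; it gives VF online/offline variances
of 0.25/0.09 N² and ~99% sign reliability of the 5-trial offline covariance
estimate. These defaults are a plausible operating point, not a fit to any
dataset.

**Synthetic studies** (`make_synthetic_study`) add: a lognormal per-subject
noise multiplier (σ = 0.15); a monotone uncertainty→noise map
(L/ML/MH/H → ×0.6/0.8/1.0/1.4 on both covariances — error grows with
uncertainty, no quantitative gain-vs-noise law is implied); a mild F/I
asymmetry (×1.1/×0.9) so the unimodal conditions differ; condition biases
drawn per subject (s.d. 0.25 N, scaled with the level). The FI condition is
constructed from the model itself: its true VF variance is `fi_ve_scale`
times the Bayesian prediction from the true F and I variances, and its bias
is the precision-weighted combination of the F and I biases. `fi_ve_scale=1`
therefore builds an exactly optimal integrator (a null study);
values below 1 build super-optimal ones.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: no tremor spectral peaks, drift, fatigue or
learning across trials; no neural/motor delay or feedback-loop dynamics (the
feedback gain influences synthetic data only through the uncertainty-level
noise map, not through a closed loop); Gaussian noise throughout;
stationarity within trials. Tests establish that the estimators and tests
recover what the model puts in, not that real data satisfy the model.

## Problem sizes used in simulation tests

Chosen as the package's own verification design: conservation identities on
100 random 4-trial sets (1 s at 200 Hz); generator moment recovery on 100
seeds of the study geometry (5 trials, 9 s, 1 kHz); bootstrap calibration on
500 Gaussian null studies (10 pairs, B = 2000); super-optimality detection
power (fi_ve_scale = 0.7, 10 subjects) and null consistency on seeded
studies of one uncertainty level (MH) with 9-s trials at 250 Hz and
B = 2000 — at an 8 Hz noise bandwidth the 250 Hz rate leaves the effective
sample count, and hence estimator precision, essentially unchanged relative
to 1 kHz.

## Known limitations

- The repeated-measures ANOVA stage (sphericity correction, post-hocs) is
  deliberately not implemented; the tidy per-subject tables are designed for
  export to standard statistics tools.
- Only the covariance form of the synergy index is computed; no explicit
  UCM projection onto task-relevant/irrelevant subspaces (the two are
  algebraically equivalent for a sum-force task).
- With 5 trials per condition, offline quantities (`ve_off`, `cov_off`)
  carry large sampling noise and the population-moment shrinkage noted
  above; inferences about offline components at study scale rest on the
  paired comparison, not on their absolute values.
- `summarize` refuses to log-transform non-positive values (possible for a
  degenerate `se` of exactly 0 in noise-free synthetic data); disable the
  transform for such inputs.
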