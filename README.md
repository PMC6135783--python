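# audiomotor

Analysis toolkit for multi-finger constant-force production under auditory
feedback: a hierarchical variability decomposition of motor error, a
Bayesian (maximum-likelihood) cue-integration model for bimodal auditory
feedback, a seeded bootstrap paired comparison, and a synthetic trial
generator that makes the whole pipeline testable without access to raw
recordings.

## The problem

In force-sonification experiments, subjects press with four fingers to hold
a constant virtual-finger (VF) force — the sum of the individual-finger (IF)
forces — at a 20 N target while a tracking tone encodes the force error
through its frequency (F), its intensity (I), or both (FI), against a fixed
reference tone (1000 Hz, 70 dB). The feedback gain (Hz/N or dB/N) sets how
perceptible a given error is, and thereby the level of feedback uncertainty
(four levels L/ML/MH/H, gains spaced in equal log increments).

Two questions drive the analysis:

1. **Does the nervous system fuse the two auditory cues optimally?** With
   unimodal Gaussian force estimates of variance σ²F, σ²I and biases
   b_F, b_I, the statistically optimal (precision-weighted) bimodal estimate
   has

       w_F = σ²I / (σ²F + σ²I),   σ²FI = σ²F σ²I / (σ²F + σ²I),
       b_FI = w_F b_F + w_I b_I,  OMSE_FI = σ²FI + b²FI.

   Observed FI performance *below* this prediction is super-optimal
   integration.

2. **How is the error organised across the motor hierarchy?** Writing the
   VF force of trial *i* as y_i(t) = X_i(t) + E_i + m, the overall
   mean-squared error against the target f_T decomposes exactly as

       OMSE = SE + VE_ON + VE_OFF,        SE = (f_T − m)²,

   with the online (within-trial) and offline (between-trial) variable
   errors each splitting at the finger level into the sum of IF variances
   plus the sum of between-finger covariances (ordered pairs):

       VE_ON = Var_ON + Cov_ON,   VE_OFF = Var_OFF + Cov_OFF.

   Negative covariance terms are error-attenuating finger covariation —
   motor synergy, algebraically equivalent to uncontrolled-manifold (UCM)
   synergy indices for this task.

## Worked example

Generate a synthetic one-level study of 10 subjects in which the FI
condition is built *super-optimal* (its true VF variance is 0.7× the
Bayesian prediction from its F and I conditions), decompose the 6–15 s
window of each 20-s trial, and test observed FI performance against the
per-subject predictions:

```python
from audiomotor.pipeline import make_synthetic_study, decompose_study, bayes_compare

study = make_synthetic_study(n_subjects=10, uncertainties=("MH",), seed=7,
                             fi_ve_scale=0.7)
table = decompose_study(study)          # default 6-15 s analysis window
comparison = bayes_compare(table, n_boot=10_000, seed=7)
```

One subject's decomposition (N², except the labels):

```
subject mode uncertainty   omse     ve     se  ve_on  ve_off  cov_on  cov_off
    S01    F          MH 0.4778 0.4374 0.0404 0.2891  0.1483 -0.8499  -0.1303
    S01   FI          MH 0.1042 0.1018 0.0024 0.0919  0.0099 -0.2746  -0.0710
    S01    I          MH 0.5087 0.3141 0.1947 0.2238  0.0903 -0.7851  -0.2247
```

Every row satisfies omse = se + ve_on + ve_off; the negative covariance
columns show synergistic finger coupling. The group comparison:

```
uncertainty component  observed_mean  predicted_mean  mean_difference  p_value
         MH      omse         0.1819          0.2624          -0.0805   0.0058
         MH        ve         0.1225          0.1699          -0.0474   0.0002
         MH        se         0.0594          0.0925          -0.0331   0.1010
```

Observed FI variable error (0.12 N²) falls significantly below the
Bayesian prediction (0.17 N², p = 0.0002, paired bootstrap over subjects) —
the pipeline correctly flags the built-in super-optimality, while the bias
term (se) shows no significant deviation.

The same pipeline is available from a shell:

```sh
audiomotor simulate --out study/ --subject S01 --mode FI --uncertainty MH --seed 1
audiomotor decompose study/S01/FI_MH --out results/S01_FI_MH.csv
audiomotor run-study --config config.yaml --out results/
```

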