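"""Maximum-likelihood (Bayesian) integration of two auditory cues.

When force error is conveyed simultaneously through tone frequency (F) and
tone intensity (I), an ideal observer fuses the two unimodal estimates by
precision weighting.  With Gaussian unimodal estimates of variance sigma_F^2
and sigma_I^2 and biases b_F = f_T - mu_F, b_I = f_T - mu_I, the optimal
bimodal estimate has

    w_F = sigma_I^2 / (sigma_F^2 + sigma_I^2),   w_I = 1 - w_F,
    sigma_FI^2 = sigma_F^2 sigma_I^2 / (sigma_F^2 + sigma_I^2),
    b_FI = w_F b_F + w_I b_I,
    OMSE_FI = sigma_FI^2 + b_FI^2.

The fused variance is never larger than either unimodal variance; observed
bimodal error *below* this prediction is evidence of super-optimal
integration.  The model is pure likelihood fusion — no prior over force.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class UnimodalEstimate:
    """Moments of one unimodal (F or I) force estimate.

    ``variance`` in N^2; ``bias`` is f_T - mu in N.
    """

    variance: float
    bias: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


@dataclass(frozen=True)
class BayesPrediction:
    """Predicted bimodal weights, variance, bias and OMSE."""

    w_f: float
    w_i: float
    variance: float
    bias: float
    omse: float


def _total_variance(f: UnimodalEstimate, i: UnimodalEstimate) -> float:
    total = f.variance + i.variance
    if total <= 0:
        raise ValueError("cue weights are undefined when both variances are zero")
    return total


def cue_weights(f: UnimodalEstimate, i: UnimodalEstimate) -> tuple[float, float]:
    """Precision weights ``(w_F, w_I)``; the noisier cue gets the smaller weight."""
    total = _total_variance(f, i)
    return i.variance / total, f.variance / total


def combined_variance(f: UnimodalEstimate, i: UnimodalEstimate) -> float:
    """Fused variance ``sigma_F^2 sigma_I^2 / (sigma_F^2 + sigma_I^2)``."""
    return f.variance * i.variance / _total_variance(f, i)


def combined_bias(f: UnimodalEstimate, i: UnimodalEstimate) -> float:
    """Precision-weighted average of the unimodal biases."""
    w_f, w_i = cue_weights(f, i)
    return w_f * f.bias + w_i * i.bias


def predict_omse(f: UnimodalEstimate, i: UnimodalEstimate) -> BayesPrediction:
    """Full bimodal prediction: weights, variance, bias and their OMSE."""
    w_f, w_i = cue_weights(f, i)
    variance = combined_variance(f, i)
    bias = w_f * f.bias + w_i * i.bias
    return BayesPrediction(
        w_f=w_f,
        w_i=w_i,
        variance=variance,
        bias=bias,
        omse=variance + bias**2,
    )
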