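"""Maximum-likelihood cue-integration predictions and empirical weights.

Pure arithmetic on fitted psychometric parameters: inverse-variance
weights, fused audiovisual variance, predicted conflict-condition PSEs,
and the empirical auditory weight read out from PSE shifts under small
audiovisual conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass


class DegenerateDenominatorError(ZeroDivisionError):
    """Unisensory biases cancel the imposed conflict; weight undefined."""


@dataclass(frozen=True)
class MLEPrediction:
    """MLE-predicted weights, fused variance and conflict PSEs."""

    w_A_mle: float
    w_V_mle: float
    sigma2_AV_mle: float
    pse_AVp_mle: float
    pse_AVm_mle: float


@dataclass(frozen=True)
class WeightEstimate:
    """An empirical auditory-weight estimate and its provenance."""

    w_A_emp: float
    variant: str  # eq6_pooled | eq8_ALVR | eq8_VLAR
    inputs_used: dict


def mle_weights(sigma2_A: float, sigma2_V: float) -> tuple[float, float]:
    """Inverse-variance (reliability-proportional) weights; sums to 1."""
    if sigma2_A <= 0 or sigma2_V <= 0:
        raise ValueError("variances must be positive")
    r_a = 1.0 / sigma2_A
    r_v = 1.0 / sigma2_V
    w_a = r_a / (r_a + r_v)
    return w_a, 1.0 - w_a


def mle_fused_variance(sigma2_A: float, sigma2_V: float) -> float:
    """Fused variance: product over sum, strictly below both inputs."""
    if sigma2_A <= 0 or sigma2_V <= 0:
        raise ValueError("variances must be positive")
    return sigma2_A * sigma2_V / (sigma2_A + sigma2_V)


def mle_predicted_pses(
    w_A: float, disparity: float, pse_congruent: float
) -> tuple[float, float]:
    """Predicted conflict-condition PSEs, anchored at the congruent PSE.

    With the visual probe component at +disparity/2 and the auditory one
    at -disparity/2, the fused probe mean shifts by
    ``(w_V - w_A) * disparity / 2``; the PSE shifts by the opposite sign.
    """
    if disparity <= 0:
        raise ValueError("disparity must be positive")
    w_V = 1.0 - w_A
    shift = (w_A - w_V) * disparity / 2.0
    return pse_congruent + shift, pse_congruent - shift


def predict(
    sigma2_A: float,
    sigma2_V: float,
    disparity: float,
    pse_congruent: float = 0.0,
) -> MLEPrediction:
    """Full set of MLE predictions from the unisensory variances."""
    w_a, w_v = mle_weights(sigma2_A, sigma2_V)
    pse_p, pse_m = mle_predicted_pses(w_a, disparity, pse_congruent)
    return MLEPrediction(
        w_A_mle=w_a,
        w_V_mle=w_v,
        sigma2_AV_mle=mle_fused_variance(sigma2_A, sigma2_V),
        pse_AVp_mle=pse_p,
        pse_AVm_mle=pse_m,
    )


def empirical_weight_eq6(
    pse_AVp: float, pse_AVm: float, disparity: float
) -> WeightEstimate:
    """Empirical auditory weight from the two conflict-condition PSEs.

    ``(PSE_+ - PSE_-) / (2 |disparity|) + 1/2``; deliberately NOT clamped
    to [0, 1] so that sampling noise does not bias group tests toward the
    null.
    """
    if disparity <= 0:
        raise ValueError("disparity must be positive")
    w = (pse_AVp - pse_AVm) / (2.0 * abs(disparity)) + 0.5
    return WeightEstimate(
        w_A_emp=float(w),
        variant="eq6_pooled",
        inputs_used={"pse_AVp": pse_AVp, "pse_AVm": pse_AVm, "disparity": disparity},
    )


def empirical_weight_eq8(
    pse_AV_conflict: float,
    pse_A: float,
    pse_V: float,
    X: float,
    side: str,
) -> WeightEstimate:
    """Per-conflict-condition auditory weight accounting for unisensory bias.

    ``side='ALVR'`` is the +X conflict (auditory left, visual right), for
    which the visual-capture PSE is ``PSE_V - X/2`` and the
    auditory-capture PSE is ``PSE_A + X/2``; ``'VLAR'`` mirrors the signs.
    """
    if side not in ("ALVR", "VLAR"):
        raise ValueError(f"side must be 'ALVR' or 'VLAR', got {side!r}")
    sign = 1.0 if side == "ALVR" else -1.0
    capture_v = pse_V - sign * X / 2.0
    capture_a = pse_A + sign * X / 2.0
    denom = capture_a - capture_v
    if abs(denom) < 1e-9 * abs(X):
        raise DegenerateDenominatorError(
            "unisensory biases cancel the conflict; auditory weight undefined"
        )
    w = (pse_AV_conflict - capture_v) / denom
    return WeightEstimate(
        w_A_emp=float(w),
        variant=f"eq8_{side}",
        inputs_used={
            "pse_AV_conflict": pse_AV_conflict,
            "pse_A": pse_A,
            "pse_V": pse_V,
            "X": X,
        },
    )
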