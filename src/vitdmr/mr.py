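"""Wald-ratio instrumental-variable estimation with delta-method SEs.

The causal ratio estimate per ``scale`` nmol/L 25OHD is
``scale * beta1 / beta2`` where ``beta1`` is the log hazard ratio per
score unit from the Cox model and ``beta2`` the nmol/L-per-score-unit
first-stage slope.  Standard errors propagate both stages by the delta
method (the stages are treated as independent); the "simple" rescaling
variant multiplies beta and SE by ``scale / beta2``, treating the slope
as known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import Z975

__all__ = [
    "IvEstimate",
    "WeakInstrumentWarning",
    "wald_iv",
    "rescale_simple",
    "bonferroni_threshold",
]


class WeakInstrumentWarning(UserWarning):
    """First stage too weak for a stable ratio estimate."""


@dataclass
class IvEstimate:
    """A ratio-scale causal estimate per ``scale`` nmol/L 25OHD.

    ``or_`` is the exponentiated estimate; the fitted outcome model is a
    hazard model, so this is a hazard-ratio-type quantity even where the
    literature labels Wald-ratio outputs "odds ratios" — ``source``
    records the outcome model.
    """

    beta_iv: float
    se_iv: float
    or_: float
    ci95: tuple[float, float]
    p: float
    scale: float
    method: str
    weak_instrument: bool = False
    source: str = "cox"

    @classmethod
    def _build(cls, beta_iv, se_iv, scale, method, weak):
        z = beta_iv / se_iv if se_iv > 0 else np.inf * np.sign(beta_iv)
        return cls(
            beta_iv=float(beta_iv),
            se_iv=float(se_iv),
            or_=float(np.exp(beta_iv)),
            ci95=(
                float(np.exp(beta_iv - Z975 * se_iv)),
                float(np.exp(beta_iv + Z975 * se_iv)),
            ),
            p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0,
            scale=float(scale),
            method=method,
            weak_instrument=weak,
        )


def wald_iv(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    scale: float = 20.0,
) -> IvEstimate:
    """Delta-method Wald ratio: ``scale * beta1 / beta2``.

    ``se_iv^2 = (scale/beta2)^2 se1^2 + (scale beta1 / beta2^2)^2 se2^2``.
    A first stage with ``|beta2|/se2 < 2`` triggers a weak-instrument
    warning (flagged on the estimate, never an error).
    """
    if beta2 == 0:
        raise ValueError("beta2 = 0: the Wald ratio is undefined")
    if se1 < 0 or se2 < 0 or scale <= 0:
        raise ValueError("se1, se2 must be >= 0 and scale > 0")
    weak = se2 > 0 and abs(beta2) / se2 < 2
    if weak:
        warnings.warn(
            f"weak instrument: |beta2|/se2 = {abs(beta2) / se2:.2f} < 2",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    beta_iv = scale * beta1 / beta2
    se_iv = np.hypot(scale / beta2 * se1, scale * beta1 / beta2**2 * se2)
    return IvEstimate._build(beta_iv, se_iv, scale, "delta", weak)


def rescale_simple(
    beta: float, se: float, slope: float, target: float = 20.0
) -> IvEstimate:
    """Rescaling variant: multiply beta and SE by ``target / slope``.

    Treats the first-stage slope as a known constant, so its SE never
    exceeds the delta-method SE for the same inputs.
    """
    if slope == 0:
        raise ValueError("slope = 0: rescaling undefined")
    if se < 0 or target <= 0:
        raise ValueError("se must be >= 0 and target > 0")
    factor = target / slope
    return IvEstimate._build(beta * factor, abs(se * factor), target, "simple", False)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level ``alpha / m`` for ``m`` comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m
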