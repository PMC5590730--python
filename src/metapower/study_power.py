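"""Power of the individual studies contributing to a meta-analysis.

Each study tests its own effect (H0: mu_i = mu0) with the two-sided Z test
|Y_i - mu0|/sigma_i >= za.  Under a common effect the power of study i is

    beta_i(delta, sigma_i) = 1 + Phi(-za + delta/sigma_i) - Phi(za + delta/sigma_i),

which deliberately includes the "type III" (wrong-sign) rejections; the
directional variant Phi(-za + delta/sigma_i) is the opt-out.  Under a
random-effects truth delta_i ~ N(delta, tau2), averaging over delta_i gives
per-study powers

    1 + Phi((-za*sigma_i + delta)/sqrt(sigma_i^2 + tau2))
      - Phi(( za*sigma_i + delta)/sqrt(sigma_i^2 + tau2)),

and the average study power is the mean over the empirical distribution of
the sigma_i (equal study weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core_model import MetaAnalysisData, PowerResult, TestSpec, ValidationError, EffectScenario

__all__ = [
    "StudyPowerVector",
    "study_power",
    "directional_power",
    "study_powers_fixed",
    "study_powers_random",
]


@dataclass(frozen=True)
class StudyPowerVector:
    """Per-study powers aligned with the meta-analysis study order."""

    powers: np.ndarray
    method: str

    def __post_init__(self) -> None:
        p = np.asarray(self.powers, dtype=float)
        object.__setattr__(self, "powers", p)
        if np.any((p < -1e-12) | (p > 1 + 1e-12)):
            raise ValidationError("study powers outside [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.powers))

    @property
    def median(self) -> float:
        return float(np.median(self.powers))

    @property
    def max(self) -> float:
        return float(np.max(self.powers))

    def summary(self, which: str) -> float:
        try:
            return {"mean": self.mean, "median": self.median, "max": self.max}[which]
        except KeyError:
            raise ValidationError(f"unknown summary {which!r}; use mean|median|max") from None


def _two_sided(ncp: np.ndarray | float, za: float) -> np.ndarray | float:
    return 1.0 + norm.cdf(-za + ncp) - norm.cdf(za + ncp)


def study_power(delta_i: float, sigma_i: float, spec: TestSpec = TestSpec()) -> PowerResult:
    """Two-sided power of a single study's Z test, symmetric in the sign of delta_i."""
    if sigma_i <= 0:
        raise ValidationError(f"sigma_i must be positive, got {sigma_i}")
    return PowerResult(float(_two_sided(delta_i / sigma_i, spec.za)), method="study")


def directional_power(delta_i: float, sigma_i: float, spec: TestSpec = TestSpec()) -> PowerResult:
    """Probability of rejecting AND estimating the effect in the direction of delta_i > 0.

    Not symmetric in delta_i; satisfies
    ``directional_power(d) + directional_power(-d) == study_power(d)`` exactly.
    """
    if sigma_i <= 0:
        raise ValidationError(f"sigma_i must be positive, got {sigma_i}")
    return PowerResult(float(norm.cdf(-spec.za + delta_i / sigma_i)), method="study_directional")


def study_powers_fixed(
    data: MetaAnalysisData, delta: float, spec: TestSpec = TestSpec()
) -> StudyPowerVector:
    """Per-study powers under a common effect delta (no heterogeneity)."""
    se = data.se
    if np.any(se <= 0):
        raise ValidationError("all standard errors must be positive")
    return StudyPowerVector(_two_sided(delta / se, spec.za), method="study")


def study_powers_random(
    data: MetaAnalysisData, scenario: EffectScenario, spec: TestSpec = TestSpec()
) -> StudyPowerVector:
    """Per-study powers averaged over the random effect delta_i ~ N(delta, tau2).

    Assumes delta_i independent of sigma_i (no small-study effects).  At
    tau2 = 0 this reduces exactly to :func:`study_powers_fixed`.
    """
    if scenario.tau2 < 0:
        raise ValidationError("tau2 must be >= 0")
    se = data.se
    denom = np.sqrt(se**2 + scenario.tau2)
    upper = norm.cdf((-spec.za * se + scenario.delta) / denom)
    lower = norm.cdf((spec.za * se + scenario.delta) / denom)
    return StudyPowerVector(1.0 + upper - lower, method="study")
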