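"""Fixed-effect (common-effect) pooling and its power.

The pooled estimate is the inverse-variance weighted mean with variance
V_F = 1/sum(sigma_i^-2).  Because V_F is strictly smaller than every
sigma_i^2 once k >= 2, the fixed-effect meta-analysis power strictly
dominates every study-specific power whenever delta != 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core_model import MetaAnalysisData, PowerResult, TestSpec

__all__ = ["FixedFit", "fit_fixed", "power_fixed"]


@dataclass(frozen=True)
class FixedFit:
    """Inverse-variance pooled estimate and its variance V_F."""

    mu_hat: float
    vf: float

    def z_stat(self, mu0: float = 0.0) -> float:
        return (self.mu_hat - mu0) / np.sqrt(self.vf)


def fit_fixed(data: MetaAnalysisData) -> FixedFit:
    w = data.weights
    s1 = w.sum()
    return FixedFit(mu_hat=float(np.sum(w * data.y) / s1), vf=float(1.0 / s1))


def power_fixed(data: MetaAnalysisData, delta: float, spec: TestSpec = TestSpec()) -> PowerResult:
    """Power of the two-sided fixed-effect test of H0: mu = mu0 at true delta = mu - mu0."""
    vf = fit_fixed(data).vf
    ncp = delta / np.sqrt(vf)
    return PowerResult(float(1.0 + norm.cdf(-spec.za + ncp) - norm.cdf(spec.za + ncp)), method="fixed")
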