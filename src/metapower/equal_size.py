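"""Analytical power for equal-size random-effects meta-analyses.

When all k studies share a common within-study SD sigma, the DL test
statistic has a tractable distribution.  Write I2 = tau2/(sigma^2 + tau2)
and Delta = delta*sqrt(k)/sigma (a noncentrality parameter).  Then
T = Z / max(sqrt(1 - I2), x) in distribution, where Z ~ N(Delta*sqrt(1-I2), 1)
and x = sqrt(C/(k-1)) with C ~ chi2_{k-1} independent of Z.  The estimate
tau2_hat truncates to zero exactly when C <= (1-I2)(k-1), giving the mixture
CDF

    P(T <= t) = Pr(chi2_{k-1} <= (1-I2)(k-1)) * Phi((t - Delta) sqrt(1-I2))
              + 2(k-1) * int_{sqrt(1-I2)}^inf x Phi(t x - Delta sqrt(1-I2))
                          chi2pdf_{k-1}((k-1) x^2) dx.

The leading coefficient is the regularised lower incomplete gamma
Pr(chi2_{k-1} <= (1-I2)(k-1)) — the probability that tau2_hat is truncated —
so the two mixture weights sum to one.  Power is 1 - [P(T<=za) - P(T<=-za)]
and depends on Delta only through |Delta|.

Ignoring the uncertainty in tau2_hat instead gives the closed form

    beta_R(Delta, I2) = 1 + Phi(-za + Delta sqrt(1-I2)) - Phi(za + Delta sqrt(1-I2)),

the large-k limit of the mixture CDF power.  This module also provides the
k = 1 known-tau2 comparison formulas, the typical within-study variance
mappings from unequal-sigma data onto the equal-size machinery, and
planning-stage power grids over (Delta, I2).

The DerSimonian-Laird, REML and Paule-Mandel estimators of tau2 coincide in
the equal-size case, so these results apply to all three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import gammainc
from scipy.stats import chi2, norm

from .core_model import (
    InsufficientStudiesError,
    MetaAnalysisData,
    PowerResult,
    TestSpec,
    ValidationError,
)

__all__ = [
    "EqualSizeScenario",
    "TypicalVarianceMethod",
    "TypicalVariance",
    "gamma1",
    "t_cdf_equal",
    "power_re_equal",
    "power_no_uncertainty",
    "power_k1_study",
    "power_k1_meta",
    "typical_variance",
    "map_to_equal_size",
    "power_grid",
]


@dataclass(frozen=True)
class EqualSizeScenario:
    """k equal-size studies with heterogeneity fraction I2 and noncentrality Delta.

    ``n_nodes`` Gauss-Legendre nodes are used per quadrature panel and the
    chi-squared tail is truncated where its survival function drops below
    ``tail_sf`` (default 1e-13, well under quadrature error).
    """

    k: int
    i2: float
    delta_nc: float
    n_nodes: int = 64
    tail_sf: float = 1e-13

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InsufficientStudiesError("equal-size machinery requires k >= 2")
        if not 0 <= self.i2 < 1:
            raise ValidationError(f"I2 must lie in [0, 1), got {self.i2}")
        if self.n_nodes < 8:
            raise ValidationError("n_nodes must be >= 8")


class TypicalVarianceMethod(str, Enum):
    higgins_thompson = "higgins_thompson"
    mean_precision_reciprocal = "mean_precision_reciprocal"


@dataclass(frozen=True)
class TypicalVariance:
    value: float
    method: TypicalVarianceMethod


def gamma1(a: float, x: float) -> float:
    """Regularised lower incomplete gamma P(a, x) = gamma(a, x)/Gamma(a).

    Under this normalisation ``gamma1((k-1)/2, (1-I2)(k-1)/2)`` equals
    Pr(chi2_{k-1} <= (1-I2)(k-1)), the probability that the DL estimate of
    tau2 truncates to zero in the equal-size case.
    """
    if a <= 0:
        raise ValidationError(f"shape a must be positive, got {a}")
    if x < 0:
        raise ValidationError(f"x must be >= 0, got {x}")
    return float(gammainc(a, x))


def _quadrature_nodes(scenario: EqualSizeScenario) -> tuple[np.ndarray, np.ndarray]:
    """Panelled Gauss-Legendre nodes/weights in C-space for the mixture integral.

    The continuous part is E[ Phi(t*sqrt(C/(k-1)) - Delta*sqrt(1-I2)) ] over a
    chi2_{k-1} restricted to C > (1-I2)(k-1); panels break at chi-squared
    quantiles so mass is resolved where the density lives.
    """
    df = scenario.k - 1
    c0 = (1.0 - scenario.i2) * df
    cmax = float(chi2.isf(scenario.tail_sf, df))
    breaks = [c0]
    for q in (0.05, 0.25, 0.5, 0.75, 0.9, 0.99, 0.999):
        b = float(chi2.ppf(q, df))
        if c0 < b < cmax:
            breaks.append(b)
    breaks.append(max(cmax, c0 + 1e-6))
    xs, ws = leggauss(scenario.n_nodes)
    nodes, weights = [], []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (hi - lo)
        nodes.append(0.5 * (hi + lo) + half * xs)
        weights.append(half * ws)
    c = np.concatenate(nodes)
    w = np.concatenate(weights) * chi2.pdf(c, df)
    return c, w


def t_cdf_equal(t, scenario: EqualSizeScenario) -> np.ndarray | float:
    """CDF of the DL test statistic T for k equal-size studies.

    Accepts a scalar or array of evaluation points ``t``.  The result is a
    proper CDF: nondecreasing with limits 0 and 1, symmetric about 0 when
    Delta = 0.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    df = scenario.k - 1
    s = math.sqrt(1.0 - scenario.i2)
    d = scenario.delta_nc
    point_mass = gamma1(df / 2.0, (1.0 - scenario.i2) * df / 2.0)
    lead = point_mass * norm.cdf((t_arr - d) * s)
    c, w = _quadrature_nodes(scenario)
    x = np.sqrt(c / df)
    integral = norm.cdf(t_arr[:, None] * x[None, :] - d * s) @ w
    out = np.clip(lead + integral, 0.0, 1.0)
    return out if np.ndim(t) else float(out[0])


def power_re_equal(scenario: EqualSizeScenario, spec: TestSpec = TestSpec()) -> PowerResult:
    """Power of the DL random-effects test with k equal-size studies.

    Accounts for the estimation of tau2 through the mixture CDF of T;
    invariant under Delta -> -Delta.
    """
    f = t_cdf_equal(np.array([spec.za, -spec.za]), scenario)
    accept = float(f[0] - f[1])
    return PowerResult(1.0 - accept, method="re_equal_size")


def power_no_uncertainty(delta_nc: float, i2: float, spec: TestSpec = TestSpec()) -> PowerResult:
    """Equal-size power ignoring the uncertainty in tau2_hat (large-k limit).

    beta_R(Delta, I2) = 1 + Phi(-za + Delta sqrt(1-I2)) - Phi(za + Delta sqrt(1-I2));
    always in [alpha, 1], decreasing in I2 for Delta != 0, and handles I2 = 1
    (power alpha for any Delta).
    """
    if not 0 <= i2 <= 1:
        raise ValidationError(f"I2 must lie in [0, 1], got {i2}")
    ncp = delta_nc * math.sqrt(1.0 - i2)
    return PowerResult(
        float(1.0 + norm.cdf(-spec.za + ncp) - norm.cdf(spec.za + ncp)),
        method="re_no_uncertainty",
    )


def power_k1_study(
    delta: float, sigma: float, tau2: float, spec: TestSpec = TestSpec()
) -> PowerResult:
    """Average study-specific power for a single study with known tau2.

    Equivalent to a two-sided test with the reduced critical value
    za*sqrt(1-I2): strictly exceeds :func:`power_k1_meta` whenever tau2 > 0,
    with equality at tau2 = 0.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if tau2 < 0:
        raise ValidationError("tau2 must be >= 0")
    i2 = tau2 / (sigma**2 + tau2)
    ncp = delta / math.sqrt(sigma**2 + tau2)
    za_eff = spec.za * math.sqrt(1.0 - i2)
    return PowerResult(
        float(1.0 + norm.cdf(-za_eff + ncp) - norm.cdf(za_eff + ncp)), method="study"
    )


def power_k1_meta(
    delta: float, sigma: float, tau2: float, spec: TestSpec = TestSpec()
) -> PowerResult:
    """Random-effects meta-analysis power for a single study with known tau2."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if tau2 < 0:
        raise ValidationError("tau2 must be >= 0")
    ncp = delta / math.sqrt(sigma**2 + tau2)
    return PowerResult(
        float(1.0 + norm.cdf(-spec.za + ncp) - norm.cdf(spec.za + ncp)),
        method="re_no_uncertainty",
    )


def typical_variance(
    data: MetaAnalysisData,
    method: TypicalVarianceMethod | str = TypicalVarianceMethod.higgins_thompson,
) -> TypicalVariance:
    """A single within-study variance summarising unequal sigma_i^2.

    ``higgins_thompson``: (k-1) S1 / (S1^2 - S2) with S_r = sum(w_i^r);
    ``mean_precision_reciprocal``: k / S1, the harmonic-type mean of the
    sigma_i^2.  Both return the common sigma^2 when all studies are equal.
    """
    method = TypicalVarianceMethod(method)
    s1 = data.weight_sum(1)
    if method is TypicalVarianceMethod.higgins_thompson:
        if data.k < 2:
            raise InsufficientStudiesError("higgins_thompson requires k >= 2")
        s2 = data.weight_sum(2)
        value = (data.k - 1) * s1 / (s1**2 - s2)
    else:
        value = data.k / s1
    return TypicalVariance(value=float(value), method=method)


def map_to_equal_size(
    data: MetaAnalysisData,
    delta: float,
    tau2: float,
    method: TypicalVarianceMethod | str = TypicalVarianceMethod.higgins_thompson,
) -> EqualSizeScenario:
    """Map a real meta-analysis onto an analogous equal-size scenario.

    The typical within-study variance replaces every sigma_i^2, then
    I2 = tau2/(sigma^2 + tau2) and Delta = delta*sqrt(k)/sigma with k
    preserved.
    """
    if tau2 < 0:
        raise ValidationError("tau2 must be >= 0")
    sigma2 = typical_variance(data, method).value
    return EqualSizeScenario(
        k=data.k,
        i2=tau2 / (sigma2 + tau2),
        delta_nc=delta * math.sqrt(data.k) / math.sqrt(sigma2),
    )


def power_grid(
    k: int,
    delta_grid,
    i2_grid,
    spec: TestSpec = TestSpec(),
    method: str = "mixture",
) -> np.ndarray:
    """Matrix of powers over a (Delta, I2) grid for planning-stage contours.

    ``method`` is ``"mixture"`` (the k-dependent CDF of T, accounting for
    tau2 estimation) or ``"no_uncertainty"`` (the closed form).  Rows index
    ``delta_grid``, columns ``i2_grid``; both must be sorted ascending.
    """
    delta_grid = np.asarray(delta_grid, dtype=float)
    i2_grid = np.asarray(i2_grid, dtype=float)
    for g, name in ((delta_grid, "delta_grid"), (i2_grid, "i2_grid")):
        if np.any(np.diff(g) < 0):
            raise ValidationError(f"{name} must be sorted ascending")
    out = np.empty((delta_grid.size, i2_grid.size))
    if method == "no_uncertainty":
        for j, i2 in enumerate(i2_grid):
            for i, d in enumerate(delta_grid):
                out[i, j] = power_no_uncertainty(d, i2, spec).power
    elif method == "mixture":
        for j, i2 in enumerate(i2_grid):
            for i, d in enumerate(delta_grid):
                out[i, j] = power_re_equal(EqualSizeScenario(k=k, i2=i2, delta_nc=d), spec).power
    else:
        raise ValidationError(f"unknown grid method {method!r}; use mixture|no_uncertainty")
    return out
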