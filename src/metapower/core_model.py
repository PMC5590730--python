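"""Domain types for meta-analysis power calculations.

A meta-analysis is represented by the per-study effect estimates ``y_i``
(for example log risk ratios) and their within-study standard errors
``sigma_i``, which are treated as fixed and known throughout.  Binary
2x2 count tables are converted to the log-risk-ratio scale at ingestion;
everything downstream consumes only ``(y_i, sigma_i)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "StudyRecord",
    "MetaAnalysisData",
    "TestSpec",
    "EffectScenario",
    "PowerResult",
    "MetaPowerError",
    "ValidationError",
    "InsufficientStudiesError",
    "UndefinedEffectError",
    "log_rr_from_counts",
    "validate_meta",
    "read_study_csv",
]


class MetaPowerError(Exception):
    """Base class for errors raised by metapower."""


class ValidationError(MetaPowerError, ValueError):
    """Invalid study-level input."""


class InsufficientStudiesError(MetaPowerError, ValueError):
    """An operation requires more studies than are available."""


class UndefinedEffectError(MetaPowerError, ValueError):
    """The effect estimate cannot be formed (e.g. zero events in both arms)."""


@dataclass(frozen=True)
class StudyRecord:
    """One study: effect estimate, standard error and optional 2x2 counts.

    Parameters
    ----------
    estimate : float
        Effect estimate ``y_i`` on the analysis scale (e.g. log risk ratio).
    se : float
        Within-study standard error ``sigma_i``; must be positive and finite.
        Treated as fixed and known in all downstream analyses.
    counts : tuple of int, optional
        ``(events_trt, n_trt, events_ctl, n_ctl)`` when the study came from a
        binary-outcome 2x2 table.
    """

    estimate: float
    se: float
    counts: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"study standard error must be positive and finite, got {self.se!r}")
        if not math.isfinite(self.estimate):
            raise ValidationError(f"study estimate must be finite, got {self.estimate!r}")
        if self.counts is not None:
            a, n1, c, n2 = self.counts
            for ev, n in ((a, n1), (c, n2)):
                if n < 1:
                    raise ValidationError("arm sample size must be >= 1")
                if not 0 <= ev <= n:
                    raise ValidationError(f"event count {ev} outside [0, {n}]")


@dataclass(frozen=True)
class MetaAnalysisData:
    """An ordered collection of studies forming one meta-analysis."""

    studies: tuple[StudyRecord, ...]
    ma_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        if len(self.studies) == 0:
            raise ValidationError("meta-analysis must contain at least one study")

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def y(self) -> np.ndarray:
        return np.array([s.estimate for s in self.studies], dtype=float)

    @property
    def se(self) -> np.ndarray:
        return np.array([s.se for s in self.studies], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        """Fixed-effect (inverse-variance) weights w_i = sigma_i^-2."""
        return 1.0 / self.se**2

    def weight_sum(self, r: int = 1) -> float:
        """S_r = sum of w_i^r."""
        return float(np.sum(self.weights**r))

    @classmethod
    def from_arrays(
        cls, y: Iterable[float], se: Iterable[float], ma_id: str | None = None
    ) -> "MetaAnalysisData":
        return cls(tuple(StudyRecord(float(a), float(b)) for a, b in zip(y, se, strict=True)), ma_id=ma_id)


@dataclass(frozen=True)
class TestSpec:
    """Two-sided hypothesis-test configuration.

    ``za`` is the standard-normal critical value, consistent with ``alpha``
    through ``alpha = 2 * Phi(-za)``.  The default ``za = 1.96`` gives the
    conventional 5% level.
    """

    mu0: float = 0.0
    alpha: float | None = None
    za: float | None = None

    __test__ = False  # not a pytest test class despite the name

    def __post_init__(self) -> None:
        if self.alpha is None and self.za is None:
            object.__setattr__(self, "za", 1.96)
        if self.za is None:
            object.__setattr__(self, "za", float(norm.isf(self.alpha / 2)))
        if self.alpha is None:
            object.__setattr__(self, "alpha", float(2 * norm.cdf(-self.za)))
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.za <= 0:
            raise ValidationError("critical value za must be positive")
        if abs(2 * norm.cdf(-self.za) - self.alpha) > 1e-6:
            raise ValidationError(
                f"alpha={self.alpha} and za={self.za} are inconsistent: 2*Phi(-za)={2 * norm.cdf(-self.za):.6g}"
            )


@dataclass(frozen=True)
class EffectScenario:
    """A 'truth' under which power is evaluated.

    ``delta`` is the average effect relative to the null (mu - mu0) and
    ``tau2`` the between-study variance.  When a common within-study SD
    ``sigma`` and a study count ``k`` are supplied, the equal-size
    reparameterisation is available: I^2 = tau2/(sigma^2 + tau2) and the
    noncentrality parameter Delta = delta * sqrt(k) / sigma.
    """

    delta: float
    tau2: float = 0.0
    sigma: float | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValidationError(f"between-study variance tau2 must be >= 0, got {self.tau2}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValidationError("common within-study sigma must be positive")
        if self.k is not None and self.k < 1:
            raise ValidationError("study count k must be >= 1")

    @property
    def i2(self) -> float:
        if self.sigma is None:
            raise ValidationError("I^2 requires a common within-study sigma")
        return self.tau2 / (self.sigma**2 + self.tau2)

    @property
    def delta_nc(self) -> float:
        """Noncentrality parameter Delta = delta * sqrt(k) / sigma."""
        if self.sigma is None or self.k is None:
            raise ValidationError("the noncentrality parameter requires sigma and k")
        return self.delta * math.sqrt(self.k) / self.sigma


@dataclass(frozen=True)
class PowerResult:
    """A computed power together with its method tag.

    ``mc_se`` is present exactly when the method is stochastic (Monte Carlo),
    in which case the binomial standard error sqrt(p(1-p)/n) is reported and
    the iteration count and seed are recorded.
    """

    power: float
    method: str
    mc_se: float | None = None
    n_iterations: int | None = None
    seed: int | None = None

    _STOCHASTIC = frozenset({"re_mc"})

    def __post_init__(self) -> None:
        if not -1e-12 <= self.power <= 1 + 1e-12:
            raise ValidationError(f"power {self.power} outside [0, 1]")
        object.__setattr__(self, "power", float(min(1.0, max(0.0, self.power))))
        if (self.method in self._STOCHASTIC) != (self.mc_se is not None):
            raise ValidationError("mc_se must be present iff the method is stochastic")

    def __float__(self) -> float:
        return self.power


def log_rr_from_counts(
    events_trt: int,
    n_trt: int,
    events_ctl: int,
    n_ctl: int,
    zero_cell_correction: float = 0.5,
) -> StudyRecord:
    """Convert a 2x2 binary-outcome table to a log-risk-ratio study record.

    The estimate is ``log[(a/n1) / (c/n2)]`` with the standard large-sample
    standard error ``sqrt(1/a - 1/n1 + 1/c - 1/n2)``.  When any cell of the
    table (events or non-events in either arm) is zero, ``zero_cell_correction``
    is added to both event counts and both denominators before computing both
    quantities; the original counts are retained on the record.

    Raises
    ------
    UndefinedEffectError
        If both arms have zero events and the correction is 0 (the log risk
        ratio is then undefined).
    ValidationError
        For invalid counts or a correction that leaves a zero cell.
    """
    if zero_cell_correction < 0:
        raise ValidationError("zero_cell_correction must be non-negative")
    for ev, n in ((events_trt, n_trt), (events_ctl, n_ctl)):
        if n < 1:
            raise ValidationError("arm sample size must be >= 1")
        if not 0 <= ev <= n:
            raise ValidationError(f"event count {ev} outside [0, {n}]")

    a, c = float(events_trt), float(events_ctl)
    n1, n2 = float(n_trt), float(n_ctl)
    has_zero_cell = a == 0 or c == 0 or a == n1 or c == n2
    if events_trt == 0 and events_ctl == 0 and zero_cell_correction == 0:
        raise UndefinedEffectError("zero events in both arms: log risk ratio undefined without a correction")
    if has_zero_cell:
        if zero_cell_correction == 0:
            raise ValidationError("table has a zero cell; a positive zero_cell_correction is required")
        a += zero_cell_correction
        c += zero_cell_correction
        n1 += zero_cell_correction
        n2 += zero_cell_correction

    estimate = math.log((a / n1) / (c / n2))
    var = 1 / a - 1 / n1 + 1 / c - 1 / n2
    return StudyRecord(estimate=estimate, se=math.sqrt(var), counts=(events_trt, n_trt, events_ctl, n_ctl))


def validate_meta(data: MetaAnalysisData) -> MetaAnalysisData:
    """Check the meta-analysis invariants and return the data unchanged.

    Positive finite standard errors are enforced per study; with k >= 2 the
    weight sums satisfy S_1^2 > S_2 strictly (Cauchy-Schwarz), which
    guarantees the DerSimonian-Laird denominator is positive.
    """
    for i, s in enumerate(data.studies):
        if not (math.isfinite(s.se) and s.se > 0):
            raise ValidationError(f"study {i}: non-positive or non-finite standard error {s.se!r}")
    s1, s2 = data.weight_sum(1), data.weight_sum(2)
    if not (math.isfinite(s1) and math.isfinite(s2)):
        raise ValidationError("weight sums are not finite")
    if data.k >= 2 and not s1 * s1 > s2:
        raise ValidationError("degenerate weights: S1^2 <= S2")
    return data


_YSE_COLS = ["ma_id", "study_id", "y", "se"]
_COUNT_COLS = ["ma_id", "study_id", "events_trt", "n_trt", "events_ctl", "n_ctl"]


def read_study_csv(
    path,
    zero_cell_correction: float = 0.5,
    drop_double_zero: bool = True,
) -> list[MetaAnalysisData]:
    """Read study-level CSV into a list of meta-analyses.

    Two layouts are accepted, distinguished by the header: effect-scale rows
    ``ma_id, study_id, y, se`` or binary-count rows
    ``ma_id, study_id, events_trt, n_trt, events_ctl, n_ctl`` (converted to
    log risk ratios).  Double-zero studies (no events in either arm) are
    dropped with a warning when ``drop_double_zero`` is set.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    out: list[MetaAnalysisData] = []
    if all(c in cols for c in _YSE_COLS):
        for ma_id, grp in df.groupby("ma_id", sort=False):
            studies = tuple(StudyRecord(float(r.y), float(r.se)) for r in grp.itertuples())
            out.append(validate_meta(MetaAnalysisData(studies, ma_id=str(ma_id))))
    elif all(c in cols for c in _COUNT_COLS):
        for ma_id, grp in df.groupby("ma_id", sort=False):
            studies = []
            for r in grp.itertuples():
                if drop_double_zero and r.events_trt == 0 and r.events_ctl == 0:
                    warnings.warn(
                        f"meta-analysis {ma_id}: dropping double-zero study {r.study_id}",
                        stacklevel=2,
                    )
                    continue
                studies.append(
                    log_rr_from_counts(
                        int(r.events_trt), int(r.n_trt), int(r.events_ctl), int(r.n_ctl),
                        zero_cell_correction=zero_cell_correction,
                    )
                )
            if studies:
                out.append(validate_meta(MetaAnalysisData(tuple(studies), ma_id=str(ma_id))))
            else:
                warnings.warn(f"meta-analysis {ma_id}: no usable studies, skipped", stacklevel=2)
    else:
        raise ValidationError(
            f"unrecognised CSV header {cols}; expected {_YSE_COLS} or {_COUNT_COLS}"
        )
    return out
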