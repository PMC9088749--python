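"""Adulteration quantitation with a non-isotopic isobaric internal standard.

The measurement statistic is the molar ratio

    MR_S = sum(ICA_S) / (sum(ICA_S) + sum(ICA_T))

where ICA_S are the isotope-cluster areas of the saffron crocin signals
(C-2, C-3 and C-4 only) and ICA_T the area of the curcumin internal
standard cluster at m/z 369.13.  A calibration line of response versus
known adulteration level (% w/w) is fitted by ordinary least squares with
the usual regression ANOVA; limits of detection and quantitation follow
the IUPAC blank-based formulas

    S_LOD = S_RB + 3 * sigma_RB        S_LOQ = S_RB + 10 * sigma_RB

evaluated on 0%-adulteration ("authentic saffron") replicates and mapped
into the percent domain through the calibration line.  Unknown samples are
quantified by inverse prediction with a first-order confidence interval.

The calibration can be fitted with either orientation of the response
(MR_S itself, which decreases with adulteration, or its complement); the
orientation is recorded on the model and all downstream formulas are
orientation-agnostic (they use |slope| where a direction-free width is
needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "QuantInput",
    "CalibrationModel",
    "DetectionLimits",
    "AdulterationEstimate",
    "molar_ratio",
    "fit_calibration",
    "detection_limits",
    "estimate_adulteration",
    "precision_accuracy",
]

#: Crocin signals entering the molar-ratio numerator.
QUANT_CROCINS = ("C-2", "C-3", "C-4")


@dataclass(frozen=True)
class QuantInput:
    """Areas for one replicate: crocin clusters and the curcumin cluster."""

    ica_s: Tuple[float, ...]
    ica_t: float
    replicate: int = 0
    level_percent: Optional[float] = None

    def __post_init__(self):
        if any(a < 0 for a in self.ica_s) or self.ica_t < 0:
            raise ValueError("isotope cluster areas must be >= 0")


def molar_ratio(q: QuantInput | None = None, *, ica_s: Sequence[float] | None = None,
                ica_t: float | None = None) -> float:
    """MR_S = sum(ICA_S) / (sum(ICA_S) + ICA_T), in [0, 1]."""
    if q is not None:
        ica_s, ica_t = q.ica_s, q.ica_t
    s = float(sum(ica_s))
    total = s + float(ica_t)
    if total <= 0:
        raise ValueError("all isotope cluster areas are zero")
    return s / total


@dataclass
class CalibrationModel:
    """An OLS calibration line with its regression ANOVA.

    ``orientation`` records which response was fitted ("MR_S" or
    "1-MR_S" or any caller-supplied label); the line itself is always
    response = intercept + slope * level.
    """

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    f_stat: float
    df: Tuple[int, int]
    resid_sd: float
    n: int
    slope_ci: Tuple[float, float]
    intercept_ci: Tuple[float, float]
    intercept_includes_zero: bool
    orientation: str
    x_mean: float
    sxx: float
    x_range: Tuple[float, float]

    def predict(self, level: float) -> float:
        return self.intercept + self.slope * level

    def invert(self, response: float) -> float:
        if abs(self.slope) < 1e-12:
            raise ZeroDivisionError("calibration slope is (numerically) zero")
        return (response - self.intercept) / self.slope


def fit_calibration(
    levels: Sequence[float],
    responses: Sequence[float],
    orientation: str = "MR_S",
) -> CalibrationModel:
    """Ordinary least squares of response on adulteration level.

    Requires at least three distinct levels.  Standard errors come from the
    residual variance, the ANOVA F statistic carries (1, n-2) degrees of
    freedom, and 95% confidence intervals use the t(n-2) quantile.  The
    model records whether zero lies inside the intercept CI (the
    no-constant-bias check used to validate a calibration).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and responses must be equal-length 1-D")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    n = len(x)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    intercept_se, slope_se = res.bse
    ci = res.conf_int(alpha=0.05)
    resid_sd = float(np.sqrt(res.ssr / (n - 2)))
    f_stat = float(res.fvalue) if n > 2 else math.inf
    return CalibrationModel(
        slope=float(slope),
        slope_se=float(slope_se),
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        r2=float(res.rsquared),
        f_stat=f_stat,
        df=(1, n - 2),
        resid_sd=resid_sd,
        n=n,
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        intercept_includes_zero=bool(ci[0][0] <= 0.0 <= ci[0][1]),
        orientation=orientation,
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
        x_range=(float(x.min()), float(x.max())),
    )


def f_from_r2(r2: float, n: int) -> float:
    """Regression ANOVA identity F = R^2 (n-2) / (1 - R^2) for df (1, n-2)."""
    return r2 * (n - 2) / (1.0 - r2)


@dataclass
class DetectionLimits:
    """IUPAC blank-based detection and quantitation limits."""

    s_rb: float
    sigma_rb: float
    s_lod: float
    s_loq: float
    lod_percent: float
    loq_percent: float
    max_adulteration_percent: float


def detection_limits(
    blank_signals: Sequence[float],
    model: CalibrationModel,
) -> DetectionLimits:
    """Compute S_LOD/S_LOQ from blank replicates and map them to percent.

    Blanks are 0%-adulteration replicates measured through the same
    pipeline.  The signal-domain limits are S_RB + 3 sigma and
    S_RB + 10 sigma (sample SD, n-1 denominator); the percent-domain limits
    invert the calibration line, which for limits anchored at the blank
    mean reduces to k * sigma_RB / |slope|.  The complementary "maximum
    quantifiable adulteration" is 100 - LOD%.
    """
    blanks = np.asarray(blank_signals, dtype=float)
    if blanks.size < 3:
        raise ValueError("need at least 3 blank replicates")
    if abs(model.slope) < 1e-12:
        raise ZeroDivisionError("calibration slope is (numerically) zero")
    s_rb = float(blanks.mean())
    sigma_rb = float(blanks.std(ddof=1))
    s_lod = s_rb + 3.0 * sigma_rb
    s_loq = s_rb + 10.0 * sigma_rb
    lod_percent = abs(model.invert(s_lod) - model.invert(s_rb))
    loq_percent = abs(model.invert(s_loq) - model.invert(s_rb))
    return DetectionLimits(
        s_rb=s_rb,
        sigma_rb=sigma_rb,
        s_lod=s_lod,
        s_loq=s_loq,
        lod_percent=lod_percent,
        loq_percent=loq_percent,
        max_adulteration_percent=100.0 - lod_percent,
    )


@dataclass
class AdulterationEstimate:
    """Inverse-prediction result for one measured response."""

    level_percent: float
    se: float
    ci95: Tuple[float, float]
    extrapolated: bool


def estimate_adulteration(
    response: float,
    model: CalibrationModel,
    n_sample: int = 1,
) -> AdulterationEstimate:
    """Invert the calibration line for one measured response.

    The standard error uses the first-order inverse-prediction formula
    se = (s/|b|) sqrt(1/m + 1/n + (x - x_bar)^2 / Sxx) with m the number of
    sample replicates averaged into ``response``.  Responses outside the
    calibrated range are flagged as extrapolated.
    """
    if model.orientation in ("MR_S", "1-MR_S") and not 0.0 <= response <= 1.0:
        raise ValueError("molar-ratio response must lie in [0, 1]")
    level = model.invert(response)
    se = (model.resid_sd / abs(model.slope)) * math.sqrt(
        1.0 / n_sample + 1.0 / model.n + (level - model.x_mean) ** 2 / model.sxx
    )
    tcrit = stats.t.ppf(0.975, model.df[1])
    lo, hi = model.x_range
    return AdulterationEstimate(
        level_percent=level,
        se=se,
        ci95=(level - tcrit * se, level + tcrit * se),
        extrapolated=not lo <= level <= hi,
    )


def precision_accuracy(
    estimates: Sequence[float],
    true_level: float,
    convention: str = "ratio",
) -> Tuple[float, float]:
    """RSD% and accuracy% of replicate estimates against a known level.

    RSD% = 100 * SD / mean (sample SD).  Accuracy follows the
    mean-over-true convention, accuracy% = 100 * mean / true, matching how
    spiked-recovery results are conventionally tabulated here; pass
    ``convention="bias"`` for 100 * (1 - |mean - true| / true).
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need at least 2 estimates")
    if true_level == 0:
        raise ValueError("true level must be nonzero")
    mean = float(est.mean())
    rsd = 100.0 * float(est.std(ddof=1)) / mean
    if convention == "ratio":
        accuracy = 100.0 * mean / true_level
    elif convention == "bias":
        accuracy = 100.0 * (1.0 - abs(mean - true_level) / true_level)
    else:
        raise ValueError(f"unknown accuracy convention {convention!r}")
    return rsd, accuracy
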