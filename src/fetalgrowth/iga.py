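"""Individualized growth assessment (IGA).

Each fetus serves as its own control: second-trimester scans determine a
Rossavik growth model per anatomical parameter,

    P(t) = c * (t - t0) ** (k + s * (t - t0)),

with the base exponent k and start age t0 fixed per parameter (configuration
assets) and the scale c and slope s fitted per fetus. The fitted curves
project third-trimester size and birthweight; observed third-trimester
measurements are compared to their projections as percent deviations,

    percent deviation = 100 * (observed - predicted) / predicted,

which feed two composite indices:

* mPGAS (negative version): the mean, over all parameter-visit records, of
  each record's negative excess below its 95% deviation reference range
  (zeros for in-range records). 95% reference range 0 to -0.17 %.
* GPRI_WT: 100 * actual birthweight / predicted birthweight, predicted at the
  actual gestation for deliveries <= 38 weeks and at 38 weeks otherwise.
  95% reference range 84-118 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, DataError, EligibilityError

__all__ = [
    "IgaConfig",
    "RossavikFit",
    "RossavikModel",
    "DeviationRecord",
    "IgaSummary",
    "fit_rossavik",
    "predict_value",
    "percent_deviation",
    "prediction_error_stats",
    "mpgas_neg",
    "gpri_wt",
    "predicted_delivery_ga",
    "MPGAS_THRESHOLD",
    "GPRI_RANGE",
    "PREDICTED_DELIVERY_CAP_DAYS",
]

MPGAS_THRESHOLD = -0.17          # % ; abnormal strictly below
GPRI_RANGE = (84.0, 118.0)       # % ; abnormal strictly outside
PREDICTED_DELIVERY_CAP_DAYS = 266  # 38 weeks

SECOND_TRIMESTER_MAX_DAYS = 196  # scans must be < 28 weeks
SEPARATION_RANGE_DAYS = (28, 56)  # consecutive fitting scans 4-8 weeks apart


@dataclass(frozen=True)
class IgaConfig:
    """Configuration assets for individualized growth assessment.

    ``k`` maps parameter name -> fixed Rossavik base exponent; ``ref_ranges``
    maps parameter name -> (lo, hi) 95% percent-deviation range used by mPGAS.
    Shipped defaults are synthetic-calibration values (see config module).
    """

    k: Mapping[str, float]
    t0_days: float = 0.0
    ref_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    mpgas_threshold: float = MPGAS_THRESHOLD
    gpri_range: tuple[float, float] = GPRI_RANGE

    def k_for(self, parameter_name: str) -> float:
        try:
            return float(self.k[parameter_name])
        except KeyError:
            raise ConfigError(
                f"no Rossavik base exponent configured for {parameter_name!r}"
            ) from None


@dataclass(frozen=True)
class RossavikFit:
    """Fitted individual growth curve for one parameter."""

    parameter_name: str
    c: float
    k: float
    s: float
    t0_days: float
    fit_window: tuple[float, ...]
    rss_log: float  # residual sum of squares on the log scale (0 for 2 scans)

    def predict(self, ga_days) -> float | np.ndarray:
        """Curve value at ga_days (> t0)."""
        ga = np.asarray(ga_days, float)
        if np.any(ga <= self.t0_days):
            raise DataError(f"prediction age must exceed t0 = {self.t0_days} d")
        u = ga - self.t0_days
        out = self.c * u ** (self.k + self.s * u)
        return float(out) if out.ndim == 0 else out


def _check_eligibility(ages: np.ndarray) -> None:
    if len(ages) < 2:
        raise EligibilityError("Rossavik fit needs >= 2 second-trimester scans")
    if len(np.unique(ages)) != len(ages):
        raise DataError("fitting scans must have distinct gestational ages")
    if np.any(ages >= SECOND_TRIMESTER_MAX_DAYS):
        raise EligibilityError(
            f"all fitting scans must be < {SECOND_TRIMESTER_MAX_DAYS} d (28 wk); "
            f"got ages {sorted(ages.tolist())}"
        )
    gaps = np.diff(np.sort(ages))
    lo, hi = SEPARATION_RANGE_DAYS
    if np.any((gaps < lo) | (gaps > hi)):
        raise EligibilityError(
            f"consecutive fitting scans must be separated by {lo}-{hi} d "
            f"(4-8 wk); got gaps {gaps.tolist()}"
        )


def fit_rossavik(
    scans: Sequence[tuple[float, float]],
    parameter_name: str,
    config: IgaConfig,
) -> RossavikFit:
    """Fit (c, s) of the Rossavik curve to second-trimester scans.

    On the log scale the model is linear in (ln c, s):

        ln P = ln c + k*ln u + s*u*ln u,   u = t - t0.

    With exactly two scans the 2x2 system is solved exactly; with more, by
    least squares. k and t0 come fixed from configuration.
    """
    arr = np.asarray(scans, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DataError("scans must be (ga_days, value) pairs")
    ages, values = arr[:, 0], arr[:, 1]
    if np.any(values <= 0):
        raise DataError("scan values must be positive")
    _check_eligibility(ages)
    k = config.k_for(parameter_name)
    t0 = config.t0_days
    u = ages - t0
    if np.any(u <= 0):
        raise DataError("scan ages must exceed t0")
    lnu = np.log(u)
    X = np.column_stack([np.ones_like(u), u * lnu])
    y = np.log(values) - k * lnu
    if len(ages) == 2:
        beta = np.linalg.solve(X, y)
        rss = 0.0
    else:
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(res[0]) if len(res) else float(np.sum((y - X @ beta) ** 2))
    return RossavikFit(
        parameter_name=parameter_name,
        c=float(np.exp(beta[0])),
        k=k,
        s=float(beta[1]),
        t0_days=t0,
        fit_window=tuple(sorted(ages.tolist())),
        rss_log=rss,
    )


def predict_value(fit: RossavikFit, ga_days) -> float:
    """Evaluate a fitted Rossavik curve (thin functional alias)."""
    return fit.predict(ga_days)


class RossavikModel:
    """statsmodels-style front end: model from scans, ``fit()`` -> RossavikFit."""

    def __init__(self, scans: Sequence[tuple[float, float]], parameter_name: str,
                 config: IgaConfig):
        self.scans = list(scans)
        self.parameter_name = parameter_name
        self.config = config

    def fit(self) -> RossavikFit:
        return fit_rossavik(self.scans, self.parameter_name, self.config)


# ---------------------------------------------------------------------------
# deviations and composite indices

def percent_deviation(observed: float, predicted: float) -> float:
    """100 * (observed - predicted) / predicted."""
    if not (predicted > 0):
        raise DataError(f"predicted must be > 0, got {predicted!r}")
    return 100.0 * (observed - predicted) / predicted


@dataclass(frozen=True)
class DeviationRecord:
    """Observed vs projected value for one parameter at one visit."""

    parameter_name: str
    ga_days: float
    observed: float
    predicted: float

    @property
    def percent_deviation(self) -> float:
        return percent_deviation(self.observed, self.predicted)


def prediction_error_stats(deviations: Sequence[float]) -> tuple[float, float]:
    """(systematic, random) prediction error: mean and sample SD (n-1)."""
    arr = np.asarray(deviations, float)
    if len(arr) < 2:
        raise DataError("prediction error statistics need >= 2 deviations")
    return float(np.mean(arr)), float(np.std(arr, ddof=1))


def mpgas_neg(
    deviations: Sequence[DeviationRecord],
    ref_ranges: Mapping[str, tuple[float, float]],
) -> float:
    """Negative-version modified Prenatal Growth Assessment Score, in %.

    Each record contributes min(0, deviation - lower reference bound); the
    score is the mean contribution over all parameter-visit records (zeros
    included), hence <= 0. Positive excursions above the upper bound are
    ignored by construction of the negative version.
    """
    if not deviations:
        raise DataError("mpgas_neg needs at least one deviation record")
    excesses = []
    for rec in deviations:
        if rec.parameter_name not in ref_ranges:
            raise ConfigError(
                f"no percent-deviation reference range configured for "
                f"{rec.parameter_name!r}"
            )
        lo, _hi = ref_ranges[rec.parameter_name]
        excesses.append(min(0.0, rec.percent_deviation - lo))
    return float(np.mean(excesses))


def gpri_wt(actual_bw_g: float, predicted_bw_g: float) -> float:
    """Growth potential realization index for birthweight, in %."""
    if not (predicted_bw_g > 0):
        raise DataError(f"predicted birthweight must be > 0, got {predicted_bw_g!r}")
    return 100.0 * actual_bw_g / predicted_bw_g


def predicted_delivery_ga(ga_delivery_days: float) -> float:
    """Gestation at which birthweight is predicted: actual if <= 38 wk, else 38 wk."""
    if not (ga_delivery_days > 0):
        raise DataError("delivery gestational age must be positive")
    return min(float(ga_delivery_days), float(PREDICTED_DELIVERY_CAP_DAYS))


@dataclass(frozen=True)
class IgaSummary:
    """Per-fetus composite IGA outcome."""

    subject_id: str
    mpgas_neg: float
    gpri_wt: float | None
    predicted_bw_g: float | None
    predicted_ga_used_days: float | None
    mpgas_threshold: float = MPGAS_THRESHOLD
    gpri_range: tuple[float, float] = GPRI_RANGE

    @property
    def mpgas_abnormal(self) -> bool:
        return self.mpgas_neg < self.mpgas_threshold

    @property
    def gpri_abnormal(self) -> bool:
        if self.gpri_wt is None:
            return False
        lo, hi = self.gpri_range
        return self.gpri_wt < lo or self.gpri_wt > hi

    @property
    def any_abnormal(self) -> bool:
        return self.mpgas_abnormal or self.gpri_abnormal


def summarize_subject(
    subject_id: str,
    deviations: Sequence[DeviationRecord],
    efw_fit: RossavikFit | None,
    actual_bw_g: float | None,
    ga_delivery_days: float | None,
    config: IgaConfig,
) -> IgaSummary:
    """Assemble the composite IGA summary for one fetus."""
    score = mpgas_neg(deviations, config.ref_ranges)
    pred_bw = None
    pred_ga = None
    gpri = None
    if efw_fit is not None and ga_delivery_days is not None:
        pred_ga = predicted_delivery_ga(ga_delivery_days)
        pred_bw = efw_fit.predict(pred_ga)
        if actual_bw_g is not None:
            gpri = gpri_wt(actual_bw_g, pred_bw)
    return IgaSummary(
        subject_id=subject_id,
        mpgas_neg=score,
        gpri_wt=gpri,
        predicted_bw_g=pred_bw,
        predicted_ga_used_days=pred_ga,
        mpgas_threshold=config.mpgas_threshold,
        gpri_range=config.gpri_range,
    )
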