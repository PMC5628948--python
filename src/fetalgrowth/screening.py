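"""Outcome classification and screening-performance evaluation.

Covers the delivery side of the analysis: customized birthweight centiles
(generic Gardosi-style model), SGA/FGR/LGA classification, integer confusion
tables and their derived metrics, ROC AUC with DeLong's paired comparison,
birthweight regression summaries, and the assembly of a screening-performance
table (one row per predictor x outcome).

Printed screening tables round percentages to integers, positive likelihood
ratios to 1 decimal and negative ones to 2; published values are consistent
with rounding half away from zero in two stages (to 1 decimal, then to
integer), and :func:`display_percent` follows that convention.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, skew
from sklearn.metrics import roc_auc_score

from .config import CustomizationModel, default_customization_model
from .errors import (
    AmbiguityError,
    CollinearityError,
    DataError,
    DegenerateTableError,
    InconsistencyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeRecord",
    "ConfusionTable",
    "ScreeningMetrics",
    "customized_centile",
    "classify_outcome",
    "confusion_metrics",
    "reconstruct_confusion",
    "roc_auc",
    "delong_compare",
    "birthweight_regression",
    "screening_table",
    "round_half_away",
    "display_percent",
]

SGA_CUTOFF = 10.0
FGR_CUTOFF = 3.0
LGA_CUTOFF = 90.0


# ---------------------------------------------------------------------------
# customized centiles and outcome classes

def customized_centile(
    birthweight_g: float,
    ga_delivery_days: float,
    maternal_height_cm: float,
    maternal_weight_kg: float,
    parity: int,
    ethnicity: str,
    sex: str,
    model: CustomizationModel | None = None,
) -> float:
    """Customized birthweight centile (0-100) under a Gardosi-style model."""
    m = model or default_customization_model()
    if birthweight_g <= 0:
        raise DataError("birthweight must be positive")
    expected = m.expected_weight(ga_delivery_days, maternal_height_cm,
                                 maternal_weight_kg, parity, ethnicity, sex)
    z = math.log(birthweight_g / expected) / m.sigma_log
    return 100.0 * float(norm.cdf(z))


def classify_outcome(centile: float) -> str:
    """FGR (<3rd), SGA (3rd-<10th), LGA (>90th), else AGA; strict cutoffs."""
    if not (0.0 <= centile <= 100.0):
        raise DataError(f"centile {centile} outside [0, 100]")
    if centile < FGR_CUTOFF:
        return "FGR"
    if centile < SGA_CUTOFF:
        return "SGA"
    if centile > LGA_CUTOFF:
        return "LGA"
    return "AGA"


@dataclass(frozen=True)
class OutcomeRecord:
    """Delivery outcome with its customized centile and class."""

    subject_id: str
    birthweight_g: float
    ga_delivery_days: float
    maternal_height_cm: float
    maternal_weight_kg: float
    parity: int
    ethnicity: str
    sex: str
    customized_centile: float
    outcome_class: str

    def __post_init__(self) -> None:
        if classify_outcome(self.customized_centile) != self.outcome_class:
            raise DataError(
                f"class {self.outcome_class!r} inconsistent with centile "
                f"{self.customized_centile} for {self.subject_id!r}"
            )


# ---------------------------------------------------------------------------
# confusion tables

@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise DataError(f"{name}={v!r} must be a non-negative integer")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @property
    def prevalence(self) -> float:
        return self.positives / (self.positives + self.negatives)


@dataclass(frozen=True)
class ScreeningMetrics:
    """Percent sensitivity/specificity/PPV/NPV and likelihood ratios.

    ``None`` marks an undefined quantity (LR+ at 100% specificity, PPV with
    no positive calls) — printed as a dash in report tables.
    """

    sensitivity: float
    specificity: float
    lr_pos: float | None
    lr_neg: float
    ppv: float | None
    npv: float


def confusion_metrics(t: ConfusionTable) -> ScreeningMetrics:
    if t.positives == 0 or t.negatives == 0:
        raise DegenerateTableError("confusion table has an empty outcome margin")
    sens = t.tp / t.positives
    spec = t.tn / t.negatives
    lr_pos = None if t.fp == 0 else sens / (t.fp / t.negatives)
    lr_neg = (t.fn / t.positives) / (t.tn / t.negatives) if t.tn else math.inf
    ppv = None if (t.tp + t.fp) == 0 else 100.0 * t.tp / (t.tp + t.fp)
    npv = 100.0 * t.tn / (t.tn + t.fn) if (t.tn + t.fn) else math.nan
    return ScreeningMetrics(
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        ppv=ppv,
        npv=npv,
    )


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed clinical tables).

    The value is first snapped to 12 significant digits so that exact halves
    reached through binary division (e.g. 105/2/2 = 26.25) round up as a
    decimal calculator would.
    """
    x = float(f"{x:.12g}")
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def display_percent(x: float) -> int:
    """Integer display value: round to 1 decimal, then to integer."""
    return int(round_half_away(round_half_away(x, 1), 0))


def reconstruct_confusion(n_pos: int, n_neg: int, sens_printed: int,
                          spec_printed: int) -> ConfusionTable:
    """Unique integer counts consistent with printed sensitivity/specificity.

    Finds the (tp, tn) whose percentages round (half away from zero) to the
    printed integers; raises if none or several exist.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise DataError("group sizes must be positive")
    tps = [tp for tp in range(n_pos + 1)
           if round_half_away(100.0 * tp / n_pos) == sens_printed]
    tns = [tn for tn in range(n_neg + 1)
           if round_half_away(100.0 * tn / n_neg) == spec_printed]
    if not tps or not tns:
        raise InconsistencyError(
            f"no integer counts give sens {sens_printed}% of {n_pos} "
            f"and spec {spec_printed}% of {n_neg}"
        )
    if len(tps) > 1 or len(tns) > 1:
        raise AmbiguityError(
            f"multiple solutions: tp candidates {tps}, tn candidates {tns}"
        )
    tp, tn = tps[0], tns[0]
    return ConfusionTable(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


# ---------------------------------------------------------------------------
# ROC / AUC

def _check_labels(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise DegenerateTableError("ROC needs both outcome classes present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC with higher score predicting the positive class (ties count half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise DataError("scores and labels must have equal length")
    _check_labels(labels)
    return float(roc_auc_score(labels, scores))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)  # V10 (per positive), V01 (per negative)


def delong_compare(scores_a: Sequence[float], scores_b: Sequence[float],
                   labels: Sequence[int]) -> tuple[float, float, float, float]:
    """DeLong's paired comparison of two correlated AUCs.

    Returns (auc_a, auc_b, z, p) with a two-sided normal p-value; the variance
    of the AUC difference comes from the empirical covariance of the placement
    values across the shared subjects.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if not (len(a) == len(b) == len(labels)):
        raise DataError("paired scores and labels must have equal length")
    _check_labels(labels)
    pos_mask = labels == 1
    v10 = np.empty((2, pos_mask.sum()))
    v01 = np.empty((2, (~pos_mask).sum()))
    aucs = np.empty(2)
    for i, s in enumerate((a, b)):
        v10[i], v01[i] = _placements(s[pos_mask], s[~pos_mask])
        aucs[i] = v10[i].mean()
    m, n = v10.shape[1], v01.shape[1]
    if m < 2 or n < 2:
        raise DataError("DeLong comparison needs >= 2 subjects per class")
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    contrast = np.array([1.0, -1.0])
    var = contrast @ s10 @ contrast / m + contrast @ s01 @ contrast / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        z = 0.0
    else:
        z = float(diff / math.sqrt(var))
    p = float(2.0 * norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), z, p


# ---------------------------------------------------------------------------
# birthweight regression

@dataclass(frozen=True)
class RegressionSummary:
    predictor: str
    coefficient: float
    conf_int: tuple[float, float]
    r_squared: float
    aic: float  # statsmodels convention: -2 loglik + 2 k
    n: int
    log10_transformed: bool


def birthweight_regression(
    cohort: pd.DataFrame,
    predictor: str,
    adjusters: Sequence[str] = ("ga_at_scan_days", "ga_delivery_days"),
    outcome: str = "birthweight_g",
    skew_threshold: float = 1.0,
) -> RegressionSummary:
    """OLS of birthweight on a predictor plus gestational-age adjusters.

    Positively skewed predictors (sample skewness above ``skew_threshold``)
    are transformed to base-10 logarithms before fitting, mirroring standard
    biometry practice; the returned flag records whether that happened.
    """
    cols = [outcome, predictor, *adjusters]
    if len(set(cols)) != len(cols):
        raise CollinearityError(
            f"predictor {predictor!r} duplicated among adjusters {list(adjusters)}"
        )
    data = cohort[cols].dropna()
    if len(data) < 10:
        raise DataError(f"need >= 10 complete cases, got {len(data)}")
    x = data[predictor].to_numpy(float)
    transformed = False
    if skew(x, bias=False) > skew_threshold:
        if np.any(x <= 0):
            raise DataError("cannot log-transform a non-positive predictor")
        x = np.log10(x)
        transformed = True
    X = np.column_stack([x] + [data[a].to_numpy(float) for a in adjusters])
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            f"design matrix is rank deficient for predictor {predictor!r} "
            f"with adjusters {list(adjusters)}"
        )
    res = sm.OLS(data[outcome].to_numpy(float), X).fit()
    ci = res.conf_int()[1]  # row 1 = predictor (row 0 is the constant)
    return RegressionSummary(
        predictor=predictor,
        coefficient=float(res.params[1]),
        conf_int=(float(ci[0]), float(ci[1])),
        r_squared=float(res.rsquared),
        aic=float(res.aic),
        n=int(res.nobs),
        log10_transformed=transformed,
    )


# ---------------------------------------------------------------------------
# screening table

def _ga_adjusted_score(values: np.ndarray, ga_days: np.ndarray) -> np.ndarray:
    """Residual of ln(value) on GA — the size deficit signal at varying scan age."""
    X = sm.add_constant(ga_days.astype(float))
    res = sm.OLS(np.log(values), X).fit()
    return np.asarray(res.resid)


def _logistic_score(labels: np.ndarray, values: np.ndarray,
                    ga_days: np.ndarray) -> np.ndarray:
    """Predicted probability from logit(outcome ~ ln value + GA); falls back
    to the GA-adjusted deficit score under separation/non-convergence."""
    X = sm.add_constant(np.column_stack([np.log(values), ga_days.astype(float)]))
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(labels, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.params)):
                raise ValueError("non-finite logistic coefficients")
            return np.asarray(fit.predict(X))
    except Exception:  # perfect separation on small cohorts
        return -_ga_adjusted_score(values, ga_days)


def screening_table(
    analysis: pd.DataFrame,
    predictors: Mapping[str, str],
    outcomes: Mapping[str, str] = (("SGA", "is_sga"), ("FGR", "is_fgr")),
    threshold_centile: float = 10.0,
    threshold_rule: str = "cohort_ga_adjusted",
    score_rule: str = "logistic",
) -> pd.DataFrame:
    """Screening-performance rows: one per predictor x outcome.

    ``analysis`` holds one row per subject with a third-trimester scan:
    predictor columns (positive continuous values), ``ga_at_scan_days``, and
    binary outcome columns. Dichotomization: a positive screen is a predictor
    below the ``threshold_centile`` of the cohort's GA-adjusted distribution
    (``cohort_ga_adjusted``), or below ``threshold_centile`` directly when the
    predictor is already a centile (``direct_centile`` — used for centile
    predictors regardless of rule). AUC is computed on logistic-regression
    scores (``logistic``) or on the GA-adjusted deficit (``deficit``).
    """
    if isinstance(outcomes, tuple):
        outcomes = dict(outcomes)
    rows = []
    for pred_label, col in predictors.items():
        sub = analysis.dropna(subset=[col, "ga_at_scan_days"])
        values = sub[col].to_numpy(float)
        ga = sub["ga_at_scan_days"].to_numpy(float)
        is_centile = col.endswith("centile")
        if is_centile or threshold_rule == "direct_centile":
            screen_pos = values < threshold_centile
            deficit = -values.astype(float)
        elif threshold_rule == "cohort_ga_adjusted":
            resid = _ga_adjusted_score(values, ga)
            cut = np.quantile(resid, threshold_centile / 100.0)
            screen_pos = resid < cut
            deficit = -resid
        else:
            raise DataError(f"unknown threshold rule {threshold_rule!r}")
        for out_label, out_col in outcomes.items():
            labels = sub[out_col].to_numpy(int)
            t = ConfusionTable(
                tp=int(np.sum(screen_pos & (labels == 1))),
                fp=int(np.sum(screen_pos & (labels == 0))),
                tn=int(np.sum(~screen_pos & (labels == 0))),
                fn=int(np.sum(~screen_pos & (labels == 1))),
            )
            metrics = confusion_metrics(t)
            if score_rule == "logistic" and not is_centile:
                score = _logistic_score(labels, values, ga)
            else:
                score = deficit
            auc = roc_auc(score, labels)
            rows.append({
                "predictor": pred_label,
                "outcome": out_label,
                "tp": t.tp, "fp": t.fp, "tn": t.tn, "fn": t.fn,
                "auc": auc,
                "sensitivity_pct": metrics.sensitivity,
                "specificity_pct": metrics.specificity,
                "lr_pos": metrics.lr_pos,
                "lr_neg": metrics.lr_neg,
                "ppv_pct": metrics.ppv,
                "npv_pct": metrics.npv,
                "auc_display": round_half_away(auc, 2),
                "sens_display": display_percent(metrics.sensitivity),
                "spec_display": display_percent(metrics.specificity),
                "lr_pos_display": (None if metrics.lr_pos is None
                                   else round_half_away(metrics.lr_pos, 1)),
                "lr_neg_display": round_half_away(metrics.lr_neg, 2),
                "ppv_display": (None if metrics.ppv is None
                                else display_percent(metrics.ppv)),
                "npv_display": display_percent(metrics.npv),
            })
    return pd.DataFrame(rows)
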