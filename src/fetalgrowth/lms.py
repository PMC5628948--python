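"""LMS (Box-Cox) growth references: construction, storage, application.

The LMS method summarizes how the distribution of a measurement changes with
age by three curves: the Box-Cox power L(t) that renders the data normal, the
median M(t), and the coefficient of variation S(t). A measurement y at age t
maps to a z-score

    z = ((y/M)^L - 1) / (L*S)        (L != 0)
    z = ln(y/M) / S                  (L == 0, the analytic limit)

and centile p maps back through the inverse at z = Phi^-1(p).

Three ways to obtain a model live here:

* :func:`fit_lms_curves` / :class:`LMSGrowthModel` — penalized-likelihood fit
  of cubic smoothing-spline L, M, S curves to raw (age, value) scans, with the
  flexibility of each curve prescribed as equivalent degrees of freedom.
* :func:`backsolve_lms` — recover a single age's (L, M, S) from a published
  row of centile values, enabling validation against printed tables when the
  raw data are not deposited.
* :func:`model_from_centile_table` — back-solve every row of a weekly table
  into an age-indexed model.

A note on the shipped thigh-volume table: its seven columns are labelled
5/10/25/50/75/90/95, but the printed values are only consistent with a
Box-Cox-normal family at the channel positions 3/10/25/50/75/90/97 — the
default centile set of LMS charting software (see docs/methods.md). Back-solve
validation therefore uses :data:`TABLE_PROBS_CONSISTENT`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from scipy.stats import norm

from ._smoothing import penalty_matrix, smooth_spline
from .biometry import BiometryScan
from .errors import (
    DataError,
    ExtrapolationError,
    FitError,
    SupportError,
    TableLookupError,
)

__all__ = [
    "lms_zscore",
    "lms_centile_value",
    "backsolve_lms",
    "fit_lms_curves",
    "CentileTable",
    "LMSModel",
    "LMSGrowthModel",
    "LMSResult",
    "tvol_reference",
    "tvol_reference_lookup",
    "measurement_to_centile",
    "model_from_centile_table",
    "TABLE_PROBS_PRINTED",
    "TABLE_PROBS_CONSISTENT",
]

#: Column labels as printed in the shipped weekly TVol table.
TABLE_PROBS_PRINTED = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)
#: Channel positions the printed values are actually consistent with.
TABLE_PROBS_CONSISTENT = (0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97)

_L_EPS = 1e-8


# ---------------------------------------------------------------------------
# scalar/array LMS transforms

def lms_zscore(y, L, M, S):
    """z-score of measurement y under Box-Cox parameters (L, M, S)."""
    y = np.asarray(y, float)
    L = np.asarray(L, float)
    M = np.asarray(M, float)
    S = np.asarray(S, float)
    if np.any(y <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise DataError("lms_zscore requires y > 0, M > 0, S > 0")
    ratio = y / M
    with np.errstate(over="raise"):
        z = np.where(
            np.abs(L) < _L_EPS,
            np.log(ratio) / S,
            (np.power(ratio, np.where(np.abs(L) < _L_EPS, 1.0, L)) - 1.0)
            / (np.where(np.abs(L) < _L_EPS, 1.0, L) * S),
        )
    return z if z.ndim else float(z)


def lms_centile_value(p, L, M, S):
    """Measurement value at centile p (0 < p < 1) — inverse of lms_zscore."""
    p = np.asarray(p, float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise DataError("centile probability must lie strictly in (0, 1)")
    L = np.asarray(L, float)
    M = np.asarray(M, float)
    S = np.asarray(S, float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise DataError("lms_centile_value requires M > 0 and S > 0")
    z = norm.ppf(p)
    base = 1.0 + L * S * z
    if np.any((np.abs(L) >= _L_EPS) & (base <= 0)):
        raise SupportError("centile outside the Box-Cox support (1 + L*S*z <= 0)")
    safe_L = np.where(np.abs(L) < _L_EPS, 1.0, L)
    v = np.where(
        np.abs(L) < _L_EPS,
        M * np.exp(S * z),
        M * np.power(np.where(base > 0, base, 1.0), 1.0 / safe_L),
    )
    return v if v.ndim else float(v)


# ---------------------------------------------------------------------------
# back-solving printed rows

def backsolve_lms(values: Sequence[float], probs: Sequence[float] = TABLE_PROBS_CONSISTENT):
    """Recover (L, M, S) from one row of centile values by least squares.

    Needs >= 4 strictly increasing values. Deterministic: a coarse profile
    over L (for fixed L the model is linear on the y^L scale) picks the start,
    then a bounded Levenberg-Marquardt refine on the original scale
    (L in [-3, 3], S in (0, 1)) polishes it.

    Returns (L, M, S, rms_residual).
    """
    vals = np.asarray(values, float)
    probs_arr = np.asarray(probs, float)
    if len(vals) != len(probs_arr) or len(vals) < 4:
        raise DataError("backsolve_lms needs >= 4 centile/value pairs")
    if np.any(np.diff(vals) <= 0):
        raise DataError("centile values must be strictly increasing across probabilities")
    if np.any(np.diff(probs_arr) <= 0):
        raise DataError("probabilities must be strictly increasing")
    z = norm.ppf(probs_arr)

    def predict(L, M, S):
        base = 1.0 + L * S * z
        if abs(L) < _L_EPS:
            return M * np.exp(S * z)
        if np.any(base <= 0):
            return None
        return M * base ** (1.0 / L)

    # profile start: for fixed L regress vals^L (or ln vals) on [1, z]
    A = np.column_stack([np.ones_like(z), z])
    best = None
    for L in np.linspace(-3.0, 3.0, 121):
        if abs(L) < _L_EPS:
            coef, *_ = np.linalg.lstsq(A, np.log(vals), rcond=None)
            M, S = float(np.exp(coef[0])), float(coef[1])
        else:
            coef, *_ = np.linalg.lstsq(A, vals ** L, rcond=None)
            if coef[0] <= 0:
                continue
            M = float(coef[0] ** (1.0 / L))
            S = float(coef[1] / (L * coef[0]))
        if not (0 < S < 1):
            continue
        pred = predict(L, M, S)
        if pred is None:
            continue
        sse = float(np.sum((pred - vals) ** 2))
        if best is None or sse < best[0]:
            best = (sse, L, M, S)
    if best is None:
        raise FitError("backsolve_lms: no admissible starting point found")
    _, L0, M0, S0 = best

    def resid(params):
        pred = predict(*params)
        if pred is None:
            return np.full_like(vals, 1e6)
        return pred - vals

    sol = least_squares(
        resid,
        [L0, M0, S0],
        bounds=([-3.0, vals[0] * 0.1, 1e-6], [3.0, vals[-1] * 10.0, 1.0 - 1e-9]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise FitError(f"backsolve_lms did not converge: {sol.message}")
    L, M, S = map(float, sol.x)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return L, M, S, rms


# ---------------------------------------------------------------------------
# centile tables

@dataclass(frozen=True)
class CentileTable:
    """A printed-style reference table: weekly ages x centile columns (cm³)."""

    ages_weeks: tuple[int, ...]
    probs: tuple[float, ...]
    values: np.ndarray  # shape (n_ages, n_probs)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.ages_weeks), len(self.probs)):
            raise DataError("CentileTable shape mismatch")
        if np.any(np.diff(v, axis=1) <= 0):
            raise DataError("centile values must increase across probabilities")
        if np.any(np.diff(v, axis=0) <= 0):
            raise DataError("centile values must increase across ages")
        object.__setattr__(self, "values", v)

    def row(self, ga_weeks: int) -> np.ndarray:
        try:
            i = self.ages_weeks.index(ga_weeks)
        except ValueError:
            raise TableLookupError(f"age {ga_weeks} wk not in table") from None
        return self.values[i]

    def lookup(self, ga_weeks: int, p: float) -> float:
        row = self.row(ga_weeks)
        for j, q in enumerate(self.probs):
            if abs(q - p) < 1e-12:
                return float(row[j])
        raise TableLookupError(f"probability {p} not a column of the table")

    @classmethod
    def from_csv(cls, path_or_buf) -> "CentileTable":
        df = pd.read_csv(path_or_buf)
        probs = tuple(float(c[1:]) / 100.0 for c in df.columns[1:])
        return cls(
            ages_weeks=tuple(int(a) for a in df.iloc[:, 0]),
            probs=probs,
            values=df.iloc[:, 1:].to_numpy(float),
        )


def tvol_reference() -> CentileTable:
    """The shipped weekly fractional-thigh-volume centile table (14-37 wk)."""
    ref = resources.files("fetalgrowth.data").joinpath("tvol_centiles_weekly.csv")
    with ref.open("r") as fh:
        return CentileTable.from_csv(fh)


def tvol_reference_lookup(ga_weeks: int, p: float) -> float:
    """Exact lookup into the shipped table, keyed by its printed column labels."""
    return tvol_reference().lookup(ga_weeks, p)


# ---------------------------------------------------------------------------
# age-indexed models

@dataclass
class LMSModel:
    """Age-indexed L, M, S curves for one measurement.

    Between grid points the three curves are interpolated independently by
    natural cubic splines; ages outside the grid raise ExtrapolationError.
    """

    measurement_name: str
    age_grid_days: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    edf: tuple[float, float, float] | None = None
    loglik: float | None = None

    def __post_init__(self) -> None:
        self.age_grid_days = np.asarray(self.age_grid_days, float)
        self.L = np.asarray(self.L, float)
        self.M = np.asarray(self.M, float)
        self.S = np.asarray(self.S, float)
        if np.any(np.diff(self.age_grid_days) <= 0):
            raise DataError("age grid must be strictly increasing")
        if np.any(self.M <= 0) or np.any(self.S <= 0):
            raise DataError("M and S must be positive everywhere")
        self._iL = CubicSpline(self.age_grid_days, self.L, bc_type="natural")
        self._iM = CubicSpline(self.age_grid_days, self.M, bc_type="natural")
        self._iS = CubicSpline(self.age_grid_days, self.S, bc_type="natural")

    def _params_at(self, ga_days):
        ga = np.asarray(ga_days, float)
        lo, hi = self.age_grid_days[0], self.age_grid_days[-1]
        if np.any(ga < lo - 1e-9) or np.any(ga > hi + 1e-9):
            raise ExtrapolationError(
                f"age {ga_days} d outside model grid [{lo:.0f}, {hi:.0f}]"
            )
        return self._iL(ga), self._iM(ga), self._iS(ga)

    def zscore(self, value, ga_days):
        L, M, S = self._params_at(ga_days)
        return lms_zscore(value, L, M, S)

    def centile_value(self, p, ga_days):
        L, M, S = self._params_at(ga_days)
        return lms_centile_value(p, L, M, S)

    def centile_of(self, value, ga_days):
        """Percentile (0-100) of a measurement at an age inside the grid."""
        return 100.0 * norm.cdf(self.zscore(value, ga_days))

    def to_json(self) -> str:
        return json.dumps(
            {
                "measurement_name": self.measurement_name,
                "age_grid_days": self.age_grid_days.tolist(),
                "L": self.L.tolist(),
                "M": self.M.tolist(),
                "S": self.S.tolist(),
                "edf": list(self.edf) if self.edf else None,
                "loglik": self.loglik,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LMSModel":
        d = json.loads(text)
        return cls(
            measurement_name=d["measurement_name"],
            age_grid_days=np.array(d["age_grid_days"]),
            L=np.array(d["L"]),
            M=np.array(d["M"]),
            S=np.array(d["S"]),
            edf=tuple(d["edf"]) if d.get("edf") else None,
            loglik=d.get("loglik"),
        )


def model_from_centile_table(
    table: CentileTable,
    probs: Sequence[float] = TABLE_PROBS_CONSISTENT,
    measurement_name: str = "tvol_cm3",
) -> LMSModel:
    """Back-solve every weekly row of a table into an age-indexed LMSModel."""
    Ls, Ms, Ss = [], [], []
    for row in table.values:
        L, M, S, _ = backsolve_lms(row, probs)
        Ls.append(L)
        Ms.append(M)
        Ss.append(S)
    return LMSModel(
        measurement_name=measurement_name,
        age_grid_days=np.array(table.ages_weeks, float) * 7.0,
        L=np.array(Ls),
        M=np.array(Ms),
        S=np.array(Ss),
    )


def measurement_to_centile(scan: BiometryScan, model: LMSModel) -> float:
    """Percentile (0-100) of the scan's modelled measurement at the scan age."""
    value = scan.get(model.measurement_name)
    if value is None:
        raise DataError(
            f"scan at {scan.ga_days} d lacks {model.measurement_name}"
        )
    return float(model.centile_of(value, scan.ga_days))


# ---------------------------------------------------------------------------
# penalized-likelihood fitting (Cole-Green)

def _loglik(y, L, M, S):
    z = lms_zscore(y, L, M, S)
    return np.sum(
        (L - 1.0) * np.log(y) - L * np.log(M) - np.log(S)
        - 0.5 * z ** 2 - 0.5 * np.log(2 * np.pi)
    ), z


def fit_lms_curves(
    scans: Sequence[tuple[float, float]] | np.ndarray,
    edf: tuple[float, float, float] = (1, 8, 4),
    measurement_name: str = "tvol_cm3",
    max_iter: int = 200,
    dev_tol: float = 1e-6,
) -> LMSModel:
    """Penalized-likelihood LMS fit with prescribed equivalent df per curve.

    ``scans`` is a sequence of (ga_days, value) pairs; ``edf`` gives the
    flexibility of the (L, M, S) curves in that order — 1 is a constant,
    2 a straight line, larger values cubic smoothing splines whose smoother
    trace matches the target. The fit is Fisher-scoring backfitting: each
    cycle refreshes one curve from its working response and expected-
    information weights, smoothed at the prescribed df, until the penalized
    deviance is stationary. Deterministic for fixed input and edf.
    """
    arr = np.asarray(scans, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DataError("scans must be (ga_days, value) pairs")
    x_all, y_all = arr[:, 0], arr[:, 1]
    if len(x_all) < 50:
        raise DataError(f"need >= 50 observations, got {len(x_all)}")
    if x_all.max() - x_all.min() < 70:
        raise DataError("observations must span >= 10 weeks of gestation")
    if np.any(y_all <= 0):
        raise DataError("values must be positive")

    order = np.argsort(x_all, kind="stable")
    x_all, y_all = x_all[order], y_all[order]
    xu, inv = np.unique(x_all, return_inverse=True)
    n_knots = len(xu)
    K = penalty_matrix(xu)
    edf_L, edf_M, edf_S = edf

    def aggregate(w, ystar):
        W = np.bincount(inv, weights=w, minlength=n_knots)
        Y = np.bincount(inv, weights=w * ystar, minlength=n_knots) / W
        return W, Y

    def smooth_update(curve_k, u, w, df):
        ystar = curve_k[inv] + u / w
        W, Y = aggregate(w, ystar)
        return smooth_spline(xu, Y, W, df, K=K).values

    # --- initialization: spline median on log scale, constant S, L = 1
    W0, Ylog = aggregate(np.ones_like(y_all), np.log(y_all))
    M_k = np.exp(smooth_spline(xu, Ylog, W0, max(edf_M, 2), K=K).values)
    S_k = np.full(n_knots, max(np.std(np.log(y_all) - np.log(M_k[inv])), 1e-3))
    L_k = np.ones(n_knots)

    dev_prev = np.inf
    dev = np.inf
    for iteration in range(max_iter):
        # M update
        L, M, S = L_k[inv], M_k[inv], S_k[inv]
        z = lms_zscore(y_all, L, M, S)
        u = (z / S + L * (z ** 2 - 1.0)) / M
        w = (1.0 + 2.0 * L ** 2 * S ** 2) / (M ** 2 * S ** 2)
        M_new = smooth_update(M_k, u, w, edf_M)
        M_k = np.clip(M_new, M_k * 0.5, M_k * 2.0)  # damped, keeps positivity

        # S update
        L, M, S = L_k[inv], M_k[inv], S_k[inv]
        z = lms_zscore(y_all, L, M, S)
        u = (z ** 2 - 1.0) / S
        w = 2.0 / S ** 2
        S_new = smooth_update(S_k, u, w, edf_S)
        S_k = np.clip(S_new, np.maximum(S_k * 0.5, 1e-4), np.minimum(S_k * 2.0, 1.0))

        # L update (numeric score; expected information approx 7 S^2 / 4)
        L, M, S = L_k[inv], M_k[inv], S_k[inv]
        delta = 1e-5
        lp, _ = _loglik_pointwise(y_all, L + delta, M, S)
        lm, _ = _loglik_pointwise(y_all, L - delta, M, S)
        u = (lp - lm) / (2 * delta)
        w = 7.0 * S ** 2 / 4.0
        L_new = smooth_update(L_k, u, w, edf_L)
        L_k = np.clip(L_new, L_k - 0.5, L_k + 0.5)
        L_k = np.clip(L_k, -5.0, 5.0)

        ll, _ = _loglik(y_all, L_k[inv], M_k[inv], S_k[inv])
        dev = -2.0 * ll
        if abs(dev_prev - dev) < dev_tol:
            break
        dev_prev = dev
    else:
        raise FitError(
            f"LMS fit did not converge in {max_iter} iterations; "
            f"last deviance change {abs(dev_prev - dev):.3e}"
        )

    return LMSModel(
        measurement_name=measurement_name,
        age_grid_days=xu,
        L=L_k,
        M=M_k,
        S=S_k,
        edf=tuple(float(e) for e in edf),
        loglik=float(-0.5 * dev),
    )


def _loglik_pointwise(y, L, M, S):
    z = lms_zscore(y, L, M, S)
    ll = (
        (L - 1.0) * np.log(y) - L * np.log(M) - np.log(S)
        - 0.5 * z ** 2 - 0.5 * np.log(2 * np.pi)
    )
    return ll, z


# ---------------------------------------------------------------------------
# statsmodels-style front end

class LMSGrowthModel:
    """Growth-reference model for one measurement over gestational age.

    Construct from raw longitudinal scans, then ``fit(edf=...)`` to obtain an
    :class:`LMSResult` carrying the fitted curves.
    """

    def __init__(self, ga_days, values, measurement_name: str = "tvol_cm3"):
        self.ga_days = np.asarray(ga_days, float)
        self.values = np.asarray(values, float)
        if self.ga_days.shape != self.values.shape:
            raise DataError("ga_days and values must have equal length")
        self.measurement_name = measurement_name

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str,
                       ga_col: str = "ga_days") -> "LMSGrowthModel":
        sub = df[[ga_col, value_col]].dropna()
        return cls(sub[ga_col].to_numpy(), sub[value_col].to_numpy(),
                   measurement_name=value_col)

    def fit(self, edf: tuple[float, float, float] = (1, 8, 4), **kwargs) -> "LMSResult":
        model = fit_lms_curves(
            np.column_stack([self.ga_days, self.values]),
            edf=edf, measurement_name=self.measurement_name, **kwargs,
        )
        return LMSResult(self, model)


class LMSResult:
    """Fitted LMS reference: curves, likelihood, centile machinery."""

    def __init__(self, parent: LMSGrowthModel, model: LMSModel):
        self.model_spec = parent
        self.lms = model

    @property
    def loglik(self) -> float:
        return self.lms.loglik

    def centile_value(self, p, ga_days):
        return self.lms.centile_value(p, ga_days)

    def zscore(self, value, ga_days):
        return self.lms.zscore(value, ga_days)

    def centile_table(self, ages_weeks: Sequence[int],
                      probs: Sequence[float] = TABLE_PROBS_CONSISTENT) -> CentileTable:
        ages = np.asarray(ages_weeks, int)
        vals = np.array([
            [self.lms.centile_value(p, wk * 7.0) for p in probs] for wk in ages
        ])
        return CentileTable(tuple(int(a) for a in ages), tuple(probs), vals)

    def summary(self) -> str:
        m = self.lms
        lines = [
            f"LMS growth reference for {m.measurement_name}",
            f"  n obs:      {len(self.model_spec.values)}",
            f"  age range:  {m.age_grid_days[0]:.0f}-{m.age_grid_days[-1]:.0f} d",
            f"  edf (L,M,S): {m.edf}",
            f"  log-likelihood: {m.loglik:.2f}",
            f"  L range: [{m.L.min():.3f}, {m.L.max():.3f}]",
            f"  M range: [{m.M.min():.3f}, {m.M.max():.3f}]",
            f"  S range: [{m.S.min():.4f}, {m.S.max():.4f}]",
        ]
        return "\n".join(lines)

    def plot_centiles(self, probs=TABLE_PROBS_CONSISTENT, ax=None):
        """Scatter the data with fitted centile curves overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model_spec.ga_days
        ax.plot(x / 7.0, self.model_spec.values, ".", ms=3, alpha=0.4, color="grey")
        grid = np.linspace(self.lms.age_grid_days[0], self.lms.age_grid_days[-1], 200)
        for p in probs:
            ax.plot(grid / 7.0, [self.lms.centile_value(p, g) for g in grid],
                    lw=1, label=f"{100 * p:g}")
        ax.set_xlabel("gestational age (weeks)")
        ax.set_ylabel(self.model_spec.measurement_name)
        ax.legend(title="centile", fontsize=7)
        return ax
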