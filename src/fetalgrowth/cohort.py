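"""Seeded synthetic longitudinal cohort with the structure the analysis assumes.

Each fetus carries latent Rossavik growth curves per biometric parameter
(shared fixed exponent k, individual scale c and slope s). A latent outcome
class (AGA / SGA / FGR / LGA) fixes a target customized birthweight centile;
an overall fetal size factor is solved in closed form so that the 3D EFW of
the latent curves at delivery matches the target weight. Growth-restricted
fetuses start from an unremarkable growth potential and then falter: after
``faltering_onset_days`` the slope of the soft-tissue parameters (fractional
thigh volume, and to a lesser degree abdominal and thigh circumference) is
decremented with value-continuity at onset, so third-trimester soft-tissue
growth flattens while head measurements are spared. Scans are the latent
curve values times multiplicative log-normal measurement noise; scan days
cluster in the four study visit windows. Birthweight is the (faltered) EFW
trajectory at delivery times a residual.

The generator is the study-conditions oracle for the test-suite: its defaults
are the cohort structure being emulated (n=115, ~21% SGA, ~9% FGR, ~2.6% LGA,
FGR delivering earlier), not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import (
    ROSSAVIK_CALIBRATION,
    ROSSAVIK_T0_DAYS,
    CustomizationModel,
    default_customization_model,
    efw_bpd_ac_tvol_synthetic,
)
from .errors import ConfigError

__all__ = ["CohortConfig", "PiecewiseRossavik", "inject_faltering", "generate_cohort"]

_PARAMS = ("bpd_mm", "hc_mm", "ac_mm", "fl_mm", "thigh_circ_mm", "tvol_cm3")

#: Between-subject SD of ln c and of s, per parameter (idiosyncratic shape
#: variation on top of the shared size factor).
_LNC_SD = {"bpd_mm": 0.015, "hc_mm": 0.015, "ac_mm": 0.02, "fl_mm": 0.02,
           "thigh_circ_mm": 0.025, "tvol_cm3": 0.02}
_S_SD = {"bpd_mm": 1e-5, "hc_mm": 1e-5, "ac_mm": 1e-5, "fl_mm": 1e-5,
         "thigh_circ_mm": 1.5e-5, "tvol_cm3": 2e-5}

#: How the faltering slope decrement distributes across parameters
#: (fraction of the TVol decrement); head and femur are spared.
_FALTER_SHARE = {"tvol_cm3": 1.0, "ac_mm": 0.17, "thigh_circ_mm": 0.375}

#: EFW = C * BPD^0.25 * AC^0.806 * TVol^0.55  =>  scaling all lengths by g and
#: volumes by g^3 scales EFW by g^(0.25 + 0.806 + 3*0.55).
_EFW_SIZE_EXPONENT = 0.25 + 0.806 + 3 * 0.55

#: Fetal growth decelerates after 38 weeks while the Rossavik projection keeps
#: climbing; birthweight is realized from the trajectory at a damped
#: post-38-week age so late-term weight gain is ~30% of the projected rate.
_LATE_TERM_DAMPING = 0.3
_TERM_CAP_DAYS = 266.0


def _bw_age(ga_delivery_days: float) -> float:
    if ga_delivery_days <= _TERM_CAP_DAYS:
        return float(ga_delivery_days)
    return _TERM_CAP_DAYS + _LATE_TERM_DAMPING * (ga_delivery_days - _TERM_CAP_DAYS)

_ETHNICITIES = ("european", "indian", "pakistani", "caribbean", "chinese",
                "mixed_other", "mixed_asian_european", "mixed_caribbean_european")
_ETHNICITY_P = (0.80, 0.022, 0.044, 0.044, 0.011, 0.022, 0.033, 0.024)


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 115
    visit_windows_days: tuple[tuple[int, int], ...] = (
        (98, 112), (140, 154), (182, 196), (238, 259),
    )  # half-open [lo, hi)
    frac_sga_target: float = 0.21   # includes FGR (<10th customized centile)
    frac_fgr_target: float = 0.09   # subset of SGA (<3rd)
    frac_lga_target: float = 0.026
    measurement_cv: Mapping[str, float] = field(default_factory=lambda: {
        "bpd_mm": 0.015, "hc_mm": 0.015, "ac_mm": 0.02, "fl_mm": 0.02,
        "thigh_circ_mm": 0.025, "tvol_cm3": 0.03,
    })
    bw_residual_cv: float = 0.025
    faltering_onset_days: int = 196
    faltering_s_decrement: float = 9e-4
    dropout_rate: float = 0.0
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("frac_sga_target", "frac_fgr_target", "frac_lga_target"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.frac_fgr_target > self.frac_sga_target:
            raise ConfigError("frac_fgr_target must not exceed frac_sga_target")
        if self.frac_sga_target + self.frac_lga_target > 1.0:
            raise ConfigError("class fractions exceed 1")
        prev_hi = 0
        for lo, hi in self.visit_windows_days:
            if not (prev_hi <= lo < hi):
                raise ConfigError("visit windows must be non-overlapping and increasing")
            prev_hi = hi
        if self.faltering_s_decrement < 0:
            raise ConfigError("faltering_s_decrement must be >= 0")


@dataclass(frozen=True)
class PiecewiseRossavik:
    """Rossavik curve with an optional slope break at ``onset_days``.

    Before onset: P(t) = exp(lnc) * t**(k + s*t). After onset the slope s is
    reduced by ``decrement`` and the scale re-set so the value is continuous
    at onset. ``decrement`` = 0 is the unbroken curve.
    """

    lnc: float
    k: float
    s: float
    t0_days: float = ROSSAVIK_T0_DAYS
    onset_days: float = np.inf
    decrement: float = 0.0

    def value(self, ga_days) -> np.ndarray:
        u = np.asarray(ga_days, float) - self.t0_days
        base = self.lnc + (self.k + self.s * u) * np.log(u)
        if self.decrement > 0:
            u_on = self.onset_days - self.t0_days
            post = base - self.decrement * (u * np.log(u) - u_on * np.log(u_on))
            base = np.where(u > u_on, post, base)
        return np.exp(base)


def inject_faltering(curve: PiecewiseRossavik, onset_days: float,
                     decrement: float) -> PiecewiseRossavik:
    """Return the curve with post-onset slope reduced by ``decrement``.

    Continuity of value at onset holds by construction. Raises if the
    post-onset curve would shrink anywhere over the physiologic range
    (growth may flatten, not reverse).
    """
    if decrement < 0:
        raise ConfigError("decrement must be >= 0")
    if not (0 < onset_days < 301):
        raise ConfigError("onset must lie within gestation")
    if decrement == 0:
        return curve
    out = PiecewiseRossavik(curve.lnc, curve.k, curve.s, curve.t0_days,
                            onset_days, decrement)
    u = np.arange(onset_days + 1.0, 295.0) - curve.t0_days
    s_post = curve.s - decrement
    dlogdt = (curve.k + s_post * u) / u + s_post * np.log(u)
    if np.any(dlogdt <= 0):
        raise ConfigError(
            "decrement produces negative post-onset growth over the physiologic range"
        )
    return out


def _draw_covariates(rng: np.random.Generator) -> dict:
    height = float(np.clip(rng.normal(164.0, 6.5), 145.0, 185.0))
    weight = float(np.clip(rng.normal(66.5, 10.0), 45.0, 110.0))
    parity = int(rng.choice([0, 1, 2, 3], p=[0.63, 0.25, 0.09, 0.03]))
    ethnicity = str(rng.choice(_ETHNICITIES, p=_ETHNICITY_P))
    sex = "male" if rng.random() < 0.5 else "female"
    return dict(maternal_height_cm=round(height, 1),
                maternal_weight_kg=round(weight, 1),
                parity=parity, ethnicity=ethnicity, sex=sex)


def _draw_class(rng: np.random.Generator, cfg: CohortConfig) -> str:
    p_fgr = cfg.frac_fgr_target
    p_sga_only = cfg.frac_sga_target - cfg.frac_fgr_target
    p_lga = cfg.frac_lga_target
    p_aga = 1.0 - p_fgr - p_sga_only - p_lga
    return str(rng.choice(["FGR", "SGA", "LGA", "AGA"],
                          p=[p_fgr, p_sga_only, p_lga, p_aga]))


def _draw_delivery_ga(rng: np.random.Generator, cls: str) -> int:
    if cls == "FGR":
        return int(np.clip(round(rng.normal(268.0, 8.0)), 252, 285))
    if cls == "SGA":
        return int(np.clip(round(rng.normal(279.0, 9.0)), 262, 294))
    if cls == "LGA":
        return int(np.clip(round(rng.normal(281.0, 7.0)), 266, 294))
    return int(np.clip(round(rng.normal(280.0, 8.0)), 262, 294))


def _draw_target_centile(rng: np.random.Generator, cls: str) -> float:
    # FGR draws its pre-faltering growth potential, not its final centile
    if cls == "FGR":
        return float(rng.uniform(20.0, 60.0))
    if cls == "SGA":
        return float(rng.uniform(3.5, 9.5))
    if cls == "LGA":
        return float(rng.uniform(90.5, 98.0))
    return float(rng.uniform(15.0, 85.0))


def generate_cohort(
    config: CohortConfig | None = None,
    customization: CustomizationModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (scans, outcomes, truth) DataFrames for one cohort.

    Deterministic for a fixed config (including its seed).
    """
    cfg = config or CohortConfig()
    cust = customization or default_customization_model()
    rng = np.random.default_rng(cfg.seed)
    efw_set = efw_bpd_ac_tvol_synthetic()
    efw_scale = efw_set.terms[0].coefficient

    def efw_from_curves(curves: dict[str, PiecewiseRossavik], t: float) -> float:
        bpd = float(curves["bpd_mm"].value(t)) / 10.0
        ac = float(curves["ac_mm"].value(t)) / 10.0
        tv = float(curves["tvol_cm3"].value(t))
        return efw_scale * bpd ** 0.25 * ac ** 0.806 * tv ** 0.55

    scan_rows, outcome_rows, truth_rows = [], [], []
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:03d}"
        cov = _draw_covariates(rng)
        cls = _draw_class(rng, cfg)
        ga_del = _draw_delivery_ga(rng, cls)
        p_target = _draw_target_centile(rng, cls)
        expected = cust.expected_weight(ga_del, cov["maternal_height_cm"],
                                        cov["maternal_weight_kg"], cov["parity"],
                                        cov["ethnicity"], cov["sex"])
        w_target = expected * float(np.exp(cust.sigma_log * norm.ppf(p_target / 100.0)))

        # idiosyncratic latent curves, then closed-form size factor
        curves: dict[str, PiecewiseRossavik] = {}
        for name in _PARAMS:
            lnc, k, s = ROSSAVIK_CALIBRATION[name]
            curves[name] = PiecewiseRossavik(
                lnc + rng.normal(0.0, _LNC_SD[name]),
                k,
                s + rng.normal(0.0, _S_SD[name]),
            )  # shared t0 from calibration
        t_bw = _bw_age(ga_del)
        g = (w_target / efw_from_curves(curves, t_bw)) ** (1.0 / _EFW_SIZE_EXPONENT)
        for name in _PARAMS:
            cur = curves[name]
            factor = 3.0 if name == "tvol_cm3" else 1.0  # volumes scale as g^3
            curves[name] = PiecewiseRossavik(
                cur.lnc + factor * np.log(g), cur.k, cur.s, cur.t0_days)

        faltered = cls == "FGR" and cfg.faltering_s_decrement > 0
        if faltered:
            for name, share in _FALTER_SHARE.items():
                curves[name] = inject_faltering(
                    curves[name], cfg.faltering_onset_days,
                    share * cfg.faltering_s_decrement)

        birthweight = efw_from_curves(curves, t_bw) * float(
            np.exp(rng.normal(0.0, cfg.bw_residual_cv)))

        # scans: one visit per window, noise is multiplicative log-normal
        n_visits = len(cfg.visit_windows_days)
        if cfg.dropout_rate > 0 and rng.random() < cfg.dropout_rate:
            n_visits = int(rng.integers(1, n_visits))
        for (lo, hi) in cfg.visit_windows_days[:n_visits]:
            hi_eff = min(hi, ga_del)  # no scans after delivery
            if hi_eff <= lo:
                continue
            day = int(rng.integers(lo, hi_eff))
            row = {"subject_id": sid, "ga_days": day}
            for name in _PARAMS:
                cv = cfg.measurement_cv.get(name, 0.0)
                noise = float(np.exp(rng.normal(0.0, cv))) if cv > 0 else 1.0
                row[name] = float(curves[name].value(day)) * noise
            scan_rows.append(row)

        outcome_rows.append(dict(
            subject_id=sid,
            birthweight_g=round(float(birthweight), 1),
            ga_delivery_days=ga_del,
            sex=cov["sex"],
            maternal_height_cm=cov["maternal_height_cm"],
            maternal_weight_kg=cov["maternal_weight_kg"],
            parity=cov["parity"],
            ethnicity=cov["ethnicity"],
        ))
        truth = dict(subject_id=sid, true_class=cls, target_centile=p_target,
                     size_factor=float(g), faltered=faltered)
        for name in _PARAMS:
            truth[f"lnc_{name}"] = curves[name].lnc
            truth[f"s_{name}"] = curves[name].s
        truth_rows.append(truth)

    scans = pd.DataFrame(scan_rows)
    outcomes = pd.DataFrame(outcome_rows)
    truth = pd.DataFrame(truth_rows)
    return scans, outcomes, truth
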