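"""Configuration assets: coefficient sets, reference curves, pipeline config.

All constants that drive the analysis live here rather than inline in the
algorithms, so sensitivity analyses can vary them from a YAML file:
classification thresholds, Rossavik base exponents, EFW coefficient sets,
the customized-birthweight model, and mPGAS deviation reference ranges.

Calibration provenance. The per-parameter Rossavik population constants are
synthetic-calibration values: (ln c, k, s) solved from standard mid-pregnancy
biometry anchor values at 105/175/252 days (and, for fractional thigh volume,
least squares against the shipped weekly reference medians at the scan-window
weeks). The EFW(BPD-AC-TVol) coefficient set shipped as usable default is
likewise synthetic-calibration — a single power-law term scaled so the median
term weight is ~3.5 kg; the published coefficient sets it stands in for are
not redistributed here, and a placeholder set that refuses evaluation is
provided for users who want to transcribe one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

from .biometry import EfwCoefficients, EfwTerm, HADLOCK_BPD_AC_FL
from .errors import ConfigError
from .iga import GPRI_RANGE, MPGAS_THRESHOLD, IgaConfig

__all__ = [
    "ROSSAVIK_CALIBRATION",
    "rossavik_k_defaults",
    "efw_bpd_ac_tvol_synthetic",
    "EFW_BPD_AC_TVOL_PLACEHOLDER",
    "MPGAS_REF_RANGES_SYNTHETIC",
    "default_iga_config",
    "CustomizationModel",
    "default_customization_model",
    "PipelineConfig",
]

# ---------------------------------------------------------------------------
# Rossavik population median curves: parameter -> (ln c, k, s), shared start
# age t0, P(t) = c * u**(k + s*u) with u = t - t0 in gestational days. A
# single t0 keeps the implied EFW trajectory exactly of Rossavik form.
ROSSAVIK_T0_DAYS = 43.0
ROSSAVIK_CALIBRATION: dict[str, tuple[float, float, float]] = {
    "bpd_mm": (-0.558451, 0.988737, -2.21e-4),
    "hc_mm": (-0.382954, 1.266983, -5.34e-4),
    "ac_mm": (-0.014928, 1.109521, -1.24e-4),
    "fl_mm": (-4.186517, 1.753453, -8.48e-4),
    "thigh_circ_mm": (-0.564977, 1.002707, 4.0e-5),
    "tvol_cm3": (-20.6718947, 4.9685041, -1.6338242e-3),
}

#: Exponents of the synthetic EFW(BPD-AC-TVol) power law (BPD/AC in cm).
_EFW3D_EXPONENTS = {"BPD": 0.25, "AC": 0.806, "TVOL": 0.55}
_EFW3D_TERM_WEIGHT_G = 3480.0
#: Age at which the scale is anchored: the effective growth age where a fetus
#: delivering at term (280 d) realizes its birthweight — 38 weeks plus the
#: damped late-term gain (266 + 0.3 * 14 d). A median-curve fetus evaluated
#: there weighs the term median, keeping birthweights and the component
#: reference curves mutually consistent.
_EFW3D_ANCHOR_AGE_DAYS = 270.2


def median_curve(parameter_name: str, ga_days) -> np.ndarray:
    """Population median trajectory from the calibration constants."""
    lnc, k, s = ROSSAVIK_CALIBRATION[parameter_name]
    u = np.asarray(ga_days, float) - ROSSAVIK_T0_DAYS
    return np.exp(lnc + (k + s * u) * np.log(u))


def _efw3d_scale() -> float:
    age = _EFW3D_ANCHOR_AGE_DAYS
    bpd = float(median_curve("bpd_mm", age)) / 10.0
    ac = float(median_curve("ac_mm", age)) / 10.0
    tvol = float(median_curve("tvol_cm3", age))
    denom = (bpd ** _EFW3D_EXPONENTS["BPD"] * ac ** _EFW3D_EXPONENTS["AC"]
             * tvol ** _EFW3D_EXPONENTS["TVOL"])
    return _EFW3D_TERM_WEIGHT_G / denom


def efw_bpd_ac_tvol_synthetic() -> EfwCoefficients:
    """Usable synthetic-calibration EFW(BPD-AC-TVol) set (identity link)."""
    return EfwCoefficients(
        name="bpd_ac_tvol_synthetic",
        link="identity",
        terms=(EfwTerm(_efw3d_scale(), dict(_EFW3D_EXPONENTS)),),
    )


#: A deliberately unusable stand-in for published 3D EFW coefficients: it
#: raises at evaluation unless the caller opts in, so nobody mistakes the
#: synthetic set for a validated clinical formula.
EFW_BPD_AC_TVOL_PLACEHOLDER = EfwCoefficients(
    name="bpd_ac_tvol_placeholder",
    link="log10",
    terms=(EfwTerm(3.0),),
    placeholder=True,
)


def rossavik_k_defaults() -> dict[str, float]:
    """Fixed Rossavik base exponents per parameter, incl. the derived EFW one.

    The EFW curve implied by the synthetic power-law set is itself exactly of
    Rossavik form, with k and s the exponent-weighted sums of the component
    constants.
    """
    out = {name: vals[1] for name, vals in ROSSAVIK_CALIBRATION.items()}
    out["efw_g"] = (
        _EFW3D_EXPONENTS["BPD"] * ROSSAVIK_CALIBRATION["bpd_mm"][1]
        + _EFW3D_EXPONENTS["AC"] * ROSSAVIK_CALIBRATION["ac_mm"][1]
        + _EFW3D_EXPONENTS["TVOL"] * ROSSAVIK_CALIBRATION["tvol_cm3"][1]
    )
    return out


#: 95% percent-deviation reference ranges per parameter for mPGAS,
#: synthetic-calibration: 2.5th/97.5th percentiles of third-trimester percent
#: deviations in the generator's own normal-outcome cohort (seeded run,
#: frozen; see docs/methods.md).
MPGAS_REF_RANGES_SYNTHETIC: dict[str, tuple[float, float]] = {
    "hc_mm": (-6.5, 6.5),
    "ac_mm": (-8.0, 9.0),
    "fl_mm": (-7.5, 9.5),
    "thigh_circ_mm": (-9.5, 12.0),
    "efw_g": (-9.5, 10.5),
}


def default_iga_config() -> IgaConfig:
    return IgaConfig(
        k=rossavik_k_defaults(),
        t0_days=ROSSAVIK_T0_DAYS,
        ref_ranges=dict(MPGAS_REF_RANGES_SYNTHETIC),
        mpgas_threshold=MPGAS_THRESHOLD,
        gpri_range=GPRI_RANGE,
    )


# ---------------------------------------------------------------------------
# customized birthweight centiles (generic Gardosi-style model)

#: Fetal-weight proportionality: percent of term weight as a cubic in
#: gestational weeks up to 38 weeks, then an exponential extension at the
#: decelerated late-term growth rate (~0.24%/day — term growth flattens),
#: normalized to 1 at 40 weeks; represented as a spline over a weekly grid so
#: alternative curves can be swapped in from config.
_PROP_GRID_WEEKS = np.arange(24.0, 43.5, 0.5)
_LATE_TERM_LOG_RATE_PER_DAY = 0.00302


def _prop_percent(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, float)
    cubic = 299.1 - 31.85 * w + 1.094 * w ** 2 - 0.01055 * w ** 3
    at38 = 299.1 - 31.85 * 38 + 1.094 * 38 ** 2 - 0.01055 * 38 ** 3
    late = at38 * np.exp(_LATE_TERM_LOG_RATE_PER_DAY * 7.0 * (w - 38.0))
    return np.where(w <= 38.0, cubic, late)


@dataclass(frozen=True)
class CustomizationModel:
    """Term-optimal-weight model for customized birthweight centiles.

    TOW = baseline + height/weight/parity/ethnicity/sex adjustments at the
    reference covariates (height 164 cm, booking weight 66 kg, nulliparous,
    European). Expected weight at GA scales TOW by the proportionality curve;
    the centile is Phi((ln bw - ln expected) / sigma_log) * 100.
    """

    baseline_g: float = 3480.0
    height_g_per_cm: float = 8.5
    weight_g_per_kg: float = 7.0
    parous_g: float = 90.0
    sex_g: Mapping[str, float] = field(
        default_factory=lambda: {"male": 60.0, "female": -60.0}
    )
    ethnicity_g: Mapping[str, float] = field(
        default_factory=lambda: {
            "european": 0.0,
            "indian": -180.0,
            "pakistani": -160.0,
            "caribbean": -110.0,
            "chinese": -130.0,
            "mixed_other": -60.0,
            "mixed_asian_european": -90.0,
            "mixed_caribbean_european": -55.0,
        }
    )
    ref_height_cm: float = 164.0
    ref_weight_kg: float = 66.0
    sigma_log: float = 0.12
    prop_grid_weeks: tuple[float, ...] = tuple(_PROP_GRID_WEEKS)
    prop_values: tuple[float, ...] = tuple(
        _prop_percent(_PROP_GRID_WEEKS) / _prop_percent(np.array([40.0]))[0]
    )

    def proportionality(self, ga_days) -> np.ndarray:
        spline = CubicSpline(self.prop_grid_weeks, self.prop_values, bc_type="natural")
        w = np.asarray(ga_days, float) / 7.0
        lo, hi = self.prop_grid_weeks[0], self.prop_grid_weeks[-1]
        if np.any(w < lo) or np.any(w > hi):
            raise ConfigError(
                f"delivery GA {ga_days} d outside proportionality grid "
                f"[{lo * 7:.0f}, {hi * 7:.0f}] d"
            )
        return spline(w)

    def term_optimal_weight(self, height_cm: float, weight_kg: float,
                            parity: int, ethnicity: str, sex: str) -> float:
        try:
            eth = self.ethnicity_g[ethnicity]
        except KeyError:
            raise ConfigError(f"no ethnicity adjustment for {ethnicity!r}") from None
        try:
            sx = self.sex_g[sex]
        except KeyError:
            raise ConfigError(f"no sex adjustment for {sex!r}") from None
        return (
            self.baseline_g
            + self.height_g_per_cm * (height_cm - self.ref_height_cm)
            + self.weight_g_per_kg * (weight_kg - self.ref_weight_kg)
            + (self.parous_g if parity >= 1 else 0.0)
            + eth + sx
        )

    def expected_weight(self, ga_days, height_cm, weight_kg, parity,
                        ethnicity, sex) -> float:
        tow = self.term_optimal_weight(height_cm, weight_kg, parity, ethnicity, sex)
        return float(tow * self.proportionality(ga_days))


def default_customization_model() -> CustomizationModel:
    return CustomizationModel()


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; loadable from a YAML mapping."""

    out_dir: str = "report"
    scans_csv: str | None = None
    outcomes_csv: str | None = None
    seed: int = 17
    n_subjects: int = 115
    third_trimester_window: tuple[int, int] = (238, 259)  # half-open days
    sga_centile: float = 10.0
    fgr_centile: float = 3.0
    lga_centile: float = 90.0
    mpgas_threshold: float = MPGAS_THRESHOLD
    gpri_range: tuple[float, float] = GPRI_RANGE
    efw_2d: str = "hadlock"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("sga_centile", "fgr_centile", "lga_centile"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ConfigError(f"{name}={v} outside [0, 100]")
        if self.fgr_centile > self.sga_centile:
            raise ConfigError("FGR centile cutoff must not exceed the SGA cutoff")
        lo, hi = self.third_trimester_window
        if not (0 < lo < hi):
            raise ConfigError("third-trimester window must be increasing")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path!r} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for tup in ("third_trimester_window", "gpri_range"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["third_trimester_window"] = list(self.third_trimester_window)
        d["gpri_range"] = list(self.gpri_range)
        return d


def efw_set_by_name(name: str) -> EfwCoefficients:
    if name == "hadlock":
        return HADLOCK_BPD_AC_FL
    if name == "bpd_ac_tvol_synthetic":
        return efw_bpd_ac_tvol_synthetic()
    if name == "bpd_ac_tvol_placeholder":
        return EFW_BPD_AC_TVOL_PLACEHOLDER
    raise ConfigError(f"unknown EFW coefficient set {name!r}")
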