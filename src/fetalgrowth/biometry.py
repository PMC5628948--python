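"""Core measurement types, unit handling, and estimated-fetal-weight formulas.

Measurements are stored in canonical units — lengths in mm, volumes in cm³,
gestational age in exact days — and converted to each formula's native units
(Hadlock: cm) only at evaluation time. Mixing the two conventions silently is
the classic failure mode of clinical CSVs, hence the single canonical store.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import (
    ConfigError,
    IncompleteScanError,
    InvalidMeasurementError,
    UnitError,
)

__all__ = [
    "BiometryScan",
    "EfwCoefficients",
    "EfwTerm",
    "HADLOCK_BPD_AC_FL",
    "convert_units",
    "efw_hadlock",
    "efw_generic",
]

GA_MIN_DAYS = 84    # 12 weeks; records outside [GA_MIN, GA_MAX] are rejected at ingest
GA_MAX_DAYS = 301   # 43 weeks

_MEASUREMENT_FIELDS = ("bpd_mm", "hc_mm", "ac_mm", "fl_mm", "tvol_cm3", "thigh_circ_mm")


@dataclass(frozen=True)
class BiometryScan:
    """One ultrasound visit: 2D biometry plus optional fractional thigh volume.

    Lengths (BPD, HC, AC, FL, thigh circumference) are millimetres; fractional
    thigh volume (TVol) is cm³. TVol is defined on the middle 50% of the
    femoral diaphysis, so a scan carrying TVol must also carry FL.
    """

    subject_id: str
    ga_days: int
    bpd_mm: float | None = None
    hc_mm: float | None = None
    ac_mm: float | None = None
    fl_mm: float | None = None
    tvol_cm3: float | None = None
    thigh_circ_mm: float | None = None

    def __post_init__(self) -> None:
        if not (GA_MIN_DAYS <= self.ga_days <= GA_MAX_DAYS):
            raise InvalidMeasurementError(
                f"gestational age {self.ga_days} d outside ingest range "
                f"[{GA_MIN_DAYS}, {GA_MAX_DAYS}] for subject {self.subject_id!r}"
            )
        for name in _MEASUREMENT_FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v <= 0:
                raise InvalidMeasurementError(
                    f"{name}={v!r} must be finite and > 0 (subject {self.subject_id!r})"
                )
        if self.tvol_cm3 is not None and self.fl_mm is None:
            raise InvalidMeasurementError(
                f"scan with tvol_cm3 must also carry fl_mm (subject {self.subject_id!r})"
            )

    @property
    def ga_weeks(self) -> float:
        return self.ga_days / 7.0

    def get(self, measurement: str) -> float | None:
        return getattr(self, measurement)


# ---------------------------------------------------------------------------
# units

_LENGTH = {"mm": 1.0, "cm": 10.0}
_VOLUME = {"cm3": 1.0}
_MASS = {"g": 1.0, "kg": 1000.0}
_TIME = {"days": 1.0, "weeks": 7.0}
_DIMENSIONS = [_LENGTH, _VOLUME, _MASS, _TIME]


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact scale-factor conversion within one dimension.

    Supported units: mm, cm (length); cm3 (volume); g, kg (mass);
    days, weeks (time, 7 days/week). Cross-dimension pairs raise UnitError.
    """
    for table in _DIMENSIONS:
        if from_unit in table:
            if to_unit not in table:
                raise UnitError(f"cannot convert {from_unit!r} to {to_unit!r}")
            return value * table[from_unit] / table[to_unit]
    raise UnitError(f"unknown unit {from_unit!r}")


# ---------------------------------------------------------------------------
# estimated fetal weight

#: Measurement symbol -> (scan field, canonical->formula-unit scale factor)
_SYMBOLS = {
    "BPD": ("bpd_mm", 0.1),       # mm -> cm
    "AC": ("ac_mm", 0.1),
    "FL": ("fl_mm", 0.1),
    "TVOL": ("tvol_cm3", 1.0),    # already cm³
}


@dataclass(frozen=True)
class EfwTerm:
    """One additive term: ``coefficient * prod(symbol ** power)``.

    ``monomial`` maps measurement symbols (BPD, AC, FL, TVOL — evaluated in
    cm / cm³) to exponents; the empty mapping is an intercept.
    """

    coefficient: float
    monomial: Mapping[str, float] = field(default_factory=dict)

    def required(self) -> set[str]:
        return set(self.monomial)

    def evaluate(self, values: Mapping[str, float]) -> float:
        out = self.coefficient
        for sym, power in self.monomial.items():
            out *= values[sym] ** power
        return out


@dataclass(frozen=True)
class EfwCoefficients:
    """A named estimated-fetal-weight formula on the link scale.

    ``link`` is applied to the linear predictor: log10 / ln formulas return
    ``10**lp`` / ``exp(lp)`` grams, identity returns the predictor itself.
    A set flagged ``placeholder`` refuses to evaluate unless the caller
    explicitly enables it — shipping silently invented coefficients for a
    published formula would fabricate science.
    """

    name: str
    terms: Sequence[EfwTerm]
    link: str = "log10"
    placeholder: bool = False

    def __post_init__(self) -> None:
        if self.link not in ("log10", "ln", "identity"):
            raise ConfigError(f"unknown link {self.link!r} in EFW set {self.name!r}")
        for t in self.terms:
            if not math.isfinite(t.coefficient):
                raise ConfigError(f"non-finite coefficient in EFW set {self.name!r}")
            for sym in t.monomial:
                if sym not in _SYMBOLS:
                    raise ConfigError(f"unknown measurement {sym!r} in EFW set {self.name!r}")

    def required(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.required()
        return out


HADLOCK_BPD_AC_FL = EfwCoefficients(
    name="hadlock_bpd_ac_fl",
    link="log10",
    terms=(
        EfwTerm(1.335),
        EfwTerm(-0.0034, {"AC": 1, "FL": 1}),
        EfwTerm(0.0316, {"BPD": 1}),
        EfwTerm(0.0457, {"AC": 1}),
        EfwTerm(0.1623, {"FL": 1}),
    ),
)


def _check_positive(**inputs: float) -> None:
    for name, v in inputs.items():
        if not (isinstance(v, (int, float)) and math.isfinite(v)) or v <= 0:
            raise InvalidMeasurementError(f"{name}={v!r} must be finite and > 0")


def efw_hadlock(bpd_cm: float, ac_cm: float, fl_cm: float) -> float:
    """Hadlock estimated fetal weight in grams; inputs in centimetres.

    log10 EFW = 1.335 − 0.0034·AC·FL + 0.0316·BPD + 0.0457·AC + 0.1623·FL
    """
    _check_positive(bpd_cm=bpd_cm, ac_cm=ac_cm, fl_cm=fl_cm)
    log10_efw = (
        1.335
        - 0.0034 * ac_cm * fl_cm
        + 0.0316 * bpd_cm
        + 0.0457 * ac_cm
        + 0.1623 * fl_cm
    )
    return 10.0 ** log10_efw


def efw_generic(scan: BiometryScan, coeffs: EfwCoefficients, *,
                allow_placeholder: bool = False) -> float:
    """Evaluate an arbitrary EFW coefficient set on a scan, in grams."""
    if coeffs.placeholder and not allow_placeholder:
        raise ConfigError(
            f"EFW set {coeffs.name!r} is a placeholder; supply real coefficients "
            "or pass allow_placeholder=True to acknowledge it"
        )
    values: dict[str, float] = {}
    for sym in coeffs.required():
        field_name, scale = _SYMBOLS[sym]
        raw = scan.get(field_name)
        if raw is None:
            raise IncompleteScanError(
                f"EFW set {coeffs.name!r} needs {field_name} but scan at "
                f"{scan.ga_days} d (subject {scan.subject_id!r}) lacks it"
            )
        values[sym] = raw * scale
    lp = sum(t.evaluate(values) for t in coeffs.terms)
    if coeffs.link == "log10":
        w = 10.0 ** lp
    elif coeffs.link == "ln":
        w = math.exp(lp)
    else:
        w = lp
    if not math.isfinite(w) or w <= 0:
        raise InvalidMeasurementError(
            f"EFW set {coeffs.name!r} produced non-positive weight {w!r}"
        )
    return w


def scans_from_rows(rows: Iterable[Mapping[str, object]]) -> list[BiometryScan]:
    """Build scans from dict-like rows (CSV ingest helper)."""
    out = []
    for row in rows:
        kwargs = {}
        for name in _MEASUREMENT_FIELDS:
            v = row.get(name)
            kwargs[name] = None if v in (None, "") else float(v)  # type: ignore[arg-type]
        out.append(
            BiometryScan(
                subject_id=str(row["subject_id"]),
                ga_days=int(row["ga_days"]),  # type: ignore[arg-type]
                **kwargs,
            )
        )
    return out
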