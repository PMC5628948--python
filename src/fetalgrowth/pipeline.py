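"""End-to-end pipeline: simulate/ingest -> centiles -> IGA -> screening -> report.

The stages are plain functions over DataFrames so they compose in scripts and
notebooks; :func:`run_pipeline` wires them together, writes versioned outputs
under an output directory, and embeds provenance (config hash, seed, package
version) in the report bundle. Idempotent for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .biometry import efw_hadlock
from .cohort import CohortConfig, generate_cohort
from .config import (
    CustomizationModel,
    PipelineConfig,
    default_customization_model,
    default_iga_config,
    efw_bpd_ac_tvol_synthetic,
)
from .errors import DataError, EligibilityError, FetalGrowthError
from .iga import DeviationRecord, IgaConfig, fit_rossavik, summarize_subject
from .io import (
    read_cohort_csv,
    read_outcomes_csv,
    write_cohort_csv,
    write_outcomes_csv,
)
from .lms import model_from_centile_table, tvol_reference
from .screening import classify_outcome, customized_centile, screening_table

logger = logging.getLogger(__name__)

__all__ = ["ReportBundle", "run_pipeline", "build_analysis_frame", "iga_report"]

#: Parameters whose percent deviations feed the composite mPGAS.
MPGAS_PARAMETERS = ("hc_mm", "ac_mm", "fl_mm", "thigh_circ_mm", "efw_g")


def _efw3d_column(scans: pd.DataFrame) -> pd.Series:
    """EFW(BPD-AC-TVol) per scan row (NaN where inputs are missing)."""
    coeffs = efw_bpd_ac_tvol_synthetic()
    scale = coeffs.terms[0].coefficient
    expo = coeffs.terms[0].monomial
    return (scale
            * (scans["bpd_mm"] / 10.0) ** expo["BPD"]
            * (scans["ac_mm"] / 10.0) ** expo["AC"]
            * scans["tvol_cm3"] ** expo["TVOL"])


def _efw_hadlock_column(scans: pd.DataFrame) -> pd.Series:
    out = np.full(len(scans), np.nan)
    ok = scans[["bpd_mm", "ac_mm", "fl_mm"]].notna().all(axis=1)
    sub = scans[ok]
    out[ok.to_numpy()] = [
        efw_hadlock(b / 10.0, a / 10.0, f / 10.0)
        for b, a, f in zip(sub["bpd_mm"], sub["ac_mm"], sub["fl_mm"])
    ]
    return pd.Series(out, index=scans.index)


def add_outcome_classes(outcomes: pd.DataFrame,
                        customization: CustomizationModel | None = None) -> pd.DataFrame:
    """Append customized centile and SGA/FGR/LGA/AGA class columns."""
    cust = customization or default_customization_model()
    cents = [
        customized_centile(r.birthweight_g, r.ga_delivery_days,
                           r.maternal_height_cm, r.maternal_weight_kg,
                           int(r.parity), r.ethnicity, r.sex, model=cust)
        for r in outcomes.itertuples()
    ]
    out = outcomes.copy()
    out["customized_centile"] = cents
    out["outcome_class"] = [classify_outcome(c) for c in cents]
    out["is_sga"] = (out["customized_centile"] < 10.0).astype(int)
    out["is_fgr"] = (out["customized_centile"] < 3.0).astype(int)
    return out


def build_analysis_frame(
    scans: pd.DataFrame,
    outcomes: pd.DataFrame,
    window: tuple[int, int] = (238, 259),
    customization: CustomizationModel | None = None,
) -> pd.DataFrame:
    """One row per subject with a scan in the third-trimester window.

    Carries the continuous predictors (AC, TVol, both EFWs, TVol reference
    centile), scan age, and outcome columns. Subjects without a window scan
    are skipped with a logged warning (attrition accounting).
    """
    lo, hi = window
    tvol_model = model_from_centile_table(tvol_reference())
    scans = scans.copy()
    scans["efw_hadlock_g"] = _efw_hadlock_column(scans)
    scans["efw_g"] = _efw3d_column(scans)
    out = add_outcome_classes(outcomes, customization)
    rows = []
    for sid, grp in scans.groupby("subject_id", sort=True):
        win = grp[(grp.ga_days >= lo) & (grp.ga_days < hi)].sort_values("ga_days")
        if win.empty:
            logger.warning("subject %s has no scan in window [%d, %d) — skipped",
                           sid, lo, hi)
            continue
        r = win.iloc[0]
        try:
            tvol_cent = (np.nan if pd.isna(r.tvol_cm3) else
                         tvol_model.centile_of(r.tvol_cm3, r.ga_days))
        except FetalGrowthError:
            tvol_cent = np.nan
        rows.append({
            "subject_id": sid,
            "ga_at_scan_days": int(r.ga_days),
            "ac_mm": r.ac_mm,
            "tvol_cm3": r.tvol_cm3,
            "tvol_centile": tvol_cent,
            "efw_hadlock_g": r.efw_hadlock_g,
            "efw_g": r.efw_g,
        })
    frame = pd.DataFrame(rows)
    return frame.merge(out, on="subject_id", how="inner")


def iga_report(
    scans: pd.DataFrame,
    outcomes: pd.DataFrame,
    iga_config: IgaConfig | None = None,
    window: tuple[int, int] = (238, 259),
) -> pd.DataFrame:
    """Per-subject individualized growth assessment.

    Fits Rossavik curves per mPGAS parameter from the second-trimester scans,
    projects them onto every third-trimester visit in the window, and derives
    mPGAS (negative version), predicted birthweight, and GPRI_WT. Subjects
    whose scans violate the eligibility rules are skipped with a warning.
    """
    cfg = iga_config or default_iga_config()
    scans = scans.copy()
    scans["efw_g"] = _efw3d_column(scans)
    out_by_id = outcomes.set_index("subject_id")
    rows = []
    for sid, grp in scans.groupby("subject_id", sort=True):
        grp = grp.sort_values("ga_days")
        second = grp[grp.ga_days < 196]
        third = grp[(grp.ga_days >= window[0]) & (grp.ga_days < window[1])]
        if len(second) < 2 or third.empty:
            logger.warning("subject %s lacks the scans required for IGA — skipped", sid)
            continue
        devs: list[DeviationRecord] = []
        fits = {}
        try:
            for p in MPGAS_PARAMETERS:
                pts = second[["ga_days", p]].dropna().to_numpy(float)
                fit = fit_rossavik(pts, p, cfg)
                fits[p] = fit
                for r in third.itertuples():
                    obs = getattr(r, p)
                    if not pd.isna(obs):
                        devs.append(DeviationRecord(p, r.ga_days, float(obs),
                                                    float(fit.predict(r.ga_days))))
        except (EligibilityError, DataError) as exc:
            logger.warning("subject %s ineligible for IGA: %s — skipped", sid, exc)
            continue
        bw = ga_del = None
        if sid in out_by_id.index:
            bw = float(out_by_id.loc[sid, "birthweight_g"])
            ga_del = float(out_by_id.loc[sid, "ga_delivery_days"])
        summ = summarize_subject(sid, devs, fits.get("efw_g"), bw, ga_del, cfg)
        row = {
            "subject_id": sid,
            "mpgas_neg": summ.mpgas_neg,
            "mpgas_abnormal": summ.mpgas_abnormal,
            "gpri_wt": summ.gpri_wt,
            "gpri_abnormal": summ.gpri_abnormal,
            "iga_abnormal": summ.any_abnormal,
            "predicted_bw_g": summ.predicted_bw_g,
            "predicted_ga_used_days": summ.predicted_ga_used_days,
        }
        for p, fit in fits.items():
            row[f"c_{p}"] = fit.c
            row[f"k_{p}"] = fit.k
            row[f"s_{p}"] = fit.s
        for d in devs:
            row[f"dev_{d.parameter_name}_{int(d.ga_days)}"] = d.percent_deviation
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    scans: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame | None
    analysis: pd.DataFrame
    iga: pd.DataFrame
    screening: pd.DataFrame
    provenance: dict


def _config_hash(cfg: PipelineConfig) -> str:
    text = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | None = None) -> ReportBundle:
    """Run all stages and, if ``config.out_dir`` is set, write the bundle."""
    cfg = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    # stage 1: simulate or ingest
    truth = None
    if cfg.scans_csv and cfg.outcomes_csv:
        logger.info("stage ingest: reading %s, %s", cfg.scans_csv, cfg.outcomes_csv)
        scans = read_cohort_csv(cfg.scans_csv)
        outcomes = read_outcomes_csv(cfg.outcomes_csv)
    else:
        logger.info("stage simulate: n=%d seed=%d", cfg.n_subjects, cfg.seed)
        scans, outcomes, truth = generate_cohort(
            CohortConfig(n_subjects=cfg.n_subjects, seed=cfg.seed))

    # stage 2: reference centiles
    logger.info("stage centiles: back-solving the shipped reference table")
    tvol_model = model_from_centile_table(tvol_reference())

    # stage 3: individualized growth assessment
    logger.info("stage iga")
    iga = iga_report(scans, outcomes, window=cfg.third_trimester_window)

    # stage 4: screening evaluation
    logger.info("stage screen")
    analysis = build_analysis_frame(scans, outcomes, window=cfg.third_trimester_window)
    screening = screening_table(
        analysis,
        predictors={
            "EFW (Hadlock)": "efw_hadlock_g",
            "EFW (BPD-AC-TVol)": "efw_g",
            "AC": "ac_mm",
            "TVol": "tvol_cm3",
            "TVol centile": "tvol_centile",
        },
    )

    provenance = {
        "package": "fetalgrowth",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "config": cfg.to_dict(),
        "n_subjects_analysed": int(len(analysis)),
    }
    bundle = ReportBundle(scans=scans, outcomes=outcomes, truth=truth,
                          analysis=analysis, iga=iga, screening=screening,
                          provenance=provenance)

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        write_cohort_csv(os.path.join(cfg.out_dir, "scans.csv"), scans)
        write_outcomes_csv(os.path.join(cfg.out_dir, "outcomes.csv"), outcomes)
        if truth is not None:
            truth.to_csv(os.path.join(cfg.out_dir, "truth.csv"), index=False)
        analysis.to_csv(os.path.join(cfg.out_dir, "analysis.csv"), index=False)
        iga.to_csv(os.path.join(cfg.out_dir, "iga_report.csv"), index=False)
        screening.to_csv(os.path.join(cfg.out_dir, "screening_report.csv"), index=False)
        with open(os.path.join(cfg.out_dir, "tvol_reference_model.json"), "w") as fh:
            fh.write(tvol_model.to_json())
        with open(os.path.join(cfg.out_dir, "provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=2)
        logger.info("report bundle written to %s", cfg.out_dir)
    return bundle
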