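"""Synthetic-trial generator for a Total-XV-like HDMTX protocol.

Builds virtual paediatric ALL cohorts, applies the protocol dosing rules
(window-phase MTX, consolidation courses individualised to a target
steady-state concentration, folinate rescue), simulates sparse PK/PD
samples with residual error, and emits a NONMEM-style rectangular dataset.

Occasions are numbered 1 (window administration) to 5 (fourth
consolidation course); HCY is sampled only in the first two consolidation
courses (occasions 2 and 3) at pre-dose, 23 h and 42 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import dataset as ds
from .pd import hcy_trajectory_grid
from .pk import MTX_MOLAR_MASS, DoseEvent, Drug, mtx_concentration
from .population import (
    PDParameters,
    PKParameters,
    RiskGroup,
    Sex,
    Subject,
    adjusted_creatinine,
    apply_residual_error,
    individual_pd_params,
    individual_pk_params,
    sample_random_effects,
)

__all__ = [
    "CovariateConfig",
    "TrialDesign",
    "CourseSchedule",
    "sample_population",
    "consolidation_dose",
    "folinate_schedule",
    "window_dose_events",
    "generate_trial",
    "TARGET_CPSS",
]

#: protocol target steady-state MTX concentrations, µM
TARGET_CPSS = {RiskGroup.LR: 33.0, RiskGroup.SHR: 65.0}

#: folinate unit doses, mg/m², by risk group (consolidation)
FOLINATE_CONS_DOSE = {RiskGroup.LR: 10.0, RiskGroup.SHR: 15.0}


# --------------------------------------------------------------------------
# virtual population
# --------------------------------------------------------------------------

# median growth references by age (years): plumbing defaults; only the
# resulting marginal medians/ranges are constrained by the study demography
_GROWTH_AGES = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 19.0])
_HEIGHT_CM = np.array([76.0, 88.0, 104.0, 117.0, 129.0, 139.0, 150.0, 161.0, 168.0, 172.0])
_WEIGHT_KG = np.array([10.5, 13.0, 17.0, 22.0, 28.0, 34.0, 43.0, 52.0, 60.0, 66.0])
_HEIGHT_SEX_FACTOR = {Sex.MALE: 1.01, Sex.FEMALE: 0.99}  # applied above 13 y


@dataclass(frozen=True)
class CovariateConfig:
    """Distributional choices for the virtual cohort."""

    age_median: float = 5.42
    age_log_sd: float = 0.55
    age_range: tuple[float, float] = (1.03, 18.85)
    p_male: float = 0.55
    p_low_risk: float = 0.53
    height_log_sd: float = 0.035
    weight_log_sd: float = 0.12
    scr_log_sd: float = 0.20
    scr_range: tuple[float, float] = (0.1, 1.2)

    def __post_init__(self) -> None:
        for p in (self.p_male, self.p_low_risk):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("invalid age range")


def mosteller_bsa(height_cm: np.ndarray, weight_kg: np.ndarray) -> np.ndarray:
    """Body surface area (m²) by the Mosteller formula."""
    return np.sqrt(np.asarray(height_cm) * np.asarray(weight_kg) / 3600.0)


def sample_population(
    n: int,
    rng: np.random.Generator | int,
    config: CovariateConfig | None = None,
) -> list[Subject]:
    """Draw ``n`` virtual patients with Total-XV-like covariate marginals.

    Ages are log-normal (right-skewed) truncated to the study range with
    median near 5.4 y; height and weight follow median growth curves with
    log-normal noise; BSA is Mosteller; serum creatinine scatters around
    the age/sex reference value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or CovariateConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    lo, hi = cfg.age_range
    ages = np.empty(n)
    filled = 0
    while filled < n:
        draw = np.exp(rng.normal(np.log(cfg.age_median), cfg.age_log_sd, size=2 * (n - filled)))
        draw = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        ages[filled : filled + len(draw)] = draw
        filled += len(draw)

    sexes = np.where(rng.random(n) < cfg.p_male, Sex.MALE.value, Sex.FEMALE.value)
    risks = np.where(rng.random(n) < cfg.p_low_risk, RiskGroup.LR.value, RiskGroup.SHR.value)

    h_med = np.interp(ages, _GROWTH_AGES, _HEIGHT_CM)
    h_med *= np.where(
        ages >= 13.0, [_HEIGHT_SEX_FACTOR[Sex(s)] for s in sexes], 1.0
    )
    heights = h_med * np.exp(rng.normal(0.0, cfg.height_log_sd, n))
    w_med = np.interp(ages, _GROWTH_AGES, _WEIGHT_KG)
    weights = w_med * np.exp(rng.normal(0.0, cfg.weight_log_sd, n))
    bsa = mosteller_bsa(heights, weights)

    scr_ref = np.array([adjusted_creatinine(a, Sex(s)) for a, s in zip(ages, sexes)])
    scr = scr_ref * np.exp(rng.normal(0.0, cfg.scr_log_sd, n))
    scr = np.clip(scr, *cfg.scr_range)

    return [
        Subject(
            id=i + 1, age=float(ages[i]), sex=Sex(sexes[i]), bsa=float(bsa[i]),
            weight=float(weights[i]), height=float(heights[i]), scr=float(scr[i]),
            risk=RiskGroup(risks[i]),
        )
        for i in range(n)
    ]


# --------------------------------------------------------------------------
# protocol dosing
# --------------------------------------------------------------------------

def consolidation_dose(target_cpss: float, cl_estimate: float) -> list[DoseEvent]:
    """Individualised consolidation HDMTX events for a target Cpss.

    Total dose (mg) over 24 h is ``Cpss * CL * 24`` converted from µmol to
    mg; 10% runs over the first hour as a loading infusion and the
    remaining 90% over the following 23 h.
    """
    if target_cpss < 0 or cl_estimate <= 0:
        raise ValueError("target and clearance estimate must be positive")
    total_mg = target_cpss * 1e-6 * MTX_MOLAR_MASS * cl_estimate * 1e3 * 24.0
    if total_mg == 0.0:
        return []
    return [
        DoseEvent(Drug.MTX, 0.1 * total_mg, start=0.0, duration=1.0),
        DoseEvent(Drug.MTX, 0.9 * total_mg, start=1.0, duration=23.0),
    ]


def window_dose_events(arm: str, bsa: float) -> list[DoseEvent]:
    """Window-phase MTX events: 4-h 1 g/m² or 200 mg/m² bolus + 800 mg/m²/24 h."""
    if arm == "short":
        return [DoseEvent(Drug.MTX, 1000.0 * bsa, start=0.0, duration=4.0)]
    if arm == "long":
        return [
            DoseEvent(Drug.MTX, 200.0 * bsa, start=0.0, duration=0.0),
            DoseEvent(Drug.MTX, 800.0 * bsa, start=0.0, duration=24.0),
        ]
    raise ValueError(f"unknown window arm {arm!r}")


def folinate_schedule(
    phase: str,
    bsa: float = 1.0,
    risk: RiskGroup = RiskGroup.LR,
) -> tuple[list[DoseEvent], tuple[float, float] | None]:
    """Folinate rescue events and the rescue window they define.

    Window phase: 50 mg/m² at 44 h then 7 doses of 15 mg/m² every 6 h
    (last at 86 h).  Consolidation: 5 doses every 6 h from 42 h (10 mg/m²
    LR, 15 mg/m² SHR).  The rescue window closes one dosing interval (6 h)
    after the last dose.  Dose amounts are bookkeeping only — folinate has
    no modelled kinetics; the window is what drives the turnover switch.
    """
    if phase in ("window-short", "window-long", "window"):
        times = 44.0 + 6.0 * np.arange(8)
        amounts = [50.0 * bsa] + [15.0 * bsa] * 7
    elif phase == "consolidation":
        times = 42.0 + 6.0 * np.arange(5)
        amounts = [FOLINATE_CONS_DOSE[RiskGroup(risk)] * bsa] * 5
    elif phase in (None, "none", ""):
        return [], None
    else:
        raise ValueError(f"unknown phase {phase!r}")
    events = [DoseEvent(Drug.FOLINATE, a, start=float(t)) for a, t in zip(amounts, times)]
    window = (float(times[0]), float(times[-1]) + 6.0)
    return events, window


@dataclass(frozen=True)
class CourseSchedule:
    """One treatment course: occasion index, dosing and sampling plan."""

    occasion: int  # 1-based; 1 = window
    phase: str  # window-short | window-long | consolidation
    dose_events: list[DoseEvent]
    pk_sample_times: tuple[float, ...]
    pd_sample_times: tuple[float, ...] = ()
    folinate_events: list[DoseEvent] = field(default_factory=list)
    rescue_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for t in (*self.pk_sample_times, *self.pd_sample_times):
            if not 0.0 <= t <= 168.0:
                raise ValueError(f"sample time {t} outside [0, 168] h")


@dataclass(frozen=True)
class TrialDesign:
    """Design knobs of the synthetic trial; defaults follow the protocol."""

    n_consolidation: int = 4
    window_pk_times: tuple[float, ...] = (4.0, 24.0, 42.0)
    cons_pk_times: tuple[float, ...] = (6.0, 23.0, 42.0)
    hcy_times: tuple[float, ...] = (0.0, 23.0, 42.0)
    hcy_occasions: tuple[int, ...] = (2, 3)  # first two consolidation courses
    p_long_infusion: float = 0.5
    include_folinate_rows: bool = True
    hcy_grid_step: float = 0.1


def build_courses(subject: Subject, arm: str, cl_estimates: Sequence[float], design: TrialDesign) -> list[CourseSchedule]:
    """Protocol course schedules for one subject.

    ``cl_estimates`` supplies the clearance (L/h) used to individualise
    each consolidation course, one value per consolidation occasion.
    """
    phase = f"window-{arm}"
    fol, window = folinate_schedule("window", subject.bsa, subject.risk)
    courses = [
        CourseSchedule(
            occasion=1, phase=phase,
            dose_events=window_dose_events(arm, subject.bsa),
            pk_sample_times=design.window_pk_times,
            folinate_events=fol, rescue_window=window,
        )
    ]
    target = TARGET_CPSS[subject.risk]
    for k in range(design.n_consolidation):
        occ = 2 + k
        fol, window = folinate_schedule("consolidation", subject.bsa, subject.risk)
        courses.append(
            CourseSchedule(
                occasion=occ, phase="consolidation",
                dose_events=consolidation_dose(target, cl_estimates[k]),
                pk_sample_times=design.cons_pk_times,
                pd_sample_times=design.hcy_times if occ in design.hcy_occasions else (),
                folinate_events=fol, rescue_window=window,
            )
        )
    return courses


# --------------------------------------------------------------------------
# trial simulation
# --------------------------------------------------------------------------

def _subject_row_base(s: Subject) -> dict:
    return {
        "ID": s.id, "AGE": s.age, "SEX": s.sex.value, "BSA": s.bsa,
        "WT": s.weight, "HT": s.height, "SCR": s.scr, "RISK": s.risk.value,
    }


def generate_trial(
    population: Sequence[Subject],
    pk_params: PKParameters,
    pd_params: PDParameters,
    rng: np.random.Generator | int,
    design: TrialDesign | None = None,
) -> pd.DataFrame:
    """Simulate the full trial for a cohort and return the dataset frame.

    Each subject receives a randomised window course followed by
    consolidation courses individualised using the clearance realised on
    the previous occasion (the protocol's "CL from previous MTX
    administrations", taken without estimation error).  Observations carry
    the residual-error model of the respective analyte.
    """
    design = design or TrialDesign()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_occ = 1 + design.n_consolidation
    res = sample_random_effects(pk_params, pd_params, len(population), n_occ, rng)
    arms = np.where(rng.random(len(population)) < design.p_long_infusion, "long", "short")

    rows: list[dict] = []
    hcy_jobs = []  # (row_indices, bl, kout, emax, ec50, mtx_grid)
    t_grid = np.arange(0.0, 42.0 + 1e-9, design.hcy_grid_step)

    for subj, re, arm in zip(population, res, arms):
        base = _subject_row_base(subj)
        # realised clearances per occasion (0-based)
        cls = [individual_pk_params(pk_params, subj, re, occ).CL for occ in range(n_occ)]
        # consolidation course k (occasion 2+k) individualised on the
        # clearance realised on the previous occasion
        cl_est = [cls[k] for k in range(design.n_consolidation)]
        courses = build_courses(subj, arm, cl_est, design)
        for course in courses:
            occ0 = course.occasion - 1
            ipk = individual_pk_params(pk_params, subj, re, occ0)
            for ev in course.dose_events:
                rows.append({
                    **base, "OCC": course.occasion, "TIME": ev.start, "AMT": ev.amount,
                    "RATE": ev.amount / ev.duration if ev.duration > 0 else 0.0,
                    "CMT": ds.CMT_MTX, "EVID": 1, "MDV": 1, "DV": np.nan, "DVID": "MTX",
                })
            if design.include_folinate_rows:
                for ev in course.folinate_events:
                    rows.append({
                        **base, "OCC": course.occasion, "TIME": ev.start, "AMT": ev.amount,
                        "RATE": 0.0, "CMT": ds.CMT_FOLINATE, "EVID": 1, "MDV": 1,
                        "DV": np.nan, "DVID": "FOL",
                    })
            pk_times = np.asarray(course.pk_sample_times, dtype=float)
            pred = mtx_concentration(ipk, course.dose_events, pk_times)
            eps = rng.normal(0.0, pk_params.sigma_exp, len(pk_times)) if pk_params.sigma_exp > 0 else np.zeros(len(pk_times))
            dv = apply_residual_error(pred, "MTX", eps)
            for t, v in zip(pk_times, dv):
                rows.append({
                    **base, "OCC": course.occasion, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                    "CMT": ds.CMT_MTX, "EVID": 0, "MDV": 0, "DV": v, "DVID": "MTX",
                })
            if course.pd_sample_times:
                ipd = individual_pd_params(pd_params, subj, re, occ0)
                mtx_grid = mtx_concentration(ipk, course.dose_events, t_grid)
                idx = []
                for t in course.pd_sample_times:
                    rows.append({
                        **base, "OCC": course.occasion, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                        "CMT": ds.CMT_HCY, "EVID": 0, "MDV": 0, "DV": np.nan, "DVID": "HCY",
                    })
                    idx.append(len(rows) - 1)
                hcy_jobs.append((idx, ipd.BL, ipd.kout, ipd.Emax, ipd.EC50, mtx_grid))

    if hcy_jobs:
        mtx = np.stack([j[5] for j in hcy_jobs])
        traj = hcy_trajectory_grid(
            np.array([j[1] for j in hcy_jobs]), np.array([j[2] for j in hcy_jobs]),
            np.array([j[3] for j in hcy_jobs]), np.array([j[4] for j in hcy_jobs]),
            mtx, t_grid,
        )
        for (idx, *_), y in zip(hcy_jobs, traj):
            times = [rows[i]["TIME"] for i in idx]
            gi = np.searchsorted(t_grid, np.asarray(times) - 1e-9)
            pred = y[gi]
            n = len(idx)
            e1 = rng.normal(0.0, pd_params.sigma_exp, n) if pd_params.sigma_exp > 0 else np.zeros(n)
            e2 = rng.normal(0.0, pd_params.sigma_add, n) if pd_params.sigma_add > 0 else np.zeros(n)
            dv = apply_residual_error(pred, "HCY", e1, e2)
            for i, v in zip(idx, dv):
                rows[i]["DV"] = float(v)

    df = pd.DataFrame(rows)[ds.COLUMNS]
    return ds.validate_dataset(df)
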