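"""Population layer: covariate models, random effects and residual error.

Maps population parameters (fixed effects, IIV/IOV variances, residual
SDs) plus subject covariates and random-effect draws to the individual
PK/PD parameters consumed by :mod:`mtxhcy.pk` and :mod:`mtxhcy.pd`.

All PK structural parameters scale linearly with body surface area (BSA);
clearance additionally carries a renal-function covariate, a power model on
serum creatinine normalised by an age/sex reference value.  The typical HCY
baseline increases linearly with age, centred at the study median age so
that ``theta_bl`` is the typical value for the median patient.
Interindividual (IIV) and interoccasion (IOV) variability act as
log-normal multiplicative factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from enum import Enum

import numpy as np

from .pd import IndividualPDParams
from .pk import IndividualPKParams

__all__ = [
    "AGE_REF",
    "Sex",
    "RiskGroup",
    "Subject",
    "PKParameters",
    "PDParameters",
    "RandomEffects",
    "adjusted_creatinine",
    "individual_pk_params",
    "individual_pd_params",
    "apply_residual_error",
    "sample_random_effects",
    "cv_to_omega2",
    "omega2_to_cv",
    "N_OCCASIONS",
]

logger = logging.getLogger(__name__)

#: study median age (years); centring point of the baseline-HCY age model
AGE_REF = 5.42

#: window administration (occasion 0) + four consolidation courses
N_OCCASIONS = 5


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"


class RiskGroup(str, Enum):
    LR = "LR"  # low risk, target Cpss 33 µM
    SHR = "SHR"  # standard/high risk, target Cpss 65 µM


@dataclass(frozen=True)
class Subject:
    """Covariates of one virtual or observed patient."""

    id: int
    age: float  # years
    sex: Sex
    bsa: float  # m²
    weight: float  # kg
    height: float  # cm
    scr: float  # serum creatinine, mg/dL
    risk: RiskGroup

    def __post_init__(self) -> None:
        if not 1.0 <= self.age <= 19.0:
            raise ValueError(f"age {self.age} outside the supported paediatric range [1, 19]")
        if self.bsa <= 0:
            raise ValueError("BSA must be > 0")
        if self.scr <= 0:
            raise ValueError("serum creatinine must be > 0")


def cv_to_omega2(cv_percent: float) -> float:
    """Log-scale variance of a log-normal factor with the given %CV."""
    return float(np.log1p((cv_percent / 100.0) ** 2))


def omega2_to_cv(omega2: float) -> float:
    """%CV of a log-normal factor with log-scale variance ``omega2``."""
    return float(100.0 * np.sqrt(np.expm1(omega2)))


@dataclass(frozen=True)
class PKParameters:
    """Population PK parameters; defaults are the reference adult-free,
    BSA-normalised estimates shipped with the package."""

    theta_cl: float = 6.68  # L/h/m²
    theta_v1: float = 18.6  # L/m²
    theta_q: float = 0.161  # L/h/m²
    theta_v2: float = 3.09  # L/m²
    theta_cr: float = 0.314  # creatinine power exponent (dimensionless)
    omega2_cl: float = field(default_factory=lambda: cv_to_omega2(14.53))
    omega2_v1: float = field(default_factory=lambda: cv_to_omega2(18.03))
    omega2_q: float = field(default_factory=lambda: cv_to_omega2(36.61))
    iov2_cl: float = field(default_factory=lambda: cv_to_omega2(17.15))
    sigma_exp: float = 0.235  # exponential residual SD (log scale)

    def __post_init__(self) -> None:
        _validate_positive(self, ("theta_cl", "theta_v1", "theta_q", "theta_v2"))
        _validate_nonnegative(self, ("omega2_cl", "omega2_v1", "omega2_q", "iov2_cl", "sigma_exp"))


@dataclass(frozen=True)
class PDParameters:
    """Population HCY turnover parameters (reference defaults)."""

    theta_bl: float = 4.88  # µM at the reference age
    theta_kout: float = 0.027  # 1/h
    theta_emax: float = 1.0  # fixed at 1 unless explicitly unfixed
    theta_ec50: float = 0.648  # µM
    theta_bl_age: float = 0.116  # µM/year
    omega2_bl: float = field(default_factory=lambda: cv_to_omega2(18.95))
    omega2_kout: float = field(default_factory=lambda: cv_to_omega2(33.23))
    omega2_ec50: float = field(default_factory=lambda: cv_to_omega2(53.63))
    iov2_bl: float = field(default_factory=lambda: cv_to_omega2(23.83))
    sigma_exp: float = 0.165  # exponential residual SD (log scale)
    sigma_add: float = 0.911  # additive residual SD, µM

    def __post_init__(self) -> None:
        _validate_positive(self, ("theta_bl", "theta_kout", "theta_ec50"))
        _validate_nonnegative(
            self, ("omega2_bl", "omega2_kout", "omega2_ec50", "iov2_bl", "sigma_exp", "sigma_add")
        )
        if not 0.0 <= self.theta_emax <= 1.0:
            raise ValueError(f"theta_emax must lie in [0, 1], got {self.theta_emax}")


def _validate_positive(obj, names) -> None:
    for n in names:
        if getattr(obj, n) <= 0:
            raise ValueError(f"{n} must be > 0, got {getattr(obj, n)}")


def _validate_nonnegative(obj, names) -> None:
    for n in names:
        if getattr(obj, n) < 0:
            raise ValueError(f"{n} must be >= 0, got {getattr(obj, n)}")


def params_to_dict(p: PKParameters | PDParameters) -> dict[str, float]:
    return {f.name: float(getattr(p, f.name)) for f in fields(p)}


def params_from_dict(cls, d: dict[str, float]):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{k: float(v) for k, v in d.items()})


# --------------------------------------------------------------------------
# age/sex-adjusted reference creatinine
#
# Piecewise-constant reference serum creatinine by age band, sex-specific
# above 13 years.  This is a plumbing default reflecting the well-known
# maturation of creatinine with muscle mass; it is configurable and its
# absolute level only anchors the creatinine covariate ratio.
# --------------------------------------------------------------------------

#: (age upper bound, value) bands shared by both sexes below the split age
_CCR_BANDS_CHILD: tuple[tuple[float, float], ...] = (
    (2.0, 0.30),
    (5.0, 0.35),
    (8.0, 0.43),
    (10.0, 0.47),
    (13.0, 0.53),
)
#: bands at or above the sex-split age of 13 years
_CCR_BANDS_TEEN = {
    Sex.MALE: ((15.0, 0.65), (np.inf, 0.78)),
    Sex.FEMALE: ((15.0, 0.58), (np.inf, 0.66)),
}
CCR_SEX_SPLIT_AGE = 13.0

DEFAULT_CCR_TABLE = {
    "child_bands": _CCR_BANDS_CHILD,
    "teen_bands": _CCR_BANDS_TEEN,
    "split_age": CCR_SEX_SPLIT_AGE,
    "age_range": (1.0, 19.0),
}


def adjusted_creatinine(age: float, sex: Sex, table: dict | None = None) -> float:
    """Age/sex reference serum creatinine C_CR,adj (mg/dL).

    Looks up a piecewise-constant table by age band; bands are shared by
    both sexes below the split age (default 13 y).  Ages outside the table
    range are clamped to the nearest band with a logged warning.
    """
    table = DEFAULT_CCR_TABLE if table is None else table
    lo, hi = table["age_range"]
    if not lo <= age <= hi:
        logger.warning("age %.2f outside reference creatinine table %s; clamping", age, (lo, hi))
        age = min(max(age, lo), hi)
    sex = Sex(sex)
    if age < table["split_age"]:
        bands = table["child_bands"]
    else:
        bands = table["teen_bands"][sex]
    for upper, value in bands:
        if age < upper:
            return value
    return bands[-1][1]


@dataclass(frozen=True)
class RandomEffects:
    """Per-subject random effects on the log scale.

    ``eta`` maps parameter name to the subject-level (IIV) deviation;
    ``kappa`` maps parameter name to a per-occasion (IOV) vector.
    """

    eta: dict[str, float]
    kappa: dict[str, np.ndarray]

    @classmethod
    def zero(cls, iiv_names=("CL", "V1", "Q"), iov_names=("CL",), n_occasions: int = N_OCCASIONS):
        return cls(
            eta={n: 0.0 for n in iiv_names},
            kappa={n: np.zeros(n_occasions) for n in iov_names},
        )

    def kappa_at(self, name: str, occasion: int) -> float:
        vec = self.kappa.get(name)
        if vec is None:
            return 0.0
        return float(vec[occasion])


def individual_pk_params(
    pop: PKParameters, subj: Subject, re: RandomEffects, occasion: int
) -> IndividualPKParams:
    """Individual two-compartment parameters for one occasion.

    CL carries BSA scaling, the creatinine power covariate and both IIV and
    IOV; V1 and Q carry BSA and IIV; V2 scales with BSA only.
    """
    ccr_adj = adjusted_creatinine(subj.age, subj.sex)
    cov_cl = (subj.scr / ccr_adj) ** (-pop.theta_cr)
    cl = pop.theta_cl * subj.bsa * cov_cl * np.exp(re.eta.get("CL", 0.0) + re.kappa_at("CL", occasion))
    v1 = pop.theta_v1 * subj.bsa * np.exp(re.eta.get("V1", 0.0))
    q = pop.theta_q * subj.bsa * np.exp(re.eta.get("Q", 0.0))
    v2 = pop.theta_v2 * subj.bsa
    return IndividualPKParams(CL=cl, V1=v1, Q=q, V2=v2)


def individual_pd_params(
    pop: PDParameters, subj: Subject, re: RandomEffects, occasion: int
) -> IndividualPDParams:
    """Individual turnover parameters for one occasion.

    The typical baseline is ``theta_bl + theta_bl_age*(age - AGE_REF)``;
    IIV and IOV multiply it log-normally.
    """
    bl_typ = pop.theta_bl + pop.theta_bl_age * (subj.age - AGE_REF)
    if bl_typ <= 0:
        raise ValueError(
            f"typical baseline {bl_typ:.3f} µM <= 0 at age {subj.age}: model misconfigured"
        )
    bl = bl_typ * np.exp(re.eta.get("BL", 0.0) + re.kappa_at("BL", occasion))
    kout = pop.theta_kout * np.exp(re.eta.get("kout", 0.0))
    ec50 = pop.theta_ec50 * np.exp(re.eta.get("EC50", 0.0))
    return IndividualPDParams(BL=bl, kout=kout, Emax=pop.theta_emax, EC50=ec50)


def apply_residual_error(
    pred: np.ndarray,
    analyte: str,
    eps_exp: np.ndarray,
    eps_add: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the residual-error model to noise draws.

    PK (MTX): exponential error, ``y = pred*exp(eps_exp)``.
    PD (HCY): combined error, ``y = pred*exp(eps_exp) + eps_add``; values
    may fall at or below 0 for tiny predictions and are kept as generated.
    ``eps_*`` are already-scaled normal draws (SD = sigma).
    """
    pred = np.asarray(pred, dtype=float)
    y = pred * np.exp(np.asarray(eps_exp, dtype=float))
    if str(analyte) in ("Analyte.HCY", "HCY"):
        if eps_add is None:
            raise ValueError("HCY residual error needs additive draws")
        y = y + np.asarray(eps_add, dtype=float)
    return y


def sample_random_effects(
    pk: PKParameters,
    pd: PDParameters | None,
    n_subjects: int,
    n_occasions: int,
    rng: np.random.Generator | int,
) -> list[RandomEffects]:
    """Draw independent log-normal IIV/IOV effects for a cohort.

    ``eta ~ N(0, omega²)`` per subject (diagonal IIV), ``kappa ~ N(0, iov²)``
    independently per occasion.  Reproducible for a fixed seed/generator.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    iiv = {"CL": pk.omega2_cl, "V1": pk.omega2_v1, "Q": pk.omega2_q}
    iov = {"CL": pk.iov2_cl}
    if pd is not None:
        iiv.update({"BL": pd.omega2_bl, "kout": pd.omega2_kout, "EC50": pd.omega2_ec50})
        iov["BL"] = pd.iov2_bl
    for name, var in {**iiv, **iov}.items():
        if var < 0:
            raise ValueError(f"negative variance for {name}")
    out = []
    for _ in range(n_subjects):
        eta = {k: float(rng.normal(0.0, np.sqrt(v))) if v > 0 else 0.0 for k, v in iiv.items()}
        kappa = {
            k: rng.normal(0.0, np.sqrt(v), size=n_occasions) if v > 0 else np.zeros(n_occasions)
            for k, v in iov.items()
        }
        out.append(RandomEffects(eta=eta, kappa=kappa))
    return out


def zero_variance(pk: PKParameters, pd: PDParameters) -> tuple[PKParameters, PDParameters]:
    """Copies of the parameter sets with all variability switched off."""
    pk0 = replace(pk, omega2_cl=0.0, omega2_v1=0.0, omega2_q=0.0, iov2_cl=0.0, sigma_exp=0.0)
    pd0 = replace(
        pd, omega2_bl=0.0, omega2_kout=0.0, omega2_ec50=0.0, iov2_bl=0.0,
        sigma_exp=0.0, sigma_add=0.0,
    )
    return pk0, pd0
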