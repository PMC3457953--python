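"""Two-compartment methotrexate (MTX) plasma kinetics for one individual.

MTX disposition is linear: the plasma concentration produced by any dosing
history is the superposition of closed-form responses to each bolus or
constant-rate infusion.  The central-compartment model is parameterised by
total body clearance ``CL``, central volume ``V1``, intercompartmental
clearance ``Q`` and peripheral volume ``V2``.  Doses are given in mg and
concentrations in µM; conversion uses the MTX molar mass 454.44 g/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MTX_MOLAR_MASS",
    "Drug",
    "DoseEvent",
    "IndividualPKParams",
    "mtx_concentration",
    "mtx_concentration_ode",
]

#: molar mass of methotrexate, g/mol; converts mg doses to µmol amounts
MTX_MOLAR_MASS = 454.44

#: µmol of MTX per mg
UMOL_PER_MG = 1000.0 / MTX_MOLAR_MASS


class Drug(str, Enum):
    MTX = "MTX"
    FOLINATE = "FOL"


@dataclass(frozen=True)
class DoseEvent:
    """A timed administration.

    ``duration == 0`` denotes an IV bolus, otherwise a constant-rate
    infusion of ``amount`` mg over ``duration`` hours starting at ``start``
    hours from course start.
    """

    drug: Drug
    amount: float  # mg
    start: float  # h
    duration: float = 0.0  # h; 0 = bolus

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.start < 0:
            raise ValueError(f"dose start must be >= 0, got {self.start}")
        if self.duration < 0:
            raise ValueError(f"dose duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class IndividualPKParams:
    """Individual two-compartment parameters (all strictly positive)."""

    CL: float  # total body clearance, L/h
    V1: float  # central volume, L
    Q: float  # intercompartmental clearance, L/h
    V2: float  # peripheral volume, L

    def __post_init__(self) -> None:
        for name in ("CL", "V1", "Q", "V2"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")

    @property
    def micro_constants(self) -> tuple[float, float, float]:
        """(k10, k12, k21) in 1/h."""
        return self.CL / self.V1, self.Q / self.V1, self.Q / self.V2

    def hybrid_constants(self) -> tuple[float, float, float, float]:
        """Hybrid rate constants and bolus coefficients (alpha, beta, c_a, c_b).

        The unit-bolus (1 µmol) central concentration is
        ``c_a*exp(-alpha*t) + c_b*exp(-beta*t)`` in µM.
        """
        k10, k12, k21 = self.micro_constants
        s = k10 + k12 + k21
        disc = np.sqrt(s * s - 4.0 * k10 * k21)
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        c_a = (alpha - k21) / (self.V1 * (alpha - beta))
        c_b = (k21 - beta) / (self.V1 * (alpha - beta))
        return alpha, beta, c_a, c_b


def _check_mtx_doses(doses: Iterable[DoseEvent]) -> list[DoseEvent]:
    doses = list(doses)
    for d in doses:
        if d.drug is not Drug.MTX:
            raise ValueError(f"only MTX doses drive plasma kinetics, got {d.drug}")
    return doses


def mtx_concentration(
    params: IndividualPKParams,
    doses: Sequence[DoseEvent],
    t: float | np.ndarray,
) -> float | np.ndarray:
    """Central-compartment MTX concentration (µM) at time(s) ``t`` (h).

    Analytic superposition of the closed-form two-compartment response to
    each bolus / constant-rate infusion.  Returns 0 before the first dose.
    """
    doses = _check_mtx_doses(doses)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    alpha, beta, c_a, c_b = params.hybrid_constants()
    conc = np.zeros_like(t_arr, dtype=float)
    for d in doses:
        amt = d.amount * UMOL_PER_MG  # µmol
        tt = t_arr - d.start
        active = tt >= 0
        if d.duration == 0.0:
            for lam, coef in ((alpha, c_a), (beta, c_b)):
                conc += np.where(active, amt * coef * np.exp(-lam * np.clip(tt, 0, None)), 0.0)
        else:
            rate = amt / d.duration  # µmol/h
            for lam, coef in ((alpha, c_a), (beta, c_b)):
                t_on = np.clip(tt, 0.0, d.duration)
                rise = rate * coef / lam * (1.0 - np.exp(-lam * t_on))
                decay = np.exp(-lam * np.clip(tt - d.duration, 0, None))
                conc += np.where(active, rise * decay, 0.0)
    return conc if isinstance(t, np.ndarray) else float(conc)


def _infusion_rate(doses: Sequence[DoseEvent], t: float) -> float:
    """Total µmol/h input rate at time t (bolus events excluded)."""
    rate = 0.0
    for d in doses:
        if d.duration > 0 and d.start <= t < d.start + d.duration:
            rate += d.amount * UMOL_PER_MG / d.duration
    return rate


def mtx_concentration_ode(
    params: IndividualPKParams,
    doses: Sequence[DoseEvent],
    t: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Numerically integrated central concentration (µM); cross-check path.

    Integrates the two-compartment amount ODEs with LSODA, restarting at
    every dose start/stop so boluses and rate discontinuities are exact.
    Agrees with :func:`mtx_concentration` to solver tolerance.
    """
    doses = _check_mtx_doses(doses)
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("t must be a strictly increasing 1-D grid")
    k10, k12, k21 = params.micro_constants

    breaks = {0.0, float(t[-1])}
    for d in doses:
        if d.start < t[-1]:
            breaks.add(d.start)
        if d.duration > 0 and d.start + d.duration < t[-1]:
            breaks.add(d.start + d.duration)
    breaks = sorted(breaks)

    def rhs(tt, y, rate):
        a1, a2 = y
        return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    y = np.zeros(2)
    out = np.full(t.shape, np.nan)
    if t[0] == 0.0:
        out[0] = 0.0
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        for d in doses:
            if d.duration == 0.0 and d.start == lo:
                y[0] += d.amount * UMOL_PER_MG
        rate = _infusion_rate(doses, 0.5 * (lo + hi))
        inside = (t > lo) & (t <= hi)
        sol = solve_ivp(
            rhs, (lo, hi), y, dense_output=True,
            args=(rate,), method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"two-compartment ODE integration failed at t={lo}: {sol.message}")
        if inside.any():
            out[inside] = sol.sol(t[inside])[0] / params.V1
        y = sol.y[:, -1]
    # grid points at t=0 or exactly on a break before the first dose
    for i, ti in enumerate(t):
        if np.isnan(out[i]):
            out[i] = mtx_concentration(params, doses, ti)
    return out
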