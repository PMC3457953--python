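"""Homocysteine (HCY) turnover pharmacodynamics.

HCY plasma concentration follows an indirect-response (turnover) model,

    dC_HCY/dt = k_in - k_out * I(C_MTX(t)) * C_HCY,

where MTX inhibits the elimination rate constant through an Emax model,
``I(c) = 1 - Emax*c/(EC50 + c)``.  At baseline (no drug) the system sits at
the steady state ``C_HCY = BL`` so that ``k_in = k_out * BL`` always.
During folinate rescue the MTX effect is assumed fully reversed:
``I`` is replaced by 1 inside each rescue window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Analyte",
    "ConcentrationProfile",
    "IndividualPDParams",
    "remaining_kout_fraction",
    "simulate_hcy",
    "hcy_trajectory_grid",
]


class Analyte(str, Enum):
    MTX = "MTX"
    HCY = "HCY"


@dataclass(frozen=True)
class ConcentrationProfile:
    """A sampled concentration-time course of one analyte."""

    times: np.ndarray  # h, strictly increasing
    values: np.ndarray  # µM
    analyte: Analyte

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.analyte is Analyte.MTX and len(values) and np.any(values < 0):
            raise ValueError("MTX concentrations must be >= 0")


@dataclass(frozen=True)
class IndividualPDParams:
    """Individual turnover parameters; ``kin`` is always ``kout*BL``."""

    BL: float  # baseline HCY, µM
    kout: float  # HCY elimination rate constant, 1/h
    Emax: float  # maximal fractional inhibition of kout, in [0, 1]
    EC50: float  # MTX conc. of half-maximal inhibition, µM
    kin: float = field(init=False)  # HCY formation rate, µM/h (derived)

    def __post_init__(self) -> None:
        if self.BL <= 0:
            raise ValueError(f"BL must be > 0, got {self.BL}")
        if self.kout <= 0:
            raise ValueError(f"kout must be > 0, got {self.kout}")
        if self.EC50 <= 0:
            raise ValueError(f"EC50 must be > 0, got {self.EC50}")
        if not 0.0 <= self.Emax <= 1.0:
            raise ValueError(f"Emax must lie in [0, 1], got {self.Emax}")
        object.__setattr__(self, "kin", self.kout * self.BL)


def remaining_kout_fraction(c_mtx, Emax: float, EC50: float):
    """Fraction of the baseline k_out remaining at MTX concentration ``c_mtx``.

    ``1 - Emax*c/(EC50 + c)``, in (1-Emax, 1]; equals 1 with no drug and
    0.5 at ``c == EC50`` when ``Emax == 1``.
    """
    c = np.asarray(c_mtx, dtype=float)
    if np.any(c < 0):
        raise ValueError("MTX concentration must be >= 0")
    out = 1.0 - Emax * c / (EC50 + c)
    return out if isinstance(c_mtx, np.ndarray) else float(out)


def _in_windows(t: np.ndarray, windows: Sequence[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(np.shape(t), dtype=bool)
    for lo, hi in windows:
        mask |= (t >= lo) & (t < hi)
    return mask


def _check_windows(windows: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    ws = sorted((float(lo), float(hi)) for lo, hi in windows)
    for (lo, hi) in ws:
        if hi < lo:
            raise ValueError(f"rescue window ({lo}, {hi}) has end before start")
    for (_, hi0), (lo1, _) in zip(ws[:-1], ws[1:]):
        if lo1 < hi0:
            raise ValueError("rescue windows must not overlap")
    return ws


def simulate_hcy(
    pd_params: IndividualPDParams,
    mtx_profile: Callable[[float], float],
    rescue_windows: Sequence[tuple[float, float]],
    t_grid: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> ConcentrationProfile:
    """Integrate the HCY turnover ODE on ``t_grid`` (must start at 0).

    Initial condition is the individual baseline ``BL``.  Outside rescue
    windows MTX inhibits k_out through the Emax model; inside them the
    uninhibited turnover applies.  ``mtx_profile`` maps time (h) to MTX µM.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    windows = _check_windows(rescue_windows)

    kin, kout = pd_params.kin, pd_params.kout

    def rhs(t, y):
        if _in_windows(np.asarray(t), windows):
            frac = 1.0
        else:
            c = mtx_profile(t)
            if not np.isfinite(c):
                raise ValueError(f"MTX profile non-finite at t={t}")
            frac = remaining_kout_fraction(max(c, 0.0), pd_params.Emax, pd_params.EC50)
        return kin - kout * frac * y

    # restart at window edges so the coefficient discontinuity is exact
    breaks = sorted({0.0, float(t_grid[-1])} | {b for w in windows for b in w if 0 < b < t_grid[-1]})
    values = np.empty_like(t_grid)
    values[0] = pd_params.BL
    y0 = pd_params.BL
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        inside = (t_grid > lo) & (t_grid <= hi)
        sol = solve_ivp(
            rhs, (lo, hi), [y0], t_eval=t_grid[inside] if inside.any() else None,
            method="LSODA", rtol=rtol, atol=atol, max_step=(hi - lo) / 4,
        )
        if not sol.success:
            raise RuntimeError(f"HCY integration failed in [{lo}, {hi}]: {sol.message}")
        if inside.any():
            values[inside] = sol.y[0]
        y0 = float(sol.y[0, -1]) if sol.y.shape[1] else y0
    return ConcentrationProfile(times=t_grid, values=values, analyte=Analyte.HCY)


def hcy_trajectory_grid(
    bl: np.ndarray,
    kout: np.ndarray,
    emax: np.ndarray,
    ec50: np.ndarray,
    mtx_grid: np.ndarray,
    t_grid: np.ndarray,
    rescue_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Batched HCY trajectories by an exponential midpoint stepper.

    All parameter arrays broadcast against the leading axes of ``mtx_grid``
    (shape ``(..., n_t)``); ``t_grid`` is the shared, strictly increasing
    time grid starting at 0.  On each step the inhibition factor is frozen
    at the interval midpoint value and the then-linear ODE is advanced
    exactly, which is second-order accurate and exact at steady state.
    ``rescue_mask`` (same shape as ``mtx_grid``) marks grid points inside a
    folinate rescue window.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    mtx = np.asarray(mtx_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    if mtx.shape[-1] != len(t_grid):
        raise ValueError("mtx_grid last axis must match t_grid")
    bl, kout, emax, ec50 = (np.asarray(a, dtype=float)[..., None] for a in (bl, kout, emax, ec50))

    frac = 1.0 - emax * mtx / (ec50 + mtx)
    if rescue_mask is not None:
        frac = np.where(rescue_mask, 1.0, frac)
    kin = (kout * bl)[..., 0]

    shape = np.broadcast_shapes(frac.shape[:-1], bl.shape[:-1])
    y = np.empty(shape + (len(t_grid),))
    y[..., 0] = np.broadcast_to(bl[..., 0], shape)
    dt = np.diff(t_grid)
    k0 = kout[..., 0]
    for i in range(len(t_grid) - 1):
        k = k0 * 0.5 * (frac[..., i] + frac[..., i + 1])
        decay = np.exp(-k * dt[i])
        y[..., i + 1] = y[..., i] * decay + kin / k * (1.0 - decay)
    return y
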