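"""Folinate-rescue simulation study.

Simulates per-protocol consolidation courses for virtual cohorts of each
risk group (dose individualised to the target steady-state MTX
concentration, 33 µM low-risk / 65 µM standard-high-risk), computes each
patient's HCY trajectory twice — with the turnover model throughout, and
with the folinate switch (uninhibited elimination) inside the rescue
window — and summarises exposure metrics: peak concentration C_max, its
time t_max relative to the end of the 24-h infusion, AUC of HCY above the
individual baseline, and the HCY level at the end of rescue.  Metrics are
computed on noiseless individual trajectories; prediction intervals
reflect population variability only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import TARGET_CPSS, CovariateConfig, consolidation_dose, folinate_schedule, sample_population
from .pd import ConcentrationProfile
from .pk import mtx_concentration
from .population import (
    PDParameters,
    PKParameters,
    RiskGroup,
    individual_pd_params,
    individual_pk_params,
    sample_random_effects,
)

__all__ = [
    "RescueStudyResult",
    "run_rescue_study",
    "auc_over_baseline",
    "cmax_tmax",
    "wilcoxon_rank_sum",
    "RESCUE_WINDOW_CONSOLIDATION",
    "END_OF_INFUSION",
]

#: consolidation rescue window, h after start of infusion
RESCUE_WINDOW_CONSOLIDATION = (42.0, 72.0)
#: end of the consolidation MTX infusion, h
END_OF_INFUSION = 24.0


# --------------------------------------------------------------------------
# exposure metrics
# --------------------------------------------------------------------------

def auc_over_baseline(
    profile: ConcentrationProfile, baseline: float, window: tuple[float, float]
) -> float:
    """Signed trapezoidal integral of (C(t) - baseline) over ``window`` (µM·h)."""
    t, v = profile.times, profile.values
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"window {window} outside profile support [{t[0]}, {t[-1]}]")
    sel = (t >= lo) & (t <= hi)
    return float(np.trapezoid(v[sel] - baseline, t[sel]))


def cmax_tmax(profile: ConcentrationProfile, reference_time: float = 0.0) -> tuple[float, float]:
    """Peak value and its time relative to ``reference_time``; earliest on ties."""
    if len(profile.values) == 0:
        raise ValueError("empty profile")
    i = int(np.argmax(profile.values))  # argmax takes the first maximum
    return float(profile.values[i]), float(profile.times[i] - reference_time)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when min(n, m) <= 12 and no ties span the samples;
    otherwise the normal approximation with tie and continuity correction.
    Returns 1.0 when every value in both samples is identical.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


# --------------------------------------------------------------------------
# study
# --------------------------------------------------------------------------

@dataclass
class RescueStudyResult:
    """Per-patient metrics and summaries of the rescue simulation study."""

    n_patients: int
    horizon: float
    metrics: pd.DataFrame  # columns: risk, arm, patient, cmax, tmax, auc, end_hcy
    summary: pd.DataFrame  # medians, 90% PIs, % change, p-values
    curves: pd.DataFrame | None = None  # risk, arm, time, median, p5, p95
    seed: int | None = None

    def median(self, risk: str, arm: str, metric: str) -> float:
        m = self.metrics
        sel = m[(m["risk"] == risk) & (m["arm"] == arm)]
        return float(sel[metric].median())

    def auc_reduction_percent(self, risk: str) -> float:
        """100 * (1 - median AUC with folinate / median AUC without)."""
        with_f = self.median(risk, "folinate", "auc")
        without = self.median(risk, "no_folinate", "auc")
        return 100.0 * (1.0 - with_f / without)

    def p_value(self, risk: str, metric: str) -> float:
        row = self.summary[(self.summary["risk"] == risk) & (self.summary["metric"] == metric)]
        return float(row["p_value"].iloc[0])

    def plot(self, path=None):
        """Median HCY curves with shaded 90% prediction bands per stratum."""
        if self.curves is None:
            raise ValueError("curves were not stored for this study")
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        risks = self.curves["risk"].unique()
        fig, axes = plt.subplots(1, len(risks), figsize=(6 * len(risks), 4), squeeze=False)
        colors = {"no_folinate": "grey", "folinate": "black"}
        for ax, risk in zip(axes[0], risks):
            for arm, color in colors.items():
                c = self.curves[(self.curves["risk"] == risk) & (self.curves["arm"] == arm)]
                ax.plot(c["time"], c["median"], color=color, label=arm.replace("_", " "))
                ax.fill_between(c["time"], c["p5"], c["p95"], color=color, alpha=0.2)
            ax.set_title(f"{risk}: HCY with/without folinate")
            ax.set_xlabel("time after start of MTX infusion (h)")
            ax.set_ylabel("HCY (µM)")
            ax.legend()
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _simulate_stratum(
    risk: RiskGroup,
    n_patients: int,
    pk: PKParameters,
    pdp: PDParameters,
    rng: np.random.Generator,
    t_grid: np.ndarray,
    extend_rescue: bool,
    cov_config: CovariateConfig | None,
):
    """Batched HCY trajectories of one risk stratum, both arms.

    Returns (hcy_no_rescue, hcy_rescue, baselines) arrays of shape
    (n_patients, n_t) / (n_patients,).
    """
    cfg = cov_config or CovariateConfig()
    pop = sample_population(n_patients, rng, cfg)
    # two occasions: the prior course whose realised clearance is the
    # protocol's dosing estimate, and the simulated course itself
    res = sample_random_effects(pk, pdp, n_patients, 2, rng)

    target = TARGET_CPSS[risk]
    _, window = folinate_schedule("consolidation", 1.0, risk)
    n_t = len(t_grid)
    mtx = np.empty((n_patients, n_t))
    bl = np.empty(n_patients)
    kout = np.empty(n_patients)
    ec50 = np.empty(n_patients)
    emax = np.empty(n_patients)
    for i, (subj, re) in enumerate(zip(pop, res)):
        cl_est = individual_pk_params(pk, subj, re, 0).CL
        ipk = individual_pk_params(pk, subj, re, 1)
        doses = consolidation_dose(target, cl_est)
        mtx[i] = mtx_concentration(ipk, doses, t_grid)
        ipd = individual_pd_params(pdp, subj, re, 1)
        bl[i], kout[i], ec50[i], emax[i] = ipd.BL, ipd.kout, ipd.EC50, ipd.Emax

    rescue_mask = (t_grid >= window[0]) & (t_grid < window[1])
    rescue_mask = np.broadcast_to(rescue_mask, mtx.shape).copy()
    if extend_rescue:
        # protocol: rescue continues until MTX < 0.1 µM in patients with
        # MTX > 1.0 µM at 42 h
        i42 = int(np.searchsorted(t_grid, 42.0 - 1e-9))
        needs_ext = mtx[:, i42] > 1.0
        after = t_grid >= window[1]
        still_high = mtx >= 0.1
        ext = needs_ext[:, None] & after[None, :] & still_high
        # extension holds until the LAST grid point where MTX >= 0.1
        ext = np.logical_and(after[None, :], np.cumsum(ext[:, ::-1], axis=1)[:, ::-1] > 0)
        rescue_mask |= ext & needs_ext[:, None]

    from .pd import hcy_trajectory_grid

    hcy_plain = hcy_trajectory_grid(bl, kout, emax, ec50, mtx, t_grid)
    hcy_rescue = hcy_trajectory_grid(bl, kout, emax, ec50, mtx, t_grid, rescue_mask=rescue_mask)
    return hcy_plain, hcy_rescue, bl


def run_rescue_study(
    pk_params: PKParameters | None = None,
    pd_params: PDParameters | None = None,
    n_patients: int = 1000,
    seed: int | np.random.Generator = 0,
    horizon: float = 168.0,
    grid_step: float = 0.1,
    extend_rescue: bool = True,
    cov_config: CovariateConfig | None = None,
) -> RescueStudyResult:
    """Run the rescue study: ``n_patients`` virtual patients per risk group.

    Each patient's consolidation course is individualised to the risk
    group's target Cpss using the clearance realised on a prior occasion;
    the HCY trajectory is simulated on a ``grid_step``-h grid over
    ``[0, horizon]`` with and without the folinate switch (rescue window
    42-72 h, extended while MTX >= 0.1 µM in patients above 1.0 µM at
    42 h when ``extend_rescue``).
    """
    pk = pk_params or PKParameters()
    pdp = pd_params or PDParameters()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_grid = np.arange(0.0, horizon + 1e-9, grid_step)
    end_idx = int(np.searchsorted(t_grid, RESCUE_WINDOW_CONSOLIDATION[1] - 1e-9))

    rows = []
    pvals = []
    curve_rows = []
    curve_idx = np.searchsorted(t_grid, np.arange(0.0, horizon + 1e-9, 1.0))
    for risk in (RiskGroup.LR, RiskGroup.SHR):
        plain, resc, bl = _simulate_stratum(
            risk, n_patients, pk, pdp, rng, t_grid, extend_rescue, cov_config
        )
        for arm, traj in (("no_folinate", plain), ("folinate", resc)):
            sub = traj[:, curve_idx]
            q = np.percentile(sub, [5, 50, 95], axis=0)
            for j, t in enumerate(t_grid[curve_idx]):
                curve_rows.append({
                    "risk": risk.value, "arm": arm, "time": float(t),
                    "median": float(q[1, j]), "p5": float(q[0, j]), "p95": float(q[2, j]),
                })
        for arm, traj in (("no_folinate", plain), ("folinate", resc)):
            i_max = np.argmax(traj, axis=1)
            cmax = traj[np.arange(n_patients), i_max]
            tmax = t_grid[i_max] - END_OF_INFUSION
            auc = np.trapezoid(traj - bl[:, None], t_grid, axis=1)
            end_hcy = traj[:, end_idx]
            for i in range(n_patients):
                rows.append({
                    "risk": risk.value, "arm": arm, "patient": i + 1,
                    "cmax": cmax[i], "tmax": tmax[i], "auc": auc[i],
                    "end_hcy": end_hcy[i],
                })
        # per-metric Wilcoxon comparisons between arms
        for metric, a, b in (
            ("cmax", plain.max(axis=1), resc.max(axis=1)),
            ("auc", np.trapezoid(plain - bl[:, None], t_grid, axis=1),
             np.trapezoid(resc - bl[:, None], t_grid, axis=1)),
            ("end_hcy", plain[:, end_idx], resc[:, end_idx]),
        ):
            pvals.append({
                "risk": risk.value, "metric": metric,
                "p_value": wilcoxon_rank_sum(a, b),
            })

    metrics = pd.DataFrame(rows)
    summary_rows = []
    pv = pd.DataFrame(pvals)
    for risk in ("LR", "SHR"):
        for metric in ("cmax", "tmax", "auc", "end_hcy"):
            row = {"risk": risk, "metric": metric}
            for arm in ("no_folinate", "folinate"):
                sel = metrics[(metrics["risk"] == risk) & (metrics["arm"] == arm)][metric]
                row[f"median_{arm}"] = float(sel.median())
                row[f"p5_{arm}"] = float(sel.quantile(0.05))
                row[f"p95_{arm}"] = float(sel.quantile(0.95))
            if row["median_no_folinate"] != 0:
                row["change_percent"] = 100.0 * (
                    row["median_folinate"] / row["median_no_folinate"] - 1.0
                )
            hit = pv[(pv["risk"] == risk) & (pv["metric"] == metric)]
            row["p_value"] = float(hit["p_value"].iloc[0]) if len(hit) else float("nan")
            summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    return RescueStudyResult(
        n_patients=n_patients, horizon=horizon, metrics=metrics, summary=summary,
        curves=pd.DataFrame(curve_rows), seed=seed if isinstance(seed, int) else None,
    )
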