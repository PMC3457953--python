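"""Model evaluation: nonparametric bootstrap and visual predictive checks.

The bootstrap resamples subjects with replacement and refits, yielding
percentile confidence intervals of every population parameter.  The VPC
simulates replicate datasets under the fitted model (including residual
error) at the observed design and overlays the observed concentrations on
the simulated median and 90% prediction band, stratified and optionally
transformed (change from the course pre-dose baseline for HCY).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .estimation import PDProblem, PKProblem
from .population import PDParameters, PKParameters, params_to_dict

__all__ = [
    "BootstrapResult",
    "VPCResult",
    "bootstrap",
    "bootstrap_fit",
    "vpc_pk",
    "vpc_pd",
    "split_dataset",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Subject-level nonparametric bootstrap output."""

    n_replicates: int
    replicates: pd.DataFrame  # one row per successful replicate
    ci90: pd.DataFrame  # columns p5, p95; index = parameter
    n_failed: int

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.n_replicates


def resample_subjects(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Resample subjects with replacement; IDs are renumbered 1..n."""
    ids = df["ID"].unique()
    draw = rng.choice(ids, size=len(ids), replace=True)
    parts = []
    for new_id, old in enumerate(draw, start=1):
        block = df[df["ID"] == old].copy()
        block["ID"] = new_id
        parts.append(block)
    return pd.concat(parts, ignore_index=True)


def bootstrap(
    df: pd.DataFrame,
    fit_fn: Callable[[pd.DataFrame], dict[str, float]],
    n_reps: int,
    rng: np.random.Generator | int,
) -> BootstrapResult:
    """Generic subject-level bootstrap of any dataset->estimates map."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows, n_failed = [], 0
    for _ in range(n_reps):
        rep = resample_subjects(df, rng)
        try:
            rows.append(fit_fn(rep))
        except Exception as exc:
            n_failed += 1
            logger.warning("bootstrap replicate failed: %s", exc)
    reps = pd.DataFrame(rows)
    if len(reps):
        ci = reps.quantile([0.05, 0.95]).T
        ci.columns = ["p5", "p95"]
    else:
        ci = pd.DataFrame(columns=["p5", "p95"])
    res = BootstrapResult(n_replicates=n_reps, replicates=reps, ci90=ci, n_failed=n_failed)
    if n_reps and n_failed / n_reps > 0.2:
        logger.warning("more than 20%% of bootstrap replicates failed (%d/%d)",
                       n_failed, n_reps)
    return res


def bootstrap_fit(
    df: pd.DataFrame,
    n_reps: int,
    rng: np.random.Generator | int,
    start: dict | None = None,
    covariates: Sequence[str] = ("scr",),
    maxfev: int = 2000,
) -> BootstrapResult:
    """Bootstrap the population PK fit (percentile 90% CIs per parameter)."""
    from .estimation import fit_population

    def fit_fn(rep):
        f = fit_population(rep, start=start, covariates=covariates, maxfev=maxfev)
        return f.params

    return bootstrap(df, fit_fn, n_reps, rng)


# --------------------------------------------------------------------------
# visual predictive check
# --------------------------------------------------------------------------

@dataclass
class VPCResult:
    """Per-stratum VPC tables and the raw observed points."""

    analyte: str
    n_simulations: int
    tables: dict[str, pd.DataFrame]  # stratum -> [time, n_obs, median, p5, p95]
    observed: pd.DataFrame  # [stratum, time, value]

    def coverage(self) -> float:
        """Fraction of observed points inside their stratum/time 90% band."""
        inside = total = 0
        for stratum, tab in self.tables.items():
            tab_idx = tab.set_index("time")
            pts = self.observed[self.observed["stratum"] == stratum]
            for t, v in zip(pts["time"], pts["value"]):
                row = tab_idx.loc[t]
                total += 1
                inside += int(row["p5"] <= v <= row["p95"])
        return inside / total if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for stratum, tab in self.tables.items():
            t = tab.copy()
            t.insert(0, "stratum", stratum)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)

    def plot(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        strata = list(self.tables)
        fig, axes = plt.subplots(1, len(strata), figsize=(5 * len(strata), 4), squeeze=False)
        for ax, stratum in zip(axes[0], strata):
            tab = self.tables[stratum]
            pts = self.observed[self.observed["stratum"] == stratum]
            ax.plot(pts["time"], pts["value"], "ko", ms=3, alpha=0.4)
            ax.plot(tab["time"], tab["median"], "-", color="C0")
            ax.fill_between(tab["time"], tab["p5"], tab["p95"], color="C0", alpha=0.25)
            ax.set_title(f"{self.analyte} VPC — {stratum}")
            ax.set_xlabel("time (h)")
            ax.set_ylabel(f"{self.analyte} (µM)")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _percentile_tables(times, strata, values_obs, sims):
    """Build per-stratum time tables from observed values and (n_sim, n_obs) sims."""
    tables = {}
    obs_rows = []
    for stratum in pd.unique(strata):
        sel = strata == stratum
        tab_rows = []
        for t in np.unique(times[sel]):
            here = sel & (times == t)
            pool = sims[:, here].ravel()
            tab_rows.append({
                "time": float(t), "n_obs": int(here.sum()),
                "median": float(np.median(pool)),
                "p5": float(np.percentile(pool, 5)),
                "p95": float(np.percentile(pool, 95)),
            })
        tables[str(stratum)] = pd.DataFrame(tab_rows).sort_values("time").reset_index(drop=True)
        for t, v in zip(times[sel], values_obs[sel]):
            obs_rows.append({"stratum": str(stratum), "time": float(t), "value": float(v)})
    return tables, pd.DataFrame(obs_rows)


def vpc_pk(
    df: pd.DataFrame,
    pk_params: PKParameters | dict,
    n_sim: int,
    rng: np.random.Generator | int,
    stratify: str = "RISK",
    covariates: Sequence[str] = ("scr",),
) -> VPCResult:
    """VPC of the MTX submodel at the observed dosing/sampling design.

    Simulates ``n_sim`` replicates of every PK observation (new IIV/IOV
    draws and exponential residual error) and tabulates the simulated
    median and 90% prediction band per stratum and nominal sampling time.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    params = params_to_dict(pk_params) if isinstance(pk_params, PKParameters) else dict(pk_params)
    problem = PKProblem(df, covariates=covariates)
    n, q = problem.n_subjects, problem.n_re
    w = problem.prior_variances(params)
    b = rng.normal(0.0, 1.0, size=(n_sim, n, q)) * np.sqrt(w)
    logpred = problem.predict(params, b.reshape(n_sim * n, q)).reshape(n_sim, n, -1)
    eps = rng.normal(0.0, params["sigma_exp"], size=logpred.shape)
    sims = np.exp(logpred + eps)

    mask = problem.mask
    obs = np.exp(problem.y)[mask]
    sims = sims[:, mask]

    d = problem._d
    n_occ, s = d["t_obs"].shape[1:]
    times_full = d["t_obs"].reshape(n, n_occ * s)
    if stratify == "PHASE":
        # dose stratum: window arm (4-h vs 24-h) and consolidation target
        # (risk group), mirroring the dose-stratified presentation
        risk = df.groupby("ID", sort=True).first()["RISK"].to_numpy()
        phase = np.empty((n, n_occ), dtype=object)
        occs = d["occs"]
        win_long = (d["dur"][:, 0, :].max(axis=1) > 20.0)  # 24-h window arm
        for j, o in enumerate(occs):
            if o == min(occs):
                phase[:, j] = np.where(win_long, "WIN-24h", "WIN-4h")
            else:
                phase[:, j] = np.char.add("CONS-", risk.astype(str))
        strata_full = np.repeat(phase[:, :, None], s, axis=2).reshape(n, n_occ * s)
    else:
        strat_col = df.groupby("ID", sort=True).first()[stratify].to_numpy()
        strata_full = np.repeat(strat_col[:, None], n_occ * s, axis=1)
    times = times_full[mask]
    strata = strata_full[mask]

    tables, observed = _percentile_tables(times, strata, obs, sims)
    return VPCResult(analyte="MTX", n_simulations=n_sim, tables=tables, observed=observed)


def vpc_pd(
    df: pd.DataFrame,
    pk_params: PKParameters | dict,
    pd_params: PDParameters | dict,
    n_sim: int,
    rng: np.random.Generator | int,
    stratify: str = "RISK",
    transform: str = "difference",
    covariates: Sequence[str] = ("scr",),
    grid_step: float = 0.25,
    chunk: int = 25,
) -> VPCResult:
    """VPC of the HCY submodel on the change from the course pre-dose value.

    Each replicate redraws PK and PD random effects, rebuilds the subject
    MTX forcing profile, simulates HCY at the observed times with combined
    residual error and applies the same baseline transform to simulations
    and observations (``difference`` subtracts the course pre-dose sample;
    ``ratio`` divides by it; ``none`` uses raw values).
    """
    if transform not in ("difference", "ratio", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pkp = params_to_dict(pk_params) if isinstance(pk_params, PKParameters) else dict(pk_params)
    pdp = params_to_dict(pd_params) if isinstance(pd_params, PDParameters) else dict(pd_params)

    pk_problem = PKProblem(df, covariates=covariates)
    obs_hcy = df[(df["EVID"] == 0) & (df["DVID"] == "HCY") & df["DV"].notna()]
    t_max = max(42.0, float(obs_hcy["TIME"].max()))
    t_grid = np.arange(0.0, t_max + grid_step, grid_step)

    # subject MTX grids at zero random effects are placeholders; the PD
    # problem only stores design/obs layout, per-chunk grids are injected
    zero_grids = {}
    d = pk_problem._d
    id_pos = {i: k for k, i in enumerate(d["ids"])}
    occ_pos = {o: k for k, o in enumerate(d["occs"])}
    for (i, o), _ in obs_hcy.groupby(["ID", "OCC"], sort=True):
        zero_grids[(i, o)] = np.zeros(len(t_grid))
    pd_problem = PDProblem(df, zero_grids, t_grid)
    npd, n_occ_pd, max_s = pd_problem._obs_shape

    # map PD problem rows back to PK tensors for MTX grid computation
    pd_ids = pd_problem.subject_ids
    pd_occs = pd_problem.hcy_occs
    pk_rows = np.array([id_pos[i] for i in pd_ids])
    pk_cols = np.array([occ_pos[o] for o in pd_occs])

    w_pk = pk_problem.prior_variances(pkp)
    w_pd = pd_problem.prior_variances(pdp)

    sims_parts = []
    done = 0
    while done < n_sim:
        k = min(chunk, n_sim - done)
        b_pk = rng.normal(0.0, 1.0, size=(k, pk_problem.n_subjects, pk_problem.n_re)) * np.sqrt(w_pk)
        mtx = _mtx_grids_batch(pk_problem, pkp, b_pk, t_grid)  # (k, n_pk, n_occ_pk, g)
        mtx_pd = mtx[:, pk_rows][:, :, pk_cols]  # (k, npd, n_occ_pd, g)
        b_pd = rng.normal(0.0, 1.0, size=(k, npd, pd_problem.n_re)) * np.sqrt(w_pd)
        preds = _pd_predict_with_grids(pd_problem, pdp, b_pd, mtx_pd)  # (k, npd, m)
        e1 = rng.normal(0.0, pdp["sigma_exp"], size=preds.shape)
        e2 = rng.normal(0.0, pdp["sigma_add"], size=preds.shape)
        sims_parts.append(preds * np.exp(e1) + e2)
        done += k
    sims = np.concatenate(sims_parts, axis=0)  # (n_sim, npd, m)

    y = pd_problem.y.copy()
    mask = pd_problem.mask.copy()
    times_full = np.where(mask, t_grid[pd_problem._tidx.reshape(npd, -1)], np.nan)

    if transform != "none":
        # course pre-dose (t == 0) value per subject-occasion
        t3 = times_full.reshape(npd, n_occ_pd, max_s)
        base_idx = np.argmax(t3 == 0.0, axis=2)  # first t==0 slot
        has_base = np.take_along_axis(t3, base_idx[..., None], axis=2)[..., 0] == 0.0
        y3 = y.reshape(npd, n_occ_pd, max_s)
        base_obs = np.take_along_axis(y3, base_idx[..., None], axis=2)[..., 0]
        s3 = sims.reshape(-1, npd, n_occ_pd, max_s)
        base_sim = np.take_along_axis(
            s3, np.broadcast_to(base_idx[None, ..., None], s3.shape[:3] + (1,)), axis=3
        )[..., 0]
        if transform == "difference":
            y3 = y3 - base_obs[..., None]
            s3 = s3 - base_sim[..., None]
        else:
            y3 = y3 / base_obs[..., None]
            s3 = s3 / base_sim[..., None]
        keep = (t3 != 0.0) & has_base[..., None]
        mask = mask & keep.reshape(npd, -1)
        y = y3.reshape(npd, -1)
        sims = s3.reshape(-1, npd, n_occ_pd * max_s)

    strat_col = (
        obs_hcy.groupby("ID", sort=True).first()[stratify].reindex(pd_ids).to_numpy()
    )
    strata_full = np.repeat(strat_col[:, None], n_occ_pd * max_s, axis=1)
    tables, observed = _percentile_tables(
        times_full[mask], strata_full[mask], y[mask], sims[:, mask]
    )
    return VPCResult(analyte="HCY", n_simulations=n_sim, tables=tables, observed=observed)


def _mtx_grids_batch(problem: PKProblem, params: dict, b: np.ndarray, t_grid: np.ndarray):
    """MTX concentration on ``t_grid`` for stacked random-effect draws.

    Returns (k, n, n_occ, len(t_grid)); reuses the problem's dose tensors.
    """
    d = problem._d
    k, n, _ = b.shape
    saved = d["t_obs"], d["dv"]
    try:
        g = len(t_grid)
        d["t_obs"] = np.broadcast_to(t_grid, (n, len(d["occs"]), g)).copy()
        d["dv"] = np.full_like(d["t_obs"], np.nan)
        logc = problem.predict(params, b.reshape(k * n, -1)).reshape(k, n, len(d["occs"]), g)
    finally:
        d["t_obs"], d["dv"] = saved
    return np.exp(logc)


def _pd_predict_with_grids(problem: PDProblem, params: dict, b: np.ndarray, mtx: np.ndarray):
    """PD predictions with per-draw MTX grids (k, n, o, g)."""
    saved = problem.mtx
    k, n, _ = b.shape
    try:
        # fold the draw axis into the problem's grid by looping per draw
        outs = []
        for j in range(k):
            problem.mtx = mtx[j]
            outs.append(problem.predict(params, b[j]))
    finally:
        problem.mtx = saved
    return np.stack(outs, axis=0)


def split_dataset(
    df: pd.DataFrame, index_fraction: float = 2.0 / 3.0, rng: np.random.Generator | int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random subject-level split into index and evaluation datasets."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ids = df["ID"].unique()
    n_index = int(round(index_fraction * len(ids)))
    perm = rng.permutation(ids)
    index_ids = set(perm[:n_index])
    is_index = df["ID"].isin(index_ids)
    return df[is_index].reset_index(drop=True), df[~is_index].reset_index(drop=True)
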