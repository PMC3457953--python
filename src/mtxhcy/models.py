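"""Model/Results front door in the statsmodels style.

``MTXPKModel`` and ``HCYTurnoverModel`` wrap the rectangular dataset and
the Laplace/FOCE estimation engine; ``fit()`` returns a results object
carrying the estimates, OFV, empirical Bayes modes and evaluation helpers
(``bootstrap``, ``vpc``, ``summary``).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from . import estimation as est
from . import evaluation as ev
from .dataset import validate_dataset
from .population import PDParameters, PKParameters, omega2_to_cv

__all__ = ["MTXPKModel", "MTXPKResults", "HCYTurnoverModel", "HCYTurnoverResults"]

_PK_UNITS = {
    "theta_cl": "L/h/m²", "theta_v1": "L/m²", "theta_q": "L/h/m²",
    "theta_v2": "L/m²", "theta_cr": "-", "theta_cl_age": "-", "theta_cl_sex": "-",
    "sigma_exp": "(log scale)",
}
_PD_UNITS = {
    "theta_bl": "µM", "theta_kout": "1/h", "theta_ec50": "µM",
    "theta_bl_age": "µM/year", "theta_emax": "-", "sigma_exp": "(log scale)",
    "sigma_add": "µM",
}


class _ResultsBase:
    def __init__(self, model, fit: est.FitResult, units: dict):
        self.model = model
        self._fit = fit
        self._units = units

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._fit.params, dtype=float)

    @property
    def ofv(self) -> float:
        return self._fit.ofv

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def ebes(self) -> pd.DataFrame:
        return self._fit.ebes

    @property
    def fit_result(self) -> est.FitResult:
        return self._fit

    def summary(self) -> str:
        f = self._fit
        lines = [
            f"{type(self).__name__}",
            "=" * 58,
            f"subjects: {f.n_subjects}    observations: {f.n_obs}",
            f"OFV (-2 log-likelihood): {f.ofv:.3f}   converged: {f.converged}",
            f"objective evaluations: {f.n_evaluations}",
            "-" * 58,
            f"{'parameter':<16}{'estimate':>14}  {'unit / %CV':<20}",
            "-" * 58,
        ]
        for k, v in f.params.items():
            if k.startswith(("omega2", "iov2")):
                extra = f"{omega2_to_cv(v):.2f} %CV"
            else:
                extra = self._units.get(k, "")
            lines.append(f"{k:<16}{v:>14.5g}  {extra:<20}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        return self._fit.summary_frame()


class MTXPKModel:
    """Population two-compartment MTX model bound to a dataset.

    Parameters
    ----------
    data : DataFrame in the rectangular dataset layout (see mtxhcy.dataset).
    covariates : clearance covariates to include ("scr", "age", "sex").
    """

    def __init__(self, data: pd.DataFrame, covariates: Sequence[str] = ("scr",)):
        self.data = validate_dataset(data)
        self.covariates = tuple(covariates)

    @classmethod
    def from_csv(cls, path, covariates: Sequence[str] = ("scr",)) -> "MTXPKModel":
        from .dataset import read_dataset

        return cls(read_dataset(path), covariates=covariates)

    def fit(self, start: PKParameters | dict | None = None, maxfev: int = 1200,
            fixed: Sequence[str] = ()) -> "MTXPKResults":
        f = est.fit_population(
            self.data, start=start, covariates=self.covariates, fixed=fixed, maxfev=maxfev
        )
        return MTXPKResults(self, f)

    def loglike_ofv(self, params: PKParameters) -> float:
        """Laplace OFV at fixed population parameters."""
        return est.marginal_ofv(self.data, params, covariates=self.covariates)


class MTXPKResults(_ResultsBase):
    def __init__(self, model: MTXPKModel, fit: est.FitResult):
        super().__init__(model, fit, _PK_UNITS)

    def individual_params(self) -> pd.DataFrame:
        """Empirical Bayes individual PK parameters per subject-occasion."""
        problem: est.PKProblem = self._fit.problem
        return problem.individual_pk_frame(
            self._fit.params, self._fit.ebes.drop(columns="ID").to_numpy()
        )

    def bootstrap(self, n_reps: int, seed, maxfev: int = 2000) -> ev.BootstrapResult:
        return ev.bootstrap_fit(
            self.model.data, n_reps, seed, start=self._fit.params,
            covariates=self.model.covariates, maxfev=maxfev,
        )

    def vpc(self, n_sim: int = 1000, seed=0, stratify: str = "RISK") -> ev.VPCResult:
        return ev.vpc_pk(
            self.model.data, self._fit.params, n_sim, seed,
            stratify=stratify, covariates=self.model.covariates,
        )


class HCYTurnoverModel:
    """Indirect-response HCY model fitted sequentially on a PK fit."""

    def __init__(self, data: pd.DataFrame, pk_results: MTXPKResults,
                 estimate_emax: bool = False):
        self.data = validate_dataset(data)
        self.pk_results = pk_results
        self.estimate_emax = estimate_emax

    def fit(self, start: PDParameters | dict | None = None, maxfev: int = 1200) -> "HCYTurnoverResults":
        f = est.sequential_pd_fit(
            self.data, self.pk_results.fit_result, start=start,
            estimate_emax=self.estimate_emax, maxfev=maxfev,
        )
        return HCYTurnoverResults(self, f)


class HCYTurnoverResults(_ResultsBase):
    def __init__(self, model: HCYTurnoverModel, fit: est.FitResult):
        super().__init__(model, fit, _PD_UNITS)

    def vpc(self, n_sim: int = 200, seed=0, stratify: str = "RISK",
            transform: str = "difference") -> ev.VPCResult:
        pk = self.model.pk_results
        return ev.vpc_pd(
            self.model.data, pk.params.to_dict(), self.params.to_dict(),
            n_sim, seed, stratify=stratify, transform=transform,
            covariates=pk.model.covariates,
        )
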