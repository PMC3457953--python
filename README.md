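# mtxhcy

Population pharmacokinetic/pharmacodynamic modelling of high-dose
methotrexate (HDMTX) and plasma homocysteine (HCY) in paediatric acute
lymphoblastic leukaemia, with synthetic-trial generation, nonlinear
mixed-effects estimation, model evaluation and a folinate-rescue
simulation study.

## Who this is for

Pharmacometricians and clinical-pharmacology researchers who want a
self-contained, tested implementation of the MTX→HCY indirect-response
analysis: to simulate Total-XV-like trials, to check estimator behaviour on
a realistic sparse design, or to explore how folinate rescue schedules
shape HCY exposure.

## The model

MTX disposition is a BSA-scaled two-compartment model (CL, V1, Q, V2) with
a creatinine power covariate on clearance, log-normal interindividual
(IIV) and interoccasion (IOV) variability and exponential residual error.
HCY follows a turnover model in which MTX inhibits the elimination rate
constant through an Emax relationship:

    dC_HCY/dt = k_in − k_out · (1 − Emax·C_MTX/(EC50 + C_MTX)) · C_HCY,
    k_in = k_out · BL   (baseline steady state)

with an age-dependent baseline BL and combined (exponential + additive)
residual error. Folinate rescue is a switch that restores the uninhibited
k_out inside the rescue window. At the protocol steady-state targets of
33 µM (low-risk) and 65 µM (standard/high-risk), k_out is reduced to 1.93%
and 0.99% of baseline — HCY conversion is almost completely blocked during
the infusion.

Estimation is Laplace/FOCE: the marginal likelihood is expanded at the
empirical Bayes mode of each subject's random effects with a Gauss-Newton
Hessian; on linear-Gaussian models the objective equals the exact
−2 log-likelihood, and that equivalence is enforced by the test suite.
See `docs/methods.md` for assumptions, parameters, defaults and
limitations.

## Worked example

```python
import numpy as np
import mtxhcy as m

# 1. simulate a Total-XV-like trial: 60 virtual patients, full protocol
rng = np.random.default_rng(7)
pop = m.sample_population(60, rng)
data = m.generate_trial(pop, m.PKParameters(), m.PDParameters(), rng)

# 2. fit the population PK model, then the HCY model sequentially
pk = m.MTXPKModel(data).fit(maxfev=700)
pd = m.HCYTurnoverModel(data, pk).fit(maxfev=700)
print(pk.params["theta_cl"], pd.params["theta_bl"])

# 3. folinate-rescue simulation study, 1000 patients per risk group
study = m.run_rescue_study(n_patients=1000, seed=42)
print(study.median("LR", "no_folinate", "cmax"),
      study.median("LR", "no_folinate", "tmax"),
      study.auc_reduction_percent("LR"))
```

On this seed the fits return a typical clearance of 6.74 L/h/m² (simulated
truth 6.68) and a typical HCY baseline of 4.73 µM (truth 4.88). The rescue
study prints

```
9.19  14.0  14.8
```

i.e. the median low-risk HCY peak is 9.19 µM, reached 14.0 h after the end
of the 24-h MTX infusion — before rescue begins at 42 h, which is why
folinate leaves the peak essentially unchanged (Wilcoxon p = 0.84) — while
folinate cuts the median HCY AUC above baseline by 14.8% (p < 1e-20). The
same study reports the standard/high-risk stratum: peak 9.79 µM and AUC
reduction 22.2%.

The command line mirrors these steps:

```bash
mtxhcy simulate --n 150 --seed 1 -o trial.csv
mtxhcy fit trial.csv -o pk_fit
mtxhcy rescue-study --seed 7 -o rescue
```

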