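import numpy as np
import pytest

import mtxhcy as m
from mtxhcy.design import TrialDesign


@pytest.fixture(scope="session")
def pk_params():
    return m.PKParameters()


@pytest.fixture(scope="session")
def pd_params():
    return m.PDParameters()


@pytest.fixture(scope="session")
def typical_pk():
    return m.IndividualPKParams(CL=6.68, V1=18.6, Q=0.161, V2=3.09)


@pytest.fixture(scope="session")
def typical_pd():
    return m.IndividualPDParams(BL=4.88, kout=0.027, Emax=1.0, EC50=0.648)


@pytest.fixture(scope="session")
def consolidation_doses():
    """Individualised consolidation events for the typical LR subject."""
    return m.consolidation_dose(33.0, 6.68)


@pytest.fixture(scope="session")
def small_trial(pk_params, pd_params):
    """12 subjects, 2 consolidation courses: cheap dataset for mechanics."""
    rng = np.random.default_rng(99)
    pop = m.sample_population(12, rng)
    design = TrialDesign(n_consolidation=2)
    return m.generate_trial(pop, pk_params, pd_params, rng, design=design)


@pytest.fixture(scope="session")
def medium_trial(pk_params, pd_params):
    """35 subjects, full protocol design; shared by the fitting tests."""
    rng = np.random.default_rng(202)
    pop = m.sample_population(35, rng)
    return m.generate_trial(pop, pk_params, pd_params, rng)


@pytest.fixture(scope="session")
def medium_fits(medium_trial):
    """One PK fit + sequential PD fit, shared across estimation tests."""
    pk_res = m.MTXPKModel(medium_trial).fit(maxfev=600)
    pd_res = m.HCYTurnoverModel(medium_trial, pk_res).fit(maxfev=600)
    return pk_res, pd_res
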