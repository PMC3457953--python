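"""Covariate models, random effects and residual-error structure."""

import numpy as np
import pytest

import mtxhcy as m
from mtxhcy.population import (
    AGE_REF,
    DEFAULT_CCR_TABLE,
    cv_to_omega2,
    omega2_to_cv,
    params_from_dict,
    params_to_dict,
)


def _subject(**kw):
    base = dict(id=1, age=5.42, sex=m.Sex.MALE, bsa=1.0, weight=20.0,
                height=110.0, scr=0.4, risk=m.RiskGroup.LR)
    base.update(kw)
    return m.Subject(**base)


class TestAdjustedCreatinine:
    def test_deterministic_and_sex_shared_below_split(self):
        a = m.adjusted_creatinine(5.0, m.Sex.MALE)
        assert a == m.adjusted_creatinine(5.0, m.Sex.MALE)
        assert a == m.adjusted_creatinine(5.0, m.Sex.FEMALE)

    def test_sex_specific_above_split(self):
        assert m.adjusted_creatinine(16.0, m.Sex.MALE) > m.adjusted_creatinine(
            16.0, m.Sex.FEMALE
        )

    def test_whole_age_range_within_table_bounds(self):
        values = [
            m.adjusted_creatinine(a, s)
            for a in np.linspace(1.03, 18.85, 200)
            for s in (m.Sex.MALE, m.Sex.FEMALE)
        ]
        lo = min(v for _, v in DEFAULT_CCR_TABLE["child_bands"])
        hi = max(v for bands in DEFAULT_CCR_TABLE["teen_bands"].values() for _, v in bands)
        assert min(values) >= lo and max(values) <= hi

    def test_out_of_range_age_clamps(self, caplog):
        v = m.adjusted_creatinine(0.2, m.Sex.MALE)
        assert v == m.adjusted_creatinine(1.0, m.Sex.MALE)


class TestIndividualPK:
    def test_reference_subject_returns_typical_values(self, pk_params):
        subj = _subject(scr=m.adjusted_creatinine(5.42, m.Sex.MALE))
        re = m.RandomEffects.zero()
        p = m.individual_pk_params(pk_params, subj, re, 0)
        assert p.CL == pytest.approx(pk_params.theta_cl)
        assert p.V1 == pytest.approx(pk_params.theta_v1)
        assert p.V2 == pytest.approx(pk_params.theta_v2)

    def test_doubling_creatinine_scales_clearance_by_power(self, pk_params):
        ref = m.adjusted_creatinine(5.42, m.Sex.MALE)
        re = m.RandomEffects.zero()
        base = m.individual_pk_params(pk_params, _subject(scr=ref), re, 0).CL
        doubled = m.individual_pk_params(pk_params, _subject(scr=2 * ref), re, 0).CL
        assert doubled / base == pytest.approx(2.0 ** (-0.314), rel=1e-10)

    def test_eta_acts_as_lognormal_factor(self, pk_params):
        subj = _subject(scr=m.adjusted_creatinine(5.42, m.Sex.MALE))
        re = m.RandomEffects(eta={"CL": 0.1, "V1": 0.0, "Q": 0.0},
                             kappa={"CL": np.zeros(5)})
        p = m.individual_pk_params(pk_params, subj, re, 0)
        assert p.CL == pytest.approx(pk_params.theta_cl * np.exp(0.1))

    def test_clearance_monotone_decreasing_in_creatinine(self, pk_params):
        re = m.RandomEffects.zero()
        cls = [
            m.individual_pk_params(pk_params, _subject(scr=s), re, 0).CL
            for s in np.linspace(0.1, 1.2, 30)
        ]
        assert np.all(np.diff(cls) < 0)


class TestIndividualPD:
    def test_reference_age_gives_typical_baseline(self, pd_params):
        p = m.individual_pd_params(
            pd_params, _subject(age=AGE_REF),
            m.RandomEffects(eta={}, kappa={}), 0,
        )
        assert p.BL == pytest.approx(4.88)
        assert p.kout == pytest.approx(0.027)
        assert p.kin == pytest.approx(4.88 * 0.027)

    def test_baseline_age_slope(self, pd_params):
        re = m.RandomEffects(eta={}, kappa={})
        b1 = m.individual_pd_params(pd_params, _subject(age=AGE_REF + 1), re, 0).BL
        b0 = m.individual_pd_params(pd_params, _subject(age=AGE_REF), re, 0).BL
        assert b1 - b0 == pytest.approx(0.116)

    def test_negative_typical_baseline_raises(self, pd_params):
        import dataclasses

        bad = dataclasses.replace(pd_params, theta_bl=0.1, theta_bl_age=0.116)
        with pytest.raises(ValueError):
            m.individual_pd_params(bad, _subject(age=1.5), m.RandomEffects(eta={}, kappa={}), 0)


class TestResidualError:
    def test_zero_draws_return_prediction(self):
        assert m.apply_residual_error(np.array([10.0]), "MTX", np.array([0.0]))[0] == 10.0
        assert m.apply_residual_error(
            np.array([10.0]), "HCY", np.array([0.0]), np.array([0.0])
        )[0] == 10.0

    def test_pk_exponential_error_sd(self):
        """1e5 draws at sigma_exp=0.235: SD of log(y) within 2%."""
        rng = np.random.default_rng(1)
        eps = rng.normal(0.0, 0.235, 100_000)
        y = m.apply_residual_error(np.full(100_000, 10.0), "MTX", eps)
        assert np.std(np.log(y)) == pytest.approx(0.235, rel=0.02)

    def test_pd_additive_term_dominates_at_zero_prediction(self):
        rng = np.random.default_rng(2)
        e1 = rng.normal(0.0, 0.165, 100_000)
        e2 = rng.normal(0.0, 0.911, 100_000)
        y = m.apply_residual_error(np.full(100_000, 1e-9), "HCY", e1, e2)
        assert np.var(y) == pytest.approx(0.911**2, rel=0.02)


class TestRandomEffects:
    def test_zero_variances_give_zero_draws(self, pk_params, pd_params):
        import dataclasses

        pk0 = dataclasses.replace(
            pk_params, omega2_cl=0.0, omega2_v1=0.0, omega2_q=0.0, iov2_cl=0.0
        )
        pd0 = dataclasses.replace(
            pd_params, omega2_bl=0.0, omega2_kout=0.0, omega2_ec50=0.0, iov2_bl=0.0
        )
        res = m.sample_random_effects(pk0, pd0, 5, 3, 0)
        for r in res:
            assert all(v == 0.0 for v in r.eta.values())
            assert all(np.all(k == 0.0) for k in r.kappa.values())

    def test_lognormal_cv_matches_reported_percent(self, pk_params, pd_params):
        """omega² from 14.53%CV reproduces that CV over 1e5 draws within 2%."""
        res = m.sample_random_effects(pk_params, None, 100_000, 1, 7)
        factors = np.exp([r.eta["CL"] for r in res])
        cv = 100.0 * np.std(factors) / np.mean(factors)
        assert cv == pytest.approx(14.53, rel=0.02)

    def test_same_seed_identical_draws(self, pk_params, pd_params):
        a = m.sample_random_effects(pk_params, pd_params, 4, 5, 42)
        b = m.sample_random_effects(pk_params, pd_params, 4, 5, 42)
        for ra, rb in zip(a, b):
            assert ra.eta == rb.eta
            for k in ra.kappa:
                np.testing.assert_array_equal(ra.kappa[k], rb.kappa[k])

    def test_iiv_iov_variance_decomposition(self, pk_params, pd_params):
        """Within-subject log-CL variance across occasions ~ iov²;
        total across subjects ~ omega² + iov² (Monte Carlo)."""
        res = m.sample_random_effects(pk_params, None, 4000, 5, 3)
        log_cl = np.array([[r.eta["CL"] + k for k in r.kappa["CL"]] for r in res])
        within = np.mean(np.var(log_cl, axis=1, ddof=1))
        total = np.var(log_cl.ravel(), ddof=1)
        assert within == pytest.approx(pk_params.iov2_cl, rel=0.1)
        assert total == pytest.approx(pk_params.omega2_cl + pk_params.iov2_cl, rel=0.1)


def test_cv_omega2_round_trip():
    assert omega2_to_cv(cv_to_omega2(14.53)) == pytest.approx(14.53)


def test_params_dict_round_trip(pk_params, pd_params):
    assert params_from_dict(m.PKParameters, params_to_dict(pk_params)) == pk_params
    assert params_from_dict(m.PDParameters, params_to_dict(pd_params)) == pd_params
    with pytest.raises(ValueError):
        params_from_dict(m.PKParameters, {"nonsense": 1.0})
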