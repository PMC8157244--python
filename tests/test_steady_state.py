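"""Closed-form steady-state engine versus the numerical multiple-dose oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tamsim as ts
from tamsim.steady_state import MG_TO_NG, L_TO_ML, _ss_troughs_arrays


def make_ind(ka=0.4, cl20=5.5, cl23=0.25, cl30=5.0, v_tam=1000.0, v_endx=400.0,
             tlag=0.5):
    return ts.IndividualPK(cl20_i=cl20, cl23_i=cl23, cl30=cl30, ka=ka,
                           tlag=tlag, v_tam_f=v_tam, v_endx_f=v_endx)


class TestAnalyticTrough:
    def test_zero_dose_gives_zero_concentrations(self):
        res = ts.ss_trough_analytic(make_ind(), ts.DosingRegimen(dose=0.0))
        assert res.c_ss_min_tam == 0.0 and res.c_ss_min_endx == 0.0

    def test_dose_linearity_exact(self):
        ind = make_ind()
        r20 = ts.ss_trough_analytic(ind, ts.DosingRegimen(dose=20.0))
        r40 = ts.ss_trough_analytic(ind, ts.DosingRegimen(dose=40.0))
        assert r40.c_ss_min_tam == pytest.approx(2 * r20.c_ss_min_tam, rel=1e-15)
        assert r40.c_ss_min_endx == pytest.approx(2 * r20.c_ss_min_endx, rel=1e-15)

    def test_formation_fraction_limit(self):
        # cl23 -> 0 with total clearance fixed: endoxifen vanishes,
        # tamoxifen unchanged
        base = make_ind(cl20=5.0, cl23=0.75)
        limit = make_ind(cl20=5.75, cl23=0.0)
        reg = ts.DosingRegimen()
        rb = ts.ss_trough_analytic(base, reg)
        rl = ts.ss_trough_analytic(limit, reg)
        assert rl.c_ss_min_endx == 0.0
        assert rl.c_ss_min_tam == pytest.approx(rb.c_ss_min_tam, rel=1e-12)

    def test_rejects_lag_not_shorter_than_interval(self):
        with pytest.raises(ValueError, match="lag"):
            ts.ss_trough_analytic(make_ind(tlag=24.0), ts.DosingRegimen())

    def test_accumulation_factor_equals_superposition(self):
        """Summing K single-dose contributions (geometric series partial
        sums) converges to the accumulation-factor closed form."""
        ind = make_ind()
        reg = ts.DosingRegimen()
        dose_ng = reg.dose * MG_TO_NG
        ka, k_tam, k_endx, fm = ind.ka, ind.k_tam, ind.k_endx, ind.fm
        t0 = reg.tau - ind.tlag

        def single_dose_amounts(t):
            a_tam = dose_ng * ka / (ka - k_tam) * (
                math.exp(-k_tam * t) - math.exp(-ka * t))
            pref = dose_ng * ka * k_tam * fm
            a_endx = pref * (
                math.exp(-ka * t) / ((k_tam - ka) * (k_endx - ka))
                + math.exp(-k_tam * t) / ((ka - k_tam) * (k_endx - k_tam))
                + math.exp(-k_endx * t) / ((ka - k_endx) * (k_tam - k_endx))
            )
            return a_tam, a_endx

        n_terms = 4000  # ~33 tamoxifen half-lives of history
        tam = sum(single_dose_amounts(t0 + k * reg.tau)[0] for k in range(n_terms))
        endx = sum(single_dose_amounts(t0 + k * reg.tau)[1] for k in range(n_terms))
        res = ts.ss_trough_analytic(ind, reg)
        assert tam / (ind.v_tam_f * L_TO_ML) == pytest.approx(
            res.c_ss_min_tam, rel=1e-9)
        assert endx / (ind.v_endx_f * L_TO_ML) == pytest.approx(
            res.c_ss_min_endx, rel=1e-9)

    def test_degenerate_rates_warn_and_match_oracle(self):
        # k_tam == k_endx exactly: the engine perturbs and must still agree
        # with the numerical solution to well within the perturbation scale
        ind = make_ind(cl20=4.75, cl23=0.25, cl30=2.0, v_endx=400.0)
        assert ind.k_tam == pytest.approx(ind.k_endx)
        reg = ts.DosingRegimen(duration=200.0)
        with pytest.warns(RuntimeWarning, match="near-equal rate constants"):
            res = ts.ss_trough_analytic(ind, reg)
        oracle = ts.ode_oracle(ind, reg)
        assert res.c_ss_min_endx == pytest.approx(
            oracle.final_trough_endx, rel=1e-4)


class TestOdeOracle:
    def test_zero_dose_trajectory_identically_zero(self):
        series = ts.ode_oracle(make_ind(), ts.DosingRegimen(dose=0.0, duration=5))
        assert np.all(series.c_tam == 0) and np.all(series.c_endx == 0)

    def test_single_dose_matches_bateman_curve(self):
        ind = make_ind(tlag=0.0)
        reg = ts.DosingRegimen(dose=20.0, tau=24.0, duration=10.0)
        t_eval = np.linspace(1.0, 200.0, 40)
        series = ts.ode_oracle(ind, reg, n_doses=1, t_eval=t_eval)
        dose_ng = reg.dose * MG_TO_NG
        ka, k_tam = ind.ka, ind.k_tam
        expected = (dose_ng * ka / (ka - k_tam)
                    * (np.exp(-k_tam * t_eval) - np.exp(-ka * t_eval))
                    / (ind.v_tam_f * L_TO_ML))
        assert series.sample_c_tam == pytest.approx(expected, rel=1e-6)

    def test_pre_dose_sequence_accumulates_monotonically(self):
        series = ts.ode_oracle(make_ind(), ts.DosingRegimen(duration=60.0))
        assert np.all(np.diff(series.c_tam) > -1e-9)
        assert np.all(np.diff(series.c_endx) > -1e-9)

    def test_six_months_reaches_steady_state_within_one_percent(
            self, params, reference_patient, regimen):
        # the 182-day treatment covers ~36 tamoxifen half-lives for the
        # typical individual, so the final trough sits on the steady state
        ind = ts.individual_clearances(reference_patient, params)
        half_life_days = math.log(2) / min(ind.ka, ind.k_tam, ind.k_endx) / 24
        assert half_life_days <= 14
        oracle = ts.ode_oracle(ind, regimen)
        res = ts.ss_trough_analytic(ind, regimen)
        assert oracle.final_trough_endx == pytest.approx(
            res.c_ss_min_endx, rel=0.01)
        assert oracle.final_trough_tam == pytest.approx(
            res.c_ss_min_tam, rel=0.01)


class TestEngineOracleEquivalence:
    @given(
        ka=st.floats(min_value=0.1, max_value=2.0),
        k_tam=st.floats(min_value=0.004, max_value=0.05),
        k_endx=st.floats(min_value=0.004, max_value=0.05),
        fm=st.floats(min_value=0.01, max_value=0.9),
        tlag=st.floats(min_value=0.0, max_value=5.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_analytic_matches_ode_after_twenty_half_lives(
            self, ka, k_tam, k_endx, fm, tlag):
        v_tam, v_endx = 1000.0, 400.0
        cl_total = k_tam * v_tam
        ind = ts.IndividualPK(
            cl20_i=cl_total * (1 - fm), cl23_i=cl_total * fm,
            cl30=k_endx * v_endx, ka=ka, tlag=tlag,
            v_tam_f=v_tam, v_endx_f=v_endx,
        )
        tau = 24.0
        slowest = min(ka, k_tam, k_endx)
        n_doses = math.ceil(20 * math.log(2) / slowest / tau) + 1
        reg = ts.DosingRegimen(dose=20.0, tau=tau, duration=n_doses * tau / 24.0)
        oracle = ts.ode_oracle(ind, reg, n_doses=n_doses)
        res = ts.ss_trough_analytic(ind, reg)
        assert res.c_ss_min_tam == pytest.approx(oracle.final_trough_tam, rel=1e-4)
        assert res.c_ss_min_endx == pytest.approx(oracle.final_trough_endx, rel=1e-4)


class TestSimulatePopulation:
    def test_single_reference_patient_equals_typical(self, params,
                                                     reference_patient, regimen):
        results = ts.simulate_population([reference_patient], params, regimen)
        ind = ts.individual_clearances(reference_patient, params)
        expected = ts.ss_trough_analytic(ind, regimen)
        assert results[0].c_ss_min_tam == pytest.approx(
            expected.c_ss_min_tam, rel=1e-12)
        assert results[0].c_ss_min_endx == pytest.approx(
            expected.c_ss_min_endx, rel=1e-12)

    def test_bitwise_deterministic(self, bundled_tables, small_pool, params,
                                   regimen):
        pop = ts.build_population(bundled_tables["Latino"], 300, small_pool,
                                  seed=2, omega2_cl20=params.omega2_cl20,
                                  omega2_cl23=params.omega2_cl23)
        a = ts.simulate_population(pop, params, regimen)
        b = ts.simulate_population(pop, params, regimen)
        assert a == b

    def test_endoxifen_monotone_in_activity_score(self, params, regimen):
        troughs = []
        for c in ts.AS_CLASSES:
            p = ts.VirtualPatient(0, "European", c, 55.0, 67.0, 0.0, 0.0)
            r = ts.simulate_population([p], params, regimen)[0]
            troughs.append(r.c_ss_min_endx)
        assert troughs == sorted(troughs)

    def test_optional_residual_noise_is_opt_in(self, params, regimen,
                                               reference_patient):
        import numpy as np

        d = params.to_dict()
        d["sigma_resid"] = 0.2
        noisy_params = ts.PKParameters.from_dict(d)
        clean = ts.simulate_population([reference_patient], noisy_params, regimen)
        noisy = ts.simulate_population(
            [reference_patient], noisy_params, regimen,
            residual_rng=np.random.default_rng(0))
        base = ts.simulate_population([reference_patient], params, regimen)
        assert clean == base  # no rng supplied -> residual-free
        assert noisy[0].c_ss_min_endx != base[0].c_ss_min_endx
        assert noisy[0].c_ss_min_endx > 0

    def test_error_carries_patient_context(self, params, regimen):
        bad = ts.VirtualPatient(77, "European", "2", -5.0, 67.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="patient 77"):
            ts.simulate_population([bad], params, regimen)
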