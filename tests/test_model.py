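import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transpkpd import (
    DoseRegimen,
    PDParams,
    PKParams,
    ValidationError,
    ce_regimen_analytic,
    conc_regimen,
    conc_single_dose,
    effect_on_grid,
    simulate_pkpd,
    steady_state_metrics,
)


class TestConcSingleDose:
    def test_zero_at_time_zero(self, mouse_pk):
        assert conc_single_dose(0.0, 100.0, mouse_pk) == 0.0

    def test_peak_concentration_at_100_mg_kg(self, mouse_pk):
        ke = mouse_pk.ke
        tmax = np.log(mouse_pk.ka / ke) / (mouse_pk.ka - ke)
        assert tmax == pytest.approx(0.83, abs=0.01)
        assert conc_single_dose(tmax, 100.0, mouse_pk) == pytest.approx(6.9e4, rel=0.01)

    def test_negative_time_rejected(self, mouse_pk):
        with pytest.raises(ValidationError):
            conc_single_dose(-1.0, 10.0, mouse_pk)

    def test_equal_absorption_elimination_rates_finite_limit(self):
        pk = PKParams(ka=0.5, cl_f=0.5, v_f=1.0)  # ke = ka = 0.5
        t = 2.0
        expected = 10.0 * 0.5 * t * np.exp(-0.5 * t) / 1.0 * 1000.0
        assert conc_single_dose(t, 10.0, pk) == pytest.approx(expected, rel=1e-9)

    def test_continuity_across_the_degenerate_limit(self):
        near = PKParams(ka=0.5 * (1 + 1e-9), cl_f=0.5, v_f=1.0)
        at = PKParams(ka=0.5, cl_f=0.5, v_f=1.0)
        assert conc_single_dose(3.0, 10.0, near) == pytest.approx(conc_single_dose(3.0, 10.0, at), rel=1e-7)


class TestConcRegimen:
    def test_single_dose_reduction(self, mouse_pk):
        reg = DoseRegimen(25.0, interval=24.0, n_doses=1)
        t = np.linspace(0, 48, 50)
        np.testing.assert_allclose(
            conc_regimen(t, reg, mouse_pk), conc_single_dose(t, 25.0, mouse_pk), rtol=1e-12
        )

    def test_superposition_equals_explicit_sum(self, mouse_pk):
        reg = DoseRegimen(25.0, interval=12.0, n_doses=5)
        t = np.linspace(0, 96, 97)
        explicit = np.zeros_like(t)
        for td in reg.dose_times:
            m = t >= td
            explicit[m] += np.asarray(conc_single_dose(t[m] - td, 25.0, mouse_pk))
        np.testing.assert_allclose(conc_regimen(t, reg, mouse_pk), explicit, rtol=1e-9)

    def test_linearity_in_dose(self, mouse_pk):
        t = np.linspace(0.5, 72, 40)
        reg1 = DoseRegimen(10.0, 12.0, 4)
        reg2 = DoseRegimen(20.0, 12.0, 4)
        np.testing.assert_allclose(
            conc_regimen(t, reg2, mouse_pk), 2 * np.asarray(conc_regimen(t, reg1, mouse_pk)), rtol=1e-12
        )

    def test_steady_state_trough_matches_accumulation_formula(self, mouse_pk):
        """Criterion: superposed trough equals the geometric-series closed form."""
        tau, dose, n = 12.0, 25.0, 200
        reg = DoseRegimen(dose, tau, n)
        ka, ke, vf = mouse_pk.ka, mouse_pk.ke, mouse_pk.v_f
        qe, qa = np.exp(-ke * tau), np.exp(-ka * tau)
        closed = (
            dose / vf * 1000.0 * ka / (ka - ke) * (qe / (1 - qe) - qa / (1 - qa))
        )
        simulated = conc_regimen(n * tau, reg, mouse_pk)
        assert simulated == pytest.approx(closed, rel=5e-3)


class TestEffectCompartment:
    def test_analytic_ce_matches_ode(self, mouse_pk, mouse_pd):
        reg = DoseRegimen(25.0, 12.0, 8)
        sim = simulate_pkpd(reg, mouse_pk, mouse_pd, t_end=120.0)
        ce = np.asarray(ce_regimen_analytic(sim.times, reg, mouse_pk, mouse_pd.ke0))
        mask = sim.ce > 1e-3
        assert np.max(np.abs(ce[mask] - sim.ce[mask]) / sim.ce[mask]) < 1e-3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analytic_ce_matches_ode_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        pk = PKParams(ka=rng.uniform(1.0, 4.0), cl_f=rng.uniform(0.2, 0.8), v_f=rng.uniform(0.5, 2.0))
        pdp = PDParams(
            ke0=rng.uniform(0.02, 0.2), kin=30.0, kout=rng.uniform(0.5, 2.0), imax=0.9, ic50=300.0
        )
        reg = DoseRegimen(rng.uniform(5, 50), 24.0, 3)
        sim = simulate_pkpd(reg, pk, pdp, t_end=96.0)
        ce = np.asarray(ce_regimen_analytic(sim.times, reg, pk, pdp.ke0))
        mask = sim.ce > 1e-3
        assert np.max(np.abs(ce[mask] - sim.ce[mask]) / sim.ce[mask]) < 1e-3

    def test_fast_grid_integrator_tracks_ode(self, mouse_pk, mouse_pd):
        reg = DoseRegimen(25.0, 12.0, 8)
        sim = simulate_pkpd(reg, mouse_pk, mouse_pd, t_end=96.0)
        fast = effect_on_grid(sim.times, reg, mouse_pk, mouse_pd)
        assert np.max(np.abs(fast - sim.effect) / sim.effect) < 2e-3


class TestSimulate:
    def test_negligible_dose_keeps_baseline(self, mouse_pk, mouse_pd):
        sim = simulate_pkpd(DoseRegimen(1e-9, 24.0, 3), mouse_pk, mouse_pd, t_end=96.0)
        np.testing.assert_allclose(sim.effect, mouse_pd.baseline, rtol=1e-6)
        assert mouse_pd.baseline == pytest.approx(20.07, abs=0.005)

    def test_no_inhibition_keeps_baseline(self, mouse_pk, mouse_pd):
        pdp = PDParams(ke0=mouse_pd.ke0, kin=mouse_pd.kin, kout=mouse_pd.kout, imax=0.0, ic50=340.0)
        sim = simulate_pkpd(DoseRegimen(100.0, 12.0, 4), mouse_pk, pdp, t_end=72.0)
        np.testing.assert_allclose(sim.effect, pdp.baseline, rtol=1e-8)

    def test_saturated_inhibition_approaches_asymptote(self, mouse_pk, mouse_pd):
        # Ce >> IC50 drives E towards kin/(kout·(1−imax)) = 223 µg/mg
        reg = DoseRegimen(1.0e4, 12.0, 2000)
        ss = steady_state_metrics(reg, mouse_pk, mouse_pd)
        assert mouse_pd.e_max_asymptote == pytest.approx(223.0, abs=0.1)
        assert ss.e_max == pytest.approx(223.0, rel=0.03)

    @given(
        st.floats(min_value=5.0, max_value=100.0),
        st.floats(min_value=0.3, max_value=0.95),
    )
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_effect_trajectory_bounds(self, dose, imax):
        pk = PKParams(ka=2.7, cl_f=0.415, v_f=1.034)
        pdp = PDParams(ke0=0.0566, kin=29.1, kout=1.45, imax=imax, ic50=340.0)
        grid = np.arange(0.0, 96.0 + 1e-9, 0.1)
        e = effect_on_grid(grid, DoseRegimen(dose, 12.0, 6), pk, pdp)
        assert np.min(e) >= pdp.baseline * (1 - 1e-6)
        assert np.max(e) <= pdp.e_max_asymptote * (1 + 1e-6)


class TestSteadyState:
    def test_efficacious_regimen_maintains_target(self, mouse_pk, mouse_pd):
        ss = steady_state_metrics(DoseRegimen(25.0, 12.0, 10000), mouse_pk, mouse_pd)
        assert ss.converged
        assert ss.e_min >= 125.0
        assert ss.e_min == pytest.approx(132.2, rel=0.02)

    def test_metric_orderings(self, mouse_pk, mouse_pd):
        ss = steady_state_metrics(DoseRegimen(25.0, 12.0, 10000), mouse_pk, mouse_pd)
        assert ss.c_trough <= ss.c_avg <= ss.c_max
        assert ss.e_min <= ss.e_max

    def test_e_min_monotone_in_dose(self, mouse_pk, mouse_pd):
        mins = [
            steady_state_metrics(DoseRegimen(d, 12.0, 10000), mouse_pk, mouse_pd).e_min
            for d in (5.0, 10.0, 25.0, 50.0)
        ]
        assert mins == sorted(mins)

    def test_sparse_single_dosing_has_vanishing_trough(self, mouse_pk, mouse_pd):
        ss = steady_state_metrics(DoseRegimen(25.0, 3000.0, 5), mouse_pk, mouse_pd)
        assert ss.c_trough < 1e-6
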