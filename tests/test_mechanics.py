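"""Compartment mechanics: PV law, filling dynamics, hysteresis, metrics."""

import numpy as np
import pytest

from alveosim._kernels import run_breaths
from alveosim.mechanics import (CompartmentParams, LungParams, LungState,
                                MechanicsConfig, alveolar_pressure,
                                dynamic_compliance, p_peak_top20,
                                percent_recruited, step_mechanics,
                                update_derecruitment, update_recruitment)


def single_lung(k=0.1, k3=0.0, p_ext=0.0, top=0.0, d_close=0.0, r_aw=1.0,
                tau_c=0.0, n=1):
    comps = [CompartmentParams(k=k, k3=k3, p_ext=p_ext, top=top,
                               d_close=d_close, r_aw=r_aw, tau_c=tau_c)
             for _ in range(n)]
    return LungParams.from_compartments(comps)


class TestAlveolarPressure:
    def test_unstressed_volume_returns_p_ext(self):
        p = CompartmentParams(k=0.5, p_ext=3.0)
        assert alveolar_pressure(0.0, p) == 3.0

    def test_linear_law(self):
        p = CompartmentParams(k=0.1, k3=0.0, p_ext=2.0)
        assert alveolar_pressure(100.0, p) == pytest.approx(12.0)

    def test_cubic_stiffening(self):
        # 0.05*200 + 1e-7*200**3 = 10 + 0.8
        p = CompartmentParams(k=0.05, k3=1e-7, p_ext=0.0)
        assert alveolar_pressure(200.0, p) == pytest.approx(10.8)

    def test_strictly_increasing(self):
        p = CompartmentParams(k=0.3, k3=1e-5, p_ext=1.0)
        v = np.linspace(0, 60, 200)
        assert np.all(np.diff(alveolar_pressure(v, p)) > 0)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            alveolar_pressure(-1.0, CompartmentParams(k=0.1))


class TestStepMechanics:
    def test_collapsed_compartments_unchanged(self):
        params = single_lung(n=3)
        state = LungState.initial(params)  # all collapsed
        before = state.volume.copy()
        step_mechanics(state, params, 30.0, 0.01)
        assert np.array_equal(state.volume, before)

    def test_equilibrium_no_flow(self):
        params = single_lung(k=0.2, p_ext=1.0)
        state = LungState.initial(params, open_mask=np.array([True]))
        state.volume[:] = 20.0
        state.p_alv[:] = alveolar_pressure(20.0, params.compartment(0))
        step_mechanics(state, params, state.p_alv[0], 0.01)
        assert state.volume[0] == pytest.approx(20.0)

    def test_rc_closed_form(self):
        # single open compartment, linear law: V(t) = V_inf (1 - e^{-t/(R/k)})
        k, r = 0.5, 1.0
        params = single_lung(k=k, r_aw=r)
        state = LungState.initial(params, open_mask=np.array([True]))
        p_aw, dt, t_end = 10.0, 0.001, 2.0
        for _ in range(int(t_end / dt)):
            step_mechanics(state, params, p_aw, dt)
        v_exact = (p_aw / k) * (1.0 - np.exp(-t_end / (r / k)))
        assert state.volume[0] == pytest.approx(v_exact, rel=5e-3)

    def test_mass_conservation(self):
        # total volume change equals the time-integral of total airway flow
        rng = np.random.default_rng(0)
        params = single_lung(k=0.4, r_aw=1.2, n=5)
        state = LungState.initial(params, open_mask=np.ones(5, bool))
        dt = 0.005
        integral = 0.0
        v0 = state.total_volume
        for i in range(400):
            p_aw = 10.0 + 5.0 * np.sin(i * dt * 2.0) + rng.normal(0, 0.1)
            flow = np.sum((p_aw - state.p_alv) / params.r_aw)
            step_mechanics(state, params, p_aw, dt)
            integral += flow * dt
        assert state.total_volume - v0 == pytest.approx(integral, rel=1e-6, abs=1e-6)

    def test_nonfinite_pressure_rejected(self):
        params = single_lung()
        state = LungState.initial(params, open_mask=np.array([True]))
        with pytest.raises(ValueError):
            step_mechanics(state, params, np.nan, 0.01)


class TestRecruitment:
    def test_zero_tau_opens_immediately(self):
        params = single_lung(top=20.0, d_close=12.0, tau_c=0.0)
        state = LungState.initial(params)
        update_recruitment(state, params, 25.0, 0.01)
        assert state.is_open[0]

    def test_interrupted_hold_resets_timer(self):
        params = single_lung(top=20.0, d_close=12.0, tau_c=5.0)
        state = LungState.initial(params)
        for _ in range(400):  # 4 s above TOP: not enough
            update_recruitment(state, params, 25.0, 0.01)
        assert not state.is_open[0]
        update_recruitment(state, params, 15.0, 0.01)  # drop below TOP
        assert state.opening_timer[0] == 0.0

    def test_sustained_hold_opens(self):
        params = single_lung(top=20.0, d_close=12.0, tau_c=5.0)
        state = LungState.initial(params)
        for _ in range(501):
            update_recruitment(state, params, 25.0, 0.01)
        assert state.is_open[0]
        assert state.volume[0] == 0.0  # opens empty, fills via mechanics


class TestDerecruitment:
    def setup_method(self):
        self.params = single_lung(k=0.5, top=20.0, d_close=12.0)

    def make_open_state(self, p_ee):
        state = LungState.initial(self.params, open_mask=np.array([True]))
        state.volume[:] = p_ee / 0.5
        state.p_alv[:] = p_ee
        return state

    def test_collapse_below_closing_pressure(self):
        state = self.make_open_state(7.0)  # closing pressure is 8
        update_derecruitment(state, self.params)
        assert not state.is_open[0]
        assert state.volume[0] == 0.0

    def test_stays_open_above_closing_pressure(self):
        state = self.make_open_state(9.0)
        update_derecruitment(state, self.params)
        assert state.is_open[0]

    def test_hysteresis_cycle(self):
        # rise above TOP (held >= tau_c), return above closing pressure: open
        params = single_lung(k=0.5, top=20.0, d_close=12.0, tau_c=1.0)
        state = LungState.initial(params)
        for _ in range(101):
            update_recruitment(state, params, 25.0, 0.01)
        assert state.is_open[0]
        state.volume[:] = 9.0 / 0.5
        state.p_alv[:] = 9.0  # between closing (8) and TOP (20)
        update_derecruitment(state, params)
        assert state.is_open[0]
        assert params.closing[0] < params.top[0]


class TestMetrics:
    def test_dynamic_compliance_value(self):
        assert dynamic_compliance(450.0, 25.0, 10.0) == pytest.approx(30.0)

    def test_zero_tidal_volume(self):
        assert dynamic_compliance(0.0, 25.0, 10.0) == 0.0

    def test_parallel_compartments_add(self):
        # two identical compartments deliver twice the volume of one
        def tidal(n):
            params = single_lung(k=0.5, r_aw=1.0, n=n)
            state = LungState.initial(params, open_mask=np.ones(n, bool))
            for _ in range(500):
                step_mechanics(state, params, 15.0, 0.01)
            return state.total_volume
        assert tidal(2) == pytest.approx(2 * tidal(1), rel=1e-12)

    def test_zero_driving_pressure_rejected(self):
        with pytest.raises(ValueError):
            dynamic_compliance(400.0, 10.0, 10.0)

    def test_p_peak_uniform(self):
        params = single_lung(n=10)
        state = LungState.initial(params)
        state.max_pressure[:] = 40.0
        assert p_peak_top20(state) == pytest.approx(40.0)

    def test_p_peak_top_quintile(self):
        params = single_lung(n=100)
        state = LungState.initial(params)
        state.max_pressure[:] = np.arange(1.0, 101.0)
        assert p_peak_top20(state) == pytest.approx(np.mean(np.arange(81, 101)))

    def test_p_peak_empty_lung(self):
        state = LungState(np.zeros(0, bool), np.zeros(0), np.zeros(0),
                          np.zeros(0), np.zeros(0))
        with pytest.raises(ValueError):
            p_peak_top20(state)

    def test_percent_recruited(self):
        params = single_lung(n=100)
        state = LungState.initial(params, open_mask=np.arange(100) < 74)
        assert percent_recruited(state) == pytest.approx(74.0)


class TestConfigValidation:
    def test_bad_dt(self):
        with pytest.raises(ValueError):
            MechanicsConfig(dt=0.0)

    def test_bad_compartment_params(self):
        with pytest.raises(ValueError):
            CompartmentParams(k=-1.0)
        with pytest.raises(ValueError):
            CompartmentParams(k=0.5, top=10.0, d_close=0.0)


class TestKernelEquivalence:
    """The numba breath kernel must match the reference operations."""

    def test_tidal_breaths_match_reference(self):
        rng = np.random.default_rng(3)
        n = 8
        comps = [CompartmentParams(k=0.4 + 0.1 * rng.random(), k3=2e-3,
                                   p_ext=rng.random(), top=float(t),
                                   d_close=max(float(t) - 6.0, 0.4) if t else 0.0,
                                   r_aw=1.0, tau_c=float(tc))
                 for t, tc in zip([0, 0, 0, 12, 18, 25, 8, 40],
                                  [0, 0, 0, 2, 3, 500, 0.5, 1])]
        params = LungParams.from_compartments(comps)
        peep, dp, ti, ttot, dt = 10.0, 15.0, 1.5, 5.0, 0.01
        n_breaths = 6

        # reference: explicit python stepping
        ref = LungState.initial(params, open_mask=params.top < 1.0)
        for _ in range(n_breaths):
            for s in range(int(ttot / dt)):
                p_aw = peep + dp if s < int(ti / dt) else peep
                # a compartment opening during this step starts flowing on
                # the next step, as in the kernel
                step_mechanics(ref, params, p_aw, dt)
                update_recruitment(ref, params, p_aw, dt)
            update_derecruitment(ref, params)

        # kernel
        state = LungState.initial(params, open_mask=params.top < 1.0)
        nb = n_breaths
        outs = (np.zeros((nb, n)), np.zeros((nb, n), np.bool_),
                np.zeros((nb, n)), np.zeros((nb, n)), np.zeros(nb),
                np.zeros(nb), np.zeros((nb, n)))
        run_breaths(params.k, params.k2, params.k3, params.p_ext, params.top,
                    params.closing, params.r_aw, params.tau_c,
                    state.volume, state.is_open, state.opening_timer,
                    state.max_pressure, peep, dp, ti, ttot, nb, dt, *outs)
        assert np.array_equal(state.is_open, ref.is_open)
        np.testing.assert_allclose(state.volume, ref.volume, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(state.max_pressure, ref.max_pressure,
                                   rtol=1e-8, atol=1e-10)
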