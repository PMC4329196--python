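"""Gas exchange: V/Q balance, perfusion distribution, shunt and Fick."""

import numpy as np
import pytest

from alveosim.blood import make_blood_sample, o2_content
from alveosim.gasexchange import (GasExchangeConfig, MetabolicParams,
                                  NonphysicalBloodState, PerfusionState,
                                  compartment_alveolar_gas, distribute_perfusion,
                                  mix_arterial, shunt_fraction, venous_from_fick)
from alveosim.mechanics import CompartmentParams, LungParams, LungState

MET = MetabolicParams(hb=12.0, co=6.0, vo2=250.0, rq=0.8, fio2=0.21)
VENOUS = make_blood_sample(40.0, 46.0, 12.0)


def uniform_lung(n=10, open_mask=None):
    params = LungParams.from_compartments(
        [CompartmentParams(k=0.5, r_aw=1.0) for _ in range(n)])
    state = LungState.initial(
        params, open_mask=np.ones(n, bool) if open_mask is None else open_mask)
    state.p_alv[:] = 8.0
    return params, state


class TestShuntFraction:
    def test_no_admixture(self):
        assert shunt_fraction(20.0, 20.0, 14.0) == 0.0

    def test_one_third(self):
        assert shunt_fraction(20.0, 18.0, 14.0) == pytest.approx(1.0 / 3.0)

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError):
            shunt_fraction(14.0, 14.0, 14.0)


class TestFick:
    def test_zero_vo2_venous_equals_arterial(self):
        met = MetabolicParams(hb=12.0, co=6.0, vo2=1e-9, rq=0.8, fio2=0.21)
        art = make_blood_sample(95.0, 40.0, 12.0)
        ven = venous_from_fick(art, met)
        assert ven.o2_content == pytest.approx(art.o2_content, abs=1e-6)
        assert ven.co2_content == pytest.approx(art.co2_content, abs=1e-6)

    def test_content_arithmetic(self):
        # CaO2 20, VO2 250, CO 5 -> CvO2 15
        met = MetabolicParams(hb=15.0, co=5.0, vo2=250.0, rq=0.8, fio2=0.21)
        art = make_blood_sample(300.0, 40.0, 15.0)
        ven = venous_from_fick(art, met)
        assert art.o2_content - ven.o2_content == pytest.approx(5.0, abs=1e-9)

    def test_patient_a_av_difference(self):
        # CO 11.1 l/min, VO2 294.3 ml/min -> a-v O2 difference 2.65 ml/dl
        met = MetabolicParams(hb=10.5, co=11.1, vo2=294.3, rq=0.6, fio2=0.8)
        art = make_blood_sample(150.0, 44.0, 10.5)
        ven = venous_from_fick(art, met)
        assert art.o2_content - ven.o2_content == pytest.approx(2.65, abs=0.01)

    def test_nonphysical_state_flagged(self):
        met = MetabolicParams(hb=4.0, co=1.0, vo2=390.0, rq=0.8, fio2=0.21)
        art = make_blood_sample(60.0, 40.0, 4.0)
        with pytest.raises(NonphysicalBloodState):
            venous_from_fick(art, met)


class TestPerfusionDistribution:
    def test_uniform_when_hpv_off(self):
        params, state = uniform_lung(8)
        cfg = GasExchangeConfig(hpv_enabled=False, distension_enabled=False)
        perf = distribute_perfusion(state, params, np.full(8, 100.0), cfg)
        np.testing.assert_allclose(perf.q, 1.0 / 8.0)

    def test_hpv_diverts_from_hypoxic_unit(self):
        params, state = uniform_lung(8)
        cfg = GasExchangeConfig(distension_enabled=False)
        po2 = np.full(8, 120.0)
        po2[0] = 25.0
        perf = distribute_perfusion(state, params, po2, cfg)
        assert perf.q[0] < 1.0 / 8.0

    def test_distension_diverts_from_pressurised_unit(self):
        params, state = uniform_lung(8)
        cfg = GasExchangeConfig(hpv_enabled=False)
        p_alv = np.full(8, 10.0)
        p_alv[0] = 55.0
        perf = distribute_perfusion(state, params, np.full(8, 100.0), cfg,
                                    p_alv_mean=p_alv)
        assert perf.q[0] < 1.0 / 8.0

    def test_flow_fractions_normalised(self):
        params, state = uniform_lung(5)
        perf = distribute_perfusion(state, params, np.full(5, 60.0))
        assert perf.q.sum() == pytest.approx(1.0)

    def test_perfusion_state_validation(self):
        with pytest.raises(ValueError):
            PerfusionState(q=np.array([0.5, 0.6]))


class TestAlveolarGas:
    def test_dead_space_limit(self):
        # V/Q -> infinity: alveolar gas approaches humidified inspired gas
        pao2, paco2 = compartment_alveolar_gas(
            np.array([50000.0]), np.array([0.001]), np.array([True]),
            VENOUS, MET)
        assert pao2[0] == pytest.approx(0.21 * (760 - 47), rel=0.02)
        assert paco2[0] < 5.0

    def test_shunt_limit(self):
        # V/Q -> 0: alveolar gas approaches venous tensions
        pao2, paco2 = compartment_alveolar_gas(
            np.array([1.0]), np.array([3.0]), np.array([True]), VENOUS, MET)
        assert pao2[0] == pytest.approx(VENOUS.po2, abs=3.0)
        assert paco2[0] == pytest.approx(VENOUS.pco2, abs=3.0)

    def test_unventilated_takes_venous(self):
        pao2, paco2 = compartment_alveolar_gas(
            np.array([0.0]), np.array([3.0]), np.array([False]), VENOUS, MET)
        assert pao2[0] == VENOUS.po2 and paco2[0] == VENOUS.pco2

    def test_alveolar_gas_equation_oracle(self):
        # uniform unshunted lung whose venous blood is Fick-consistent:
        # PAO2 = FiO2*(Pb-47) - PACO2/RQ within 2 mmHg
        n = 4
        va = np.full(n, 4200.0 / n)
        q = np.full(n, MET.co / n)
        venous = VENOUS
        for _ in range(40):  # close the arterial-venous loop
            pao2, paco2 = compartment_alveolar_gas(va, q, np.ones(n, bool),
                                                   venous, MET)
            from alveosim.blood import ph_from_pco2, co2_content
            art = make_blood_sample(float(pao2[0]), float(paco2[0]), MET.hb)
            venous = venous_from_fick(art, MET)
        expected = MET.fio2 * (760 - 47) - paco2 / MET.rq
        np.testing.assert_allclose(pao2, expected, atol=2.0)


class TestArterialMixing:
    def test_total_shunt_gives_venous_blood(self):
        params, state = uniform_lung(6, open_mask=np.zeros(6, bool))
        perf = PerfusionState(q=np.full(6, 1.0 / 6.0))
        art = mix_arterial(state, params, perf, VENOUS, MET, np.zeros(6))
        assert art.o2_content == pytest.approx(VENOUS.o2_content, abs=1e-6)
        assert art.po2 == pytest.approx(VENOUS.po2, abs=0.1)

    def test_no_shunt_gives_ideal_blood(self):
        # zero perfusion to collapsed units: arterial = end-capillary ideal
        n = 6
        params, state = uniform_lung(n, open_mask=np.arange(n) < 3)
        q = np.where(np.arange(n) < 3, 1.0 / 3.0, 0.0)
        perf = PerfusionState(q=q)
        va = np.where(np.arange(n) < 3, 1500.0, 0.0)
        art = mix_arterial(state, params, perf, VENOUS, MET, va)
        pao2, _ = compartment_alveolar_gas(va[:3], q[:3] * MET.co,
                                           np.ones(3, bool), VENOUS, MET)
        cc = o2_content(float(pao2.mean()), MET.hb, pco2=40.0)
        assert art.o2_content == pytest.approx(cc, rel=0.02)

    def test_imposed_shunt_recovered_by_berggren_oracle(self):
        # 30% of flow through collapsed units, HPV off: measured venous
        # admixture equals the imposed fraction to <0.5% absolute
        n = 10
        open_mask = np.arange(n) < 7
        params, state = uniform_lung(n, open_mask=open_mask)
        q = np.where(open_mask, 0.7 / 7, 0.3 / 3)
        perf = PerfusionState(q=q)
        va = np.where(open_mask, 5000.0 / 7, 0.0)
        art = mix_arterial(state, params, perf, VENOUS, MET, va)
        pao2, paco2 = compartment_alveolar_gas(va, q * MET.co, open_mask,
                                               VENOUS, MET)
        from alveosim.blood import ph_from_pco2
        cc = o2_content(float(pao2[0]), MET.hb, pco2=float(paco2[0]),
                        ph=ph_from_pco2(float(paco2[0])))
        qs = shunt_fraction(cc, art.o2_content, VENOUS.o2_content)
        assert qs == pytest.approx(0.30, abs=0.005)

    def test_mixture_bound(self):
        # arterial O2 content lies between venous and max end-capillary
        n = 5
        open_mask = np.arange(n) < 4
        params, state = uniform_lung(n, open_mask=open_mask)
        q = np.full(n, 1.0 / n)
        va = np.where(open_mask, 1000.0, 0.0)
        art = mix_arterial(state, params, PerfusionState(q=q), VENOUS, MET, va)
        cc_max = o2_content(MET.fio2 * (760 - 47), MET.hb)
        assert VENOUS.o2_content <= art.o2_content <= cc_max


class TestMetabolicValidation:
    def test_bad_fio2(self):
        with pytest.raises(ValueError):
            MetabolicParams(hb=12, co=6, vo2=250, rq=0.8, fio2=1.2)

    def test_bad_rq(self):
        with pytest.raises(ValueError):
            MetabolicParams(hb=12, co=6, vo2=250, rq=1.5, fio2=0.5)
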