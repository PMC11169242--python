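"""Whole-body engine: homeostasis, gas exchange, transport conservation."""

import numpy as np
import pytest

from naloxsim import EffectChannel, spo2_from_po2
from naloxsim.physiology import CMH2O_TO_MMHG, TRACE_COLUMNS


class TestBaselineHomeostasis:
    def test_undrugged_hour_stays_on_setpoints(self, engine_factory):
        e = engine_factory(dt=0.1)
        rr0, po20, pco20 = e.RR, e.P_O2, e.P_CO2
        e.run(3600.0, record_interval=10.0)
        df = e.trace.to_dataframe()
        assert np.max(np.abs(df.RR_per_min / rr0 - 1)) < 0.01
        assert np.max(np.abs(df.PO2_mmHg / po20 - 1)) < 0.01
        assert np.max(np.abs(df.PCO2_mmHg / pco20 - 1)) < 0.01
        assert e.alive

    def test_baseline_values_are_physiologic(self, engine_factory):
        e = engine_factory()
        assert e.RR == pytest.approx(16.0)
        assert e.VT == pytest.approx(0.5)
        assert 95.0 <= e.P_O2 <= 105.0
        assert e.P_CO2 == pytest.approx(40.0)
        assert e.SpO2 >= 0.96


class TestDissociationAndDriver:
    def test_spo2_monotone_in_po2(self):
        grid = np.linspace(1.0, 600.0, 400)
        s = [spo2_from_po2(p) for p in grid]
        assert all(b > a for a, b in zip(s, s[1:]))
        assert spo2_from_po2(0.0) == 0.0

    def test_pressure_conversion_constant(self):
        assert 10.0 * CMH2O_TO_MMHG == pytest.approx(7.35559)

    def test_pressure_floor_collapses_tidal_volume(self, engine_factory):
        # a full-scale driver-pressure depression pushes the target pressure
        # to its floor, where no tidal volume is generated
        e = engine_factory(dt=0.1)
        e.drugs["fentanyl"].props.pd_effects["driver_pressure"] = EffectChannel(
            Emax=1.0, EC50=0.5, eta=1.0
        )
        # silence the chemoreflex so the drug drives the target to its floor
        r = e.patient.reflex
        r.g_c_f = r.g_c_P = r.g_p_f = r.g_p_P = 0.0
        e.give_iv_bolus("fentanyl", 1900.0)
        for _ in range(6000):
            e.step()
        p = e.patient
        assert e.VT <= p.compliance * (p.reflex.P_floor - p.P_thresh) + 1e-6
        assert e.VT == pytest.approx(0.0, abs=1e-6)


class TestGasExchange:
    def test_apnea_desaturates_and_retains_co2(self, engine_factory):
        e = engine_factory(dt=0.1)
        e.patient.VT_max = 0.0  # clamp tidal volume: no alveolar ventilation
        spo2s, pco2s = [], []
        for _ in range(3000):
            e.step()
            spo2s.append(e.SpO2)
            pco2s.append(e.P_CO2)
        assert all(b <= a for a, b in zip(spo2s, spo2s[1:]))
        assert all(b >= a for a, b in zip(pco2s, pco2s[1:]))
        assert spo2s[-1] < spo2s[0]

    def test_inhaled_co2_step_raises_etco2(self, engine_factory):
        e = engine_factory(dt=0.1)
        base = e.EtCO2
        e.set_inhaled_co2(0.03)
        # hold ventilation fixed by silencing feedback and drug channels
        e.patient.reflex.g_c_f = e.patient.reflex.g_c_P = 0.0
        e.patient.reflex.g_p_f = e.patient.reflex.g_p_P = 0.0
        for _ in range(6000):
            e.step()
        assert e.EtCO2 > base + 5.0


class TestTransport:
    def test_no_dosing_keeps_zero_concentrations(self, engine_factory):
        e = engine_factory(dt=0.1)
        e.run(120.0)
        assert e.plasma_concentration("fentanyl") == 0.0
        assert e.plasma_concentration("naloxone") == 0.0

    def test_bolus_mass_is_conserved(self, engine_factory):
        e = engine_factory(dt=0.1)
        e.give_iv_bolus("fentanyl", 500.0)
        for _ in range(6000):
            e.step()
        assert e.total_mass("fentanyl") == pytest.approx(500.0, rel=1e-6)
        assert e.drugs["fentanyl"].cleared > 0.0

    def test_mass_conservation_under_random_dosing(self, engine_factory, rng):
        for _ in range(5):
            e = engine_factory(dt=0.1)
            admin = {"fentanyl": 0.0, "naloxone": 0.0}
            for _ in range(4):
                drug = str(rng.choice(["fentanyl", "naloxone"]))
                if rng.random() < 0.5:
                    amt = float(rng.uniform(10, 2000))
                    e.give_iv_bolus(drug, amt)
                else:
                    mg = float(rng.uniform(0.5, 4.0))
                    e.give_nasal(drug, mg)
                for _ in range(int(rng.integers(100, 800))):
                    e.step()
            for drug in admin:
                assert e.total_mass(drug) == pytest.approx(
                    e.drugs[drug].administered, rel=1e-6, abs=1e-9
                )

    def test_infusion_delivers_scheduled_mass(self, engine_factory):
        e = engine_factory(dt=0.1)
        e.start_infusion("fentanyl", rate_ug_per_s=1.0, duration_s=300.0)
        e.run(600.0)
        assert e.drugs["fentanyl"].administered == pytest.approx(300.0, rel=1e-3)
        assert e.total_mass("fentanyl") == pytest.approx(
            e.drugs["fentanyl"].administered, rel=1e-6
        )

    def test_bolus_plasma_trace_matches_regression_fixture(self, engine_factory):
        # frozen reference trajectory (0.5 mg bolus, dt = 0.02 s)
        expected = {60: 31.916997, 180: 10.881125, 300: 8.12885, 600: 5.271604}
        e = engine_factory(dt=0.02)
        e.give_iv_bolus("fentanyl", 500.0)
        got = {}
        while e.t < 600.0 + 1e-9:
            e.step()
            for tt in expected:
                if abs(e.t - tt) < 0.011:
                    got[tt] = e.plasma_concentration("fentanyl")
        for tt, ref in expected.items():
            assert got[tt] == pytest.approx(ref, rel=5e-3)


class TestIntegrationConvergence:
    def test_halving_dt_changes_outputs_below_half_percent(self, engine_factory):
        def run(dt):
            e = engine_factory(dt=dt)
            e.give_iv_bolus("fentanyl", 500.0)
            e.run(600.0, record_interval=10.0)
            df = e.trace.to_dataframe()
            return df[["RR_per_min", "SpO2", "fentanyl_plasma_ug_L"]].to_numpy()

        a, b = run(0.1), run(0.05)
        scale = np.maximum(np.abs(b), 1e-3)
        assert np.max(np.abs(a - b) / scale) < 5e-3


class TestDeathCriterion:
    def test_sustained_hypoxaemia_kills(self, engine_factory):
        e = engine_factory(dt=0.1)
        e.patient.VT_max = 0.0  # apnoea
        e.run(3600.0)
        assert not e.alive
        assert e.death_time is not None
        assert any("death" in msg for _, msg in e.events)

    def test_death_freezes_outputs(self, engine_factory):
        e = engine_factory(dt=0.1)
        e.alive = False
        rr, spo2 = e.RR, e.SpO2
        e.step()
        assert (e.RR, e.SpO2) == (rr, spo2)

    def test_healthy_patient_stays_alive(self, engine_factory):
        e = engine_factory(dt=0.1)
        e.run(1800.0)
        assert e.alive


class TestTrace:
    def test_column_contract(self, engine_factory):
        e = engine_factory(dt=0.1)
        e.run(10.0)
        df = e.trace.to_dataframe()
        assert list(df.columns) == TRACE_COLUMNS

    def test_events_recorded(self, engine_factory):
        e = engine_factory(dt=0.1)
        e.give_iv_bolus("fentanyl", 100.0)
        e.record()
        df = e.trace.to_dataframe()
        assert "iv_bolus fentanyl 100 ug" in df.events.iloc[-1]
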