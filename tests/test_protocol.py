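"""Rescue-protocol automaton, sweep statistics and CO2-challenge tests."""

import numpy as np
import pytest

from naloxsim import RescueProtocol, bin_statistics, plateau_onset, run_rescue, ventilation_co2_slope
from naloxsim.protocol import SweepResult, _drift_corrected_slope
import pandas as pd


class ScriptedPhysiology:
    """Mock model whose SpO2 follows a scripted time function."""

    def __init__(self, spo2_fn):
        self.t = 0.0
        self.spo2_fn = spo2_fn
        self.alive = True
        self.rr = 16.0
        self.boluses = []
        self.nasal_doses = []
        self.events = []

    @property
    def spo2(self):
        return self.spo2_fn(self.t)

    def give_iv_bolus(self, drug, ug):
        self.boluses.append((self.t, drug, ug))

    def give_nasal(self, drug, mg):
        self.nasal_doses.append((self.t, drug, mg))

    def log_event(self, msg):
        self.events.append((self.t, msg))

    def step(self, dt):
        self.t += dt


class TestRescueAutomaton:
    def test_two_failed_checks_hand_trace(self):
        # SpO2 scripted below threshold at exactly the first two checks after
        # the initial dose (170 s, 220 s), then above for >= 600 s:
        # hand-traced total = 3 doses = 6 mg
        rec = run_rescue(
            ScriptedPhysiology(lambda t: 0.80 if t < 225.0 else 0.95),
            fentanyl_mg=1.0,
        )
        assert rec.n_doses == 3
        assert rec.total_naloxone_mg == pytest.approx(6.0)
        assert rec.rescued and not rec.died and not rec.capped
        assert [round(t) for t in rec.dose_times] == [120, 170, 220]

    def test_never_below_threshold_gives_single_dose(self):
        rec = run_rescue(ScriptedPhysiology(lambda t: 0.97), fentanyl_mg=0.2)
        assert rec.total_naloxone_mg == pytest.approx(2.0)
        assert rec.rescued
        # rescued exactly rescued_window after the initial dose

    def test_total_equals_dose_times_one_plus_failed_checks(self):
        for cutoff, failed in [(175.0, 1), (330.0, 4), (121.0, 0)]:
            rec = run_rescue(
                ScriptedPhysiology(lambda t, c=cutoff: 0.5 if t < c else 0.99),
                fentanyl_mg=1.0,
            )
            assert rec.total_naloxone_mg == pytest.approx(2.0 * (1 + failed))

    def test_safety_cap_terminates_with_flag(self):
        rec = run_rescue(
            ScriptedPhysiology(lambda t: 0.5),
            fentanyl_mg=1.0,
            protocol=RescueProtocol(max_total_mg=6.0),
        )
        assert rec.capped
        assert rec.total_naloxone_mg <= 6.0

    def test_rescue_clock_resets_on_dip(self):
        # above threshold for 400 s, one dip, then above again: the rescued
        # flag must only be raised 600 s after the dip ends
        def spo2(t):
            if t < 130 or 530 <= t < 540:
                return 0.5
            return 0.95

        rec = run_rescue(ScriptedPhysiology(spo2), fentanyl_mg=1.0)
        assert rec.rescued
        assert rec.events[-1][0] >= 540 + 600 - 1

    def test_protocol_is_reproducible_bit_identically(self, engine_factory):
        def one():
            e = engine_factory(dt=0.1)
            rec = run_rescue(e, 0.7, RescueProtocol(), dt=0.1)
            return rec.dose_times, [(t, m) for t, m in rec.events], rec.total_naloxone_mg

        assert one() == one()

    def test_validation(self):
        with pytest.raises(Exception):
            RescueProtocol(spo2_threshold=1.5)
        with pytest.raises(Exception):
            run_rescue(ScriptedPhysiology(lambda t: 1.0), fentanyl_mg=0.0)


class TestBinStatistics:
    def make_result(self, totals):
        doses = [round(0.2 + 0.1 * i, 1) for i in range(len(totals))]
        return SweepResult(records=pd.DataFrame(
            {"fentanyl_mg": doses, "total_naloxone_mg": totals}
        ))

    def test_identical_bins_give_p_one(self):
        res = self.make_result([4.0] * 18)
        with pytest.warns(UserWarning):
            bin_statistics(res)
        assert res.p_values == [1.0, 1.0]

    def test_welch_t_against_independent_oracle(self):
        # frozen from R: t.test(c(2,2,2,2,2,2), c(4,4,4,4,4,6)) ->
        # t = -7, df = 5, p = 0.000916747514
        res = self.make_result([2, 2, 2, 2, 2, 2, 4, 4, 4, 4, 4, 6, 8, 8, 8, 8, 8, 8])
        bin_statistics(res)
        assert res.p_values[0] == pytest.approx(0.000916747514, rel=1e-6)
        assert res.bins["mean"].tolist() == pytest.approx([2.0, 13 / 3, 8.0])
        assert res.bins["sd"].iloc[0] == 0.0

    def test_bin_partition_shape(self):
        res = self.make_result(list(range(18)))
        bin_statistics(res)
        assert len(res.bins) == 3
        assert res.bins["n"].tolist() == [6, 6, 6]
        assert len(res.p_values) == 2


class TestPlateauOnset:
    @pytest.mark.parametrize(
        "totals,expected",
        [
            ([2, 2, 4, 6, 6, 6], 0.5),     # last strict increase into 0.5
            ([2, 2, 2, 2, 2, 2], 0.2),     # never increases -> first dose
            ([2, 4, 6, 8, 10, 12], 0.7),   # still rising at the top
        ],
    )
    def test_definition(self, totals, expected):
        doses = [round(0.2 + 0.1 * i, 1) for i in range(len(totals))]
        assert plateau_onset(doses, totals) == pytest.approx(expected)


class TestCO2Slope:
    def test_synthetic_linear_trace(self):
        etco2 = np.linspace(38, 46, 50)
        vent = 2.0 * etco2 + 1.5
        assert ventilation_co2_slope(vent, etco2) == pytest.approx(2.0)

    def test_zero_variance_flagged_as_undefined(self):
        assert ventilation_co2_slope([5.0, 5.0, 5.0], [40.0, 40.0, 40.0]) is None

    def test_silenced_feedback_gives_zero_slope(self):
        # a flat ventilation trace against drifting EtCO2: no CO2 response
        t = np.arange(200.0)
        etco2 = 40 + 0.02 * t + np.sin(t / 9.0)
        vent = np.full_like(t, 1.2)
        assert _drift_corrected_slope(t, vent, etco2) == pytest.approx(0.0, abs=1e-9)

    def test_drift_corrected_slope_recovers_known_gain(self):
        t = np.arange(400.0)
        etco2 = 40 + 3.0 * (t > 200) + 0.01 * t
        vent = 0.8 * etco2 - 0.005 * t + 2.0
        assert _drift_corrected_slope(t, vent, etco2) == pytest.approx(0.8, rel=1e-6)
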