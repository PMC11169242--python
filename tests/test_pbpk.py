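"""Partition-coefficient, perfusion-flux and clearance unit tests."""

import math

import numpy as np
import pytest
import sympy as sp

from naloxsim import (
    ConfigurationError,
    DomainError,
    DrugProperties,
    PlasmaEnvironment,
    TissueCompartment,
    clearance_mass_step,
    compute_xy,
    hepatic_clearance,
    partition_coefficient,
    perfusion_flux,
)
from naloxsim.fixtures import default_fentanyl, default_tissues


def make_tissue(**kw):
    base = dict(name="t", f_EW=0.2, f_IW=0.5, f_NL=0.05, f_NP=0.01,
                AP_conc=1.0, pH_IW=7.0, volume=1.0, Q_B=1.0)
    base.update(kw)
    return TissueCompartment(**base)


class TestComputeXY:
    @pytest.mark.parametrize(
        "cls,pKa,pH_IW,pH_P,expected",
        [
            ("neutral", None, 7.0, 7.4, (1.0, 1.0)),
            ("acid", 7.0, 7.0, 7.0, (2.0, 2.0)),
            ("weak_base", 8.0, 7.0, 7.4, (11.0, 1.0 + 10**0.6)),
            # strong bases follow the weak-base ionisation form
            ("strong_base", 8.0, 7.0, 7.4, (11.0, 1.0 + 10**0.6)),
        ],
    )
    def test_case_table(self, cls, pKa, pH_IW, pH_P, expected):
        X, Y = compute_xy(cls, pKa, pH_IW, pH_P)
        assert X == pytest.approx(expected[0], rel=1e-12)
        assert Y == pytest.approx(expected[1], rel=1e-12)

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_xy("gas", 7.0, 7.0, 7.4)

    def test_missing_pka_rejected(self):
        with pytest.raises(DomainError):
            compute_xy("acid", None, 7.0, 7.4)


class TestPartitionCoefficient:
    def test_pure_extracellular_water_collapses_to_unity(self):
        drug = DrugProperties(name="x", drug_class="neutral", logP=0.0, f_u=1.0, gamma_BP=1.0)
        t = make_tissue(f_EW=1.0, f_IW=0.0, f_NL=0.0, f_NP=0.0)
        assert partition_coefficient(drug, t, PlasmaEnvironment()) == pytest.approx(1.0)

    def test_pure_lipid_gives_p(self):
        drug = DrugProperties(name="x", drug_class="neutral", logP=math.log10(2.0),
                              f_u=1.0, gamma_BP=1.0)
        t = make_tissue(f_EW=0.0, f_IW=0.0, f_NL=1.0, f_NP=0.0)
        assert partition_coefficient(drug, t, PlasmaEnvironment()) == pytest.approx(2.0)

    def test_strong_base_matches_symbolic_substitution(self):
        # frozen from an independent exact-rational sympy substitution of the
        # strong-base branch with the fixture fentanyl/brain parameters
        drug = default_fentanyl()
        brain = default_tissues()["brain"]
        k = partition_coefficient(drug, brain, PlasmaEnvironment())
        assert k == pytest.approx(1.463182163927665, rel=1e-12)

    def test_strong_base_symbolic_oracle_regenerates(self):
        # regenerate the oracle symbolically so the frozen constant cannot rot
        f_u, g, fEW, fIW, fNL, fNP, AP, Ka, P, pKa, pHiw, pHp = sp.symbols(
            "f_u g fEW fIW fNL fNP AP Ka P pKa pHiw pHp"
        )
        X = 1 + 10 ** (pKa - pHiw)
        Y = 1 + 10 ** (pKa - pHp)
        K = f_u / g * (
            fEW + X / Y * fIW + Ka * AP * 10 ** (pKa - pHiw) / Y
            + (P * fNL + (sp.Rational(3, 10) * P - sp.Rational(7, 10)) * fNP) / Y
        )
        vals = {
            f_u: sp.Rational(16, 100), g: 1, fEW: sp.Rational(162, 1000),
            fIW: sp.Rational(620, 1000), fNL: sp.Rational(39, 1000),
            fNP: sp.Rational(15, 10000), AP: sp.Rational(4, 10), Ka: 2,
            P: 10 ** sp.Rational(32, 10), pKa: sp.Rational(84, 10),
            pHiw: 7, pHp: sp.Rational(74, 10),
        }
        assert float(K.subs(vals)) == pytest.approx(1.463182163927665, rel=1e-14)

    def test_acid_branch_collapses_when_ph_equal(self):
        # with pH_IW == pH_P the ionisation ratio X/Y is exactly 1 and the
        # acid/weak-base branch reduces to the f-weighted sum
        drug = DrugProperties(name="a", drug_class="acid", pKa_acid=4.5, logP=1.0,
                              f_u=0.5, gamma_BP=1.0, K_bind=0.0)
        t = make_tissue(pH_IW=7.4)
        env = PlasmaEnvironment(pH_P=7.4)
        k = partition_coefficient(drug, t, env)
        P = drug.P
        lipid = (P * t.f_NL + (0.3 * P - 0.7) * t.f_NP) / compute_xy("acid", 4.5, 7.4, 7.4)[1]
        expected = drug.f_u * (t.f_EW + 1.0 * t.f_IW + lipid)
        assert k == pytest.approx(expected, rel=1e-12)

    def test_zwitterion_branch_runs(self):
        drug = DrugProperties(name="z", drug_class="zwitterion", pKa_acid=9.5,
                              pKa_base=9.0, logP=1.0, f_u=0.5, gamma_BP=1.0, Ka_AP=1.0)
        k = partition_coefficient(drug, make_tissue(), PlasmaEnvironment())
        assert k > 0

    def test_negative_inner_raises_domain_error(self):
        # the literally-printed zwitterion correction can turn the sum negative
        drug = DrugProperties(name="z", drug_class="zwitterion", pKa_acid=1.0,
                              pKa_base=2.0, logP=-3.0, f_u=1.0, gamma_BP=1.0, Ka_AP=0.0)
        with pytest.raises(DomainError):
            partition_coefficient(drug, make_tissue(f_EW=0.01, f_IW=0.0), PlasmaEnvironment())


class TestPerfusionFlux:
    def test_equilibrium_is_zero(self):
        assert perfusion_flux(1.0, 0.5, 1.0, 2.0) == pytest.approx(0.0)

    def test_no_flow_is_zero(self):
        assert perfusion_flux(0.0, 2.0, 1.0, 2.0) == 0.0

    def test_arithmetic(self):
        assert perfusion_flux(0.01, 2.0, 1.0, 2.0) == pytest.approx(0.015)

    def test_invalid_k_tb(self):
        with pytest.raises(DomainError):
            perfusion_flux(1.0, 1.0, 1.0, 0.0)


class TestHepaticClearance:
    def test_flow_limited_ceiling(self):
        assert hepatic_clearance(1.5, 1.0, 1e9) == pytest.approx(1.5, rel=1e-6)

    def test_half_flow_symmetry(self):
        assert hepatic_clearance(1.5, 0.5, 3.0) == pytest.approx(0.75)

    def test_arithmetic(self):
        assert hepatic_clearance(90.0, 0.2, 50.0) == pytest.approx(9.0)

    def test_monotone_and_bounded(self, rng):
        for _ in range(200):
            q = rng.uniform(0.1, 10)
            fu = rng.uniform(0.01, 1.0)
            cli = rng.uniform(0.0, 50)
            base = hepatic_clearance(q, fu, cli)
            assert base < q
            assert hepatic_clearance(q, fu, cli * 1.5) > base or cli == 0
            assert hepatic_clearance(q, min(1.0, fu * 1.2), cli) >= base


class TestClearanceMassStep:
    def test_zero_concentration(self):
        assert clearance_mass_step(70, 0.001, 0.0, 60) == 0.0

    def test_arithmetic(self):
        # 70 kg, 1 mL/min/kg, 1 ug/mL, one minute
        assert clearance_mass_step(70, 0.001, 1000.0, 1.0) == pytest.approx(70.0)

    def test_clamped_at_available(self):
        assert clearance_mass_step(70, 0.001, 1000.0, 1.0, available=5.0) == 5.0


class TestTwoCompartmentEquilibration:
    def test_converges_to_partition_ratio(self):
        # closed blood/tissue pair exchanging by perfusion-limited flux must
        # equilibrate at C_T / C_B = K_TB
        Q, V_B, V_T, K = 1.0, 1.0, 2.0, 3.0
        m_B, m_T = 10.0, 0.0
        dt = 1e-3
        rate = Q * (1 / V_B + 1 / (V_T * K))
        horizon = 100 * math.log(2) / rate
        for _ in range(int(horizon / dt)):
            f = perfusion_flux(Q, m_B / V_B, m_T / V_T, K)
            m_B -= dt * f
            m_T += dt * f
        assert (m_T / V_T) / (m_B / V_B) == pytest.approx(K, rel=1e-3)
        assert m_B + m_T == pytest.approx(10.0, rel=1e-9)


class TestValidation:
    def test_fu_out_of_range(self):
        with pytest.raises(ConfigurationError):
            DrugProperties(name="x", drug_class="neutral", logP=0, f_u=0.0, gamma_BP=1.0)

    def test_neutral_must_not_set_pka(self):
        with pytest.raises(ConfigurationError):
            DrugProperties(name="x", drug_class="neutral", logP=0, f_u=0.5,
                           gamma_BP=1.0, pKa_base=8.0)

    def test_base_requires_pka(self):
        with pytest.raises(ConfigurationError):
            DrugProperties(name="x", drug_class="weak_base", logP=0, f_u=0.5, gamma_BP=1.0)

    def test_tissue_fraction_sum(self):
        with pytest.raises(ConfigurationError):
            make_tissue(f_EW=0.6, f_IW=0.6)
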