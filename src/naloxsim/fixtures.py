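"""Built-in default parameter sets: the 70 kg virtual patient, fentanyl and
naloxone property files, and nasal spray rate constants.

Tissue compositions follow standard literature PBPK composition tables
(water / neutral-lipid / phospholipid fractions and acidic-phospholipid
content per tissue); organ blood flows are textbook fractions of a 5.6 L/min
resting cardiac output.  Drug physiochemistry is literature-sourced;
pharmacodynamic parameters (EC50, Hill exponents, effect-site rates, the
naloxone inhibition constant) and the nasal rate constants were set by the
shipped calibration script (scripts/calibrate.py) against the package's
respiratory anchors: resting rate 16/min, a 2/min floor under receptor
saturation, an unrescued survival boundary at a 1.5 mg bolus, and the
rescue-sweep plateau.  Everything here is plain data and can be exported to
editable JSON with :func:`generate_fixtures`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

from .chemoreflex import ChemoreflexParams
from .nasal import NasalRateConstants
from .pbpk import DrugProperties, EffectChannel, PlasmaEnvironment, TissueCompartment
from .physiology import Engine, Patient

# name: (volume L, Q_B L/min, f_EW, f_IW, f_NL, f_NP, AP mg/g, pH_IW)
_TISSUE_TABLE = {
    "lung":   (0.5,  0.0,   0.336, 0.446, 0.022, 0.013, 3.91, 7.0),
    "brain":  (1.45, 0.672, 0.162, 0.620, 0.039, 0.0015, 0.40, 7.0),
    "liver":  (1.8,  0.364, 0.161, 0.573, 0.014, 0.024, 4.56, 7.0),
    "kidney": (0.31, 1.064, 0.273, 0.483, 0.012, 0.024, 5.03, 7.0),
    "gut":    (1.1,  1.176, 0.282, 0.475, 0.038, 0.012, 2.41, 7.0),
    "muscle": (29.0, 1.300, 0.118, 0.630, 0.022, 0.0072, 1.53, 7.0),
    "fat":    (13.0, 0.280, 0.135, 0.017, 0.790, 0.002, 0.40, 7.0),
    "skin":   (3.4,  0.280, 0.382, 0.291, 0.060, 0.0044, 1.32, 7.0),
    "rest":   (10.0, 0.464, 0.300, 0.450, 0.050, 0.010, 2.00, 7.0),
}

SWEEP_DOSES_MG = [round(0.2 + 0.1 * i, 1) for i in range(18)]  # 0.2 .. 1.9

#: branded nasal spray formulation; the volume is metadata only -- the
#: kinetics depend solely on the deposited mass
NARCAN_SPRAY = {"dose_mg": 2.0, "volume_mL": 0.1}


def default_tissues() -> Dict[str, TissueCompartment]:
    out = {}
    for name, (vol, q, f_ew, f_iw, f_nl, f_np, ap, ph) in _TISSUE_TABLE.items():
        out[name] = TissueCompartment(
            name=name, f_EW=f_ew, f_IW=f_iw, f_NL=f_nl, f_NP=f_np,
            AP_conc=ap, pH_IW=ph, volume=vol, Q_B=q,
        )
    return out


def default_fentanyl() -> DrugProperties:
    """Fentanyl: lipophilic strong base, hepatically cleared mu agonist.

    The effective logP is scaled toward the vegetable-oil lipophilicity used
    for neutral-lipid partitioning, keeping the whole-body distribution
    volume in the literature range (~300 L).
    """
    return DrugProperties(
        name="fentanyl",
        drug_class="strong_base",
        pKa_base=8.4,
        logP=3.2,
        f_u=0.16,
        gamma_BP=1.0,
        Ka_AP=2.0,
        Cl_I=0.149,     # L/min/kg intrinsic -> ~0.8 L/min hepatic
        Cl_renal=0.0,
        k_e=0.005,      # 1/s, effect-site equilibration ~3.3 min
        k_i=0.0,
        pd_effects={
            "respiration_rate": EffectChannel(Emax=0.875, EC50=4.0, eta=2.6),
            "driver_pressure": EffectChannel(Emax=0.5, EC50=4.0, eta=1.6),
            "cns": EffectChannel(Emax=1.0, EC50=8.0, eta=3.0),
        },
    )


def default_naloxone() -> DrugProperties:
    """Naloxone: pure competitive mu antagonist, no intrinsic effect channels."""
    return DrugProperties(
        name="naloxone",
        drug_class="weak_base",
        pKa_base=7.9,
        logP=2.1,
        f_u=0.59,
        gamma_BP=1.22,
        Cl_I=0.5,       # near flow-limited hepatic extraction
        Cl_renal=0.0,
        k_e=0.008,      # 1/s, fast central equilibration
        k_i=0.85,       # ug/L inhibition constant in the competitive model
        pd_effects={},
    )


def default_nasal_rates() -> NasalRateConstants:
    """Rate constants (1/s) for the 2 mg nasal spray.

    Fitted so the simulated 2 mg venous concentration peaks between 15 and
    40 minutes with roughly half the dose reaching systemic circulation.
    """
    return NasalRateConstants(
        k1=0.002, k2=0.0018, k3=0.0015, k4=0.0002, k5=0.001,
        k6=0.002, k7=0.0005, k8=0.0028, k9=0.0005, k10=0.0003,
        k11=0.0001, k12=0.0001, k13=0.0005, k14=0.0005, k15=0.0005,
    )


def default_reflex() -> ChemoreflexParams:
    return ChemoreflexParams()


def default_patient() -> Patient:
    return Patient(tissues=default_tissues(), env=PlasmaEnvironment(),
                   reflex=default_reflex())


def make_engine(dt: float = 0.02, **overrides) -> Engine:
    """Canonical engine: default patient + fentanyl + naloxone + spray rates."""
    return Engine(
        patient=overrides.pop("patient", default_patient()),
        drugs={"fentanyl": default_fentanyl(), "naloxone": default_naloxone()},
        nasal_rates=overrides.pop("nasal_rates", default_nasal_rates()),
        dt=dt,
        **overrides,
    )


# --------------------------------------------------------------- JSON export

def _drug_to_dict(d: DrugProperties) -> dict:
    return {
        "name": d.name,
        "drug_class": d.drug_class,
        "pKa_acid": d.pKa_acid,
        "pKa_base": d.pKa_base,
        "logP": d.logP,
        "f_u": d.f_u,
        "gamma_BP": d.gamma_BP,
        "K_bind": d.K_bind,
        "Ka_AP": d.Ka_AP,
        "Cl_I": d.Cl_I,
        "Cl_renal": d.Cl_renal,
        "k_e": d.k_e,
        "k_i": d.k_i,
        "pd_effects": {
            name: {"Emax": c.Emax, "EC50": c.EC50, "eta": c.eta}
            for name, c in d.pd_effects.items()
        },
    }


def _patient_to_dict(p: Patient) -> dict:
    r = p.reflex
    return {
        "BW": p.BW,
        "cardiac_output": p.cardiac_output,
        "V_art": p.V_art,
        "V_ven": p.V_ven,
        "tissues": {
            n: {
                "volume": t.volume, "Q_B": t.Q_B, "f_EW": t.f_EW, "f_IW": t.f_IW,
                "f_NL": t.f_NL, "f_NP": t.f_NP, "AP_conc": t.AP_conc, "pH_IW": t.pH_IW,
            }
            for n, t in p.tissues.items()
        },
        "env": {"pH_P": p.env.pH_P, "BW": p.env.BW, "Q_H": p.env.Q_H},
        "reflex": {
            "tau_E_c": r.tau_E_c, "tau_E_p": r.tau_E_p, "tau_f": r.tau_f,
            "g_c_f": r.g_c_f, "g_p_f": r.g_p_f, "g_c_P": r.g_c_P, "g_p_P": r.g_p_P,
            "f_max": r.f_max, "f_min": r.f_min, "P_O2_half": r.P_O2_half,
            "k_O2": r.k_O2, "K": r.K, "gamma_tune": r.gamma_tune,
            "P_CO2_set": r.P_CO2_set, "f_set": r.f_set, "A_set": r.A_set,
            "f_base": r.f_base, "P_max_base": r.P_max_base,
            "cns_slope": r.cns_slope, "f_floor": r.f_floor, "P_floor": r.P_floor,
        },
        "dead_space": p.dead_space, "compliance": p.compliance,
        "P_thresh": p.P_thresh, "VT_max": p.VT_max,
        "tau_rr": p.tau_rr, "tau_vt": p.tau_vt,
        "P_B": p.P_B, "FiO2": p.FiO2, "FiCO2": p.FiCO2,
        "VO2": p.VO2, "VCO2": p.VCO2,
        "V_store_O2": p.V_store_O2, "V_store_CO2": p.V_store_CO2,
        "hill_n": p.hill_n, "P50": p.P50, "AaG": p.AaG, "etco2_gap": p.etco2_gap,
        "death_spo2_threshold": p.death_spo2_threshold,
        "death_duration_s": p.death_duration_s,
    }


#: the four literature dosing scenarios used for fentanyl profile checks
TABLE_SCENARIOS = {
    "scenario_infusion_100ug": [
        {"time_s": 0, "route": "iv_infusion", "drug": "fentanyl",
         "concentration_ug_mL": 50.0, "rate_mL_min": 0.4, "duration_s": 300}
    ],
    "scenario_bolus_200ug": [
        {"time_s": 120, "route": "iv_bolus", "drug": "fentanyl", "amount_ug": 200.0}
    ],
    "scenario_infusion_5ugkg": [
        {"time_s": 0, "route": "iv_infusion", "drug": "fentanyl",
         "concentration_ug_mL": 50.0, "rate_mL_min": 0.7, "duration_s": 600}
    ],
    "scenario_bolus_500ug": [
        {"time_s": 0, "route": "iv_bolus", "drug": "fentanyl", "amount_ug": 500.0}
    ],
}


def _dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def generate_fixtures(outdir) -> list:
    """Write the default parameter files as editable JSON; deterministic bytes.

    Produces the patient file, both drug files, the nasal rate-constant set,
    the four literature dosing scenarios and the rescue-sweep configuration.
    Returns the list of written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def w(name: str, obj: dict) -> None:
        p = out / name
        _dump(obj, p)
        written.append(p)

    w("patient.json", _patient_to_dict(default_patient()))
    w("fentanyl.json", _drug_to_dict(default_fentanyl()))
    w("naloxone.json", _drug_to_dict(default_naloxone()))
    w("nasal_rates.json", default_nasal_rates().to_dict())
    for name, events in TABLE_SCENARIOS.items():
        w(name + ".json", {"events": events, "horizon_s": 7200})
    w("rescue_sweep.json", {
        "doses_mg": SWEEP_DOSES_MG,
        "spray": dict(NARCAN_SPRAY),
        "protocol": {
            "transit_delay": 120.0, "dose_mg": 2.0, "check_interval": 50.0,
            "spo2_threshold": 0.85, "rescued_window": 600.0, "max_total_mg": 40.0,
        },
    })
    return written
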