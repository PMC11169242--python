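"""Reduced lumped-parameter whole-body physiology engine.

Replaces a full electrical-circuit cardiopulmonary solver with the smallest
system that preserves the behaviour the rescue analysis reads out:

* a flow-limited PBPK circulation (arterial pool -> organs -> venous pool ->
  lung -> arterial pool, with the gut draining through the liver so hepatic
  clearance sees portal inflow);
* effect-site kinetics and competitive agonist/antagonist pharmacodynamics
  acting on the respiratory driver and the CNS modifier nu;
* chemoreceptor feedback (central CO2, peripheral O2/CO2 firing) attenuated
  by nu;
* a surrogate gas-exchange layer: lumped O2/CO2 stores driven by alveolar
  ventilation, a Hill-type oxyhaemoglobin dissociation curve for SpO2, and a
  fixed alveolar-arterial O2 gradient;
* a sustained-hypoxaemia death criterion.

Integration is fixed-step: explicit Euler for the slow transport/gas states
and exact-exponential relaxation updates for the first-order effect-site,
firing, effector and driver states (exact for inputs frozen over a step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import chemoreflex as chx
from . import effect as fx
from . import nasal as nz
from .errors import ConfigurationError
from .pbpk import (
    DrugProperties,
    PlasmaEnvironment,
    TissueCompartment,
    hepatic_clearance,
    partition_coefficient,
)

CMH2O_TO_MMHG = 0.735559

#: fixed column order of the trace CSV contract
TRACE_COLUMNS = [
    "time_s",
    "fentanyl_plasma_ug_L",
    "naloxone_plasma_ug_L",
    "Ce_fentanyl",
    "Ce_naloxone",
    "nu",
    "RR_per_min",
    "Vt_L",
    "SpO2",
    "PO2_mmHg",
    "PCO2_mmHg",
    "EtCO2_mmHg",
    "events",
]

ORGAN_ORDER = ["lung", "brain", "liver", "kidney", "gut", "muscle", "fat", "skin", "rest"]


@dataclass
class Patient:
    """Virtual-patient parameters: anthropometry, flows, lungs, gas exchange.

    Organ blood flows live on the ``tissues`` entries (L/min); the non-lung
    flows must sum to ``cardiac_output`` (lung perfusion is the full cardiac
    output in series).  ``VCO2`` may be None, in which case metabolic CO2
    production is solved so the chemoreflex CO2 set point is the exact
    resting equilibrium of the ventilation produced by the baseline driver.
    """

    BW: float = 70.0
    cardiac_output: float = 5.6  # L/min
    V_art: float = 1.5  # L
    V_ven: float = 3.5  # L
    tissues: Dict[str, TissueCompartment] = field(default_factory=dict)
    env: PlasmaEnvironment = field(default_factory=PlasmaEnvironment)
    reflex: chx.ChemoreflexParams = field(default_factory=chx.ChemoreflexParams)
    # respiratory driver
    dead_space: float = 0.15  # L
    compliance: float = 0.05  # L per cmH2O of driver pressure above threshold
    P_thresh: float = 3.0  # cmH2O, pressure floor below which no tidal volume
    VT_max: float = 3.0  # L, vital-capacity bound
    tau_rr: float = 8.0  # s, rate-tracking time constant
    tau_vt: float = 8.0  # s
    # gas exchange surrogate
    P_B: float = 760.0  # mmHg barometric
    FiO2: float = 0.2095
    FiCO2: float = 0.0004
    VO2: float = 0.25  # L/min O2 consumption at full saturation
    VCO2: Optional[float] = None  # L/min, None -> solved at equilibrium
    V_store_O2: float = 10.0  # L, effective O2 store (lung + blood buffer)
    V_store_CO2: float = 40.0  # L, effective body CO2 store
    hill_n: float = 2.7
    P50: float = 26.8  # mmHg
    AaG: float = 10.0  # mmHg fixed alveolar-arterial O2 gradient
    etco2_gap: float = 2.0  # mmHg end-tidal to arterial offset
    # death criterion (calibration knob, not a clinical claim)
    death_spo2_threshold: float = 0.40
    death_duration_s: float = 872.0

    def __post_init__(self) -> None:
        if self.BW <= 0 or self.cardiac_output <= 0:
            raise ConfigurationError("patient: BW and cardiac_output must be > 0")
        if self.tissues:
            missing = [n for n in ORGAN_ORDER if n not in self.tissues]
            if missing:
                raise ConfigurationError(f"patient: missing tissue compartments {missing}")
            qsum = sum(t.Q_B for n, t in self.tissues.items() if n != "lung")
            if abs(qsum - self.cardiac_output) > 1e-6 * self.cardiac_output:
                raise ConfigurationError(
                    f"patient: organ flows sum to {qsum} L/min but cardiac output "
                    f"is {self.cardiac_output} L/min"
                )

    # -- derived baseline quantities -------------------------------------
    @property
    def VT_base(self) -> float:
        return min(self.VT_max, self.compliance * (self.reflex.P_max_base - self.P_thresh))

    @property
    def VA_base(self) -> float:
        return max(0.0, self.VT_base - self.dead_space) * self.reflex.f_base

    @property
    def P_ICO2(self) -> float:
        return self.FiCO2 * (self.P_B - 47.0)

    @property
    def P_IO2(self) -> float:
        return self.FiO2 * (self.P_B - 47.0)

    def resting_VCO2(self) -> float:
        """Metabolic CO2 production consistent with the CO2 set point."""
        if self.VCO2 is not None:
            return self.VCO2
        return self.VA_base * (self.reflex.P_CO2_set - self.P_ICO2) / 863.0

    def resting_P_O2(self) -> float:
        return self.P_IO2 - self.AaG - 863.0 * self.VO2 / self.VA_base


@dataclass
class PatientState:
    """Snapshot of the externally visible physiological state."""

    time_s: float
    respiration_rate: float
    tidal_volume: float
    P_O2: float
    P_CO2: float
    EtCO2: float
    SpO2: float
    FiO2: float
    FiCO2: float
    alive: bool


class SimulationTrace:
    """Time-indexed record with the fixed trace-column contract."""

    def __init__(self) -> None:
        self.rows: List[list] = []

    def append(self, row: list) -> None:
        self.rows.append(row)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=TRACE_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.rows)


def spo2_from_po2(P_O2: float, n: float = 2.7, P50: float = 26.8) -> float:
    """Hill-type oxyhaemoglobin dissociation curve, monotone in P_O2."""
    if P_O2 <= 0:
        return 0.0
    r = (P_O2 / P50) ** n
    return r / (1.0 + r)


class _DrugState:
    """Per-drug circulation state: masses (ug) plus precomputed constants."""

    __slots__ = (
        "props", "m_art", "m_ven", "m_tis", "inv_KV", "cleared", "Ce",
        "Cl_H_perkg_Ls", "Cl_renal_perkg_Ls", "administered", "nasal",
        "infusion_rate", "infusion_end",
    )

    def __init__(self, props: DrugProperties, tissues: List[TissueCompartment],
                 env: PlasmaEnvironment) -> None:
        self.props = props
        self.m_art = 0.0
        self.m_ven = 0.0
        self.m_tis = [0.0] * len(tissues)
        self.inv_KV = [
            1.0 / (t.volume * partition_coefficient(props, t, env)) for t in tissues
        ]
        self.cleared = 0.0
        self.Ce = 0.0
        self.Cl_H_perkg_Ls = 0.0  # set by engine (needs liver total inflow)
        self.Cl_renal_perkg_Ls = props.Cl_renal / 60.0 * props.f_u
        self.administered = 0.0
        self.nasal: Optional[nz.NasalState] = None
        self.infusion_rate = 0.0  # ug/s
        self.infusion_end = 0.0


class Engine:
    """Coupled PBPK / PD / chemoreflex / gas-exchange simulator.

    Deterministic fixed-step integration at ``dt`` seconds (default 0.02 s;
    0.1 s changes the reported outputs by well under the 0.5 % convergence
    gate and is used for long batch runs).
    """

    def __init__(
        self,
        patient: Patient,
        drugs: Dict[str, DrugProperties],
        nasal_rates: Optional[nz.NasalRateConstants] = None,
        agonist: str = "fentanyl",
        antagonist: str = "naloxone",
        dt: float = 0.02,
        released_fraction: float = 0.0,
    ) -> None:
        if dt <= 0:
            raise ConfigurationError("Engine: dt must be > 0")
        self.patient = patient
        self.dt = dt
        self.agonist = agonist
        self.antagonist = antagonist
        self.nasal_rates = nasal_rates or nz.NasalRateConstants()
        self.released_fraction = released_fraction

        p = patient
        self._tissue_list = [p.tissues[n] for n in ORGAN_ORDER]
        self._ti = {n: i for i, n in enumerate(ORGAN_ORDER)}
        self._Q_Ls = [t.Q_B / 60.0 for t in self._tissue_list]
        self._Q_Ls[self._ti["lung"]] = p.cardiac_output / 60.0
        self._CO_Ls = p.cardiac_output / 60.0
        self._Q_liver_total_Ls = (
            p.tissues["liver"].Q_B + p.tissues["gut"].Q_B
        ) / 60.0

        self.drugs: Dict[str, _DrugState] = {}
        for name, props in drugs.items():
            ds = _DrugState(props, self._tissue_list, p.env)
            q_lt_perkg_min = self._Q_liver_total_Ls * 60.0 / p.BW
            cl_h_perkg_min = hepatic_clearance(q_lt_perkg_min, props.f_u, props.Cl_I)
            ds.Cl_H_perkg_Ls = cl_h_perkg_min / 60.0
            self.drugs[name] = ds

        # gas / driver state initialised at the resting equilibrium
        self.VCO2 = p.resting_VCO2()
        self.P_O2 = p.resting_P_O2()
        self.P_CO2 = p.reflex.P_CO2_set
        self.FiO2 = p.FiO2
        self.FiCO2 = p.FiCO2
        self.SpO2 = spo2_from_po2(self.P_O2, p.hill_n, p.P50)
        self.EtCO2 = max(0.0, self.P_CO2 - p.etco2_gap)
        self.RR = p.reflex.f_base
        self.VT = p.VT_base
        self.nu = 0.0

        if p.reflex.gamma_tune is None:
            chx.tune_gamma(p.reflex, self.P_O2)
        self.reflex_state = chx.ChemoreflexState(firing=p.reflex.f_set)

        self.t = 0.0
        self.alive = True
        self.death_time: Optional[float] = None
        self._hypox_accum = 0.0
        self.events: List[Tuple[float, str]] = []
        self.trace = SimulationTrace()
        self._pending_events: List[str] = []

    # ------------------------------------------------------------------ dosing
    def log_event(self, msg: str) -> None:
        self.events.append((self.t, msg))
        self._pending_events.append(msg)

    def give_iv_bolus(self, drug: str, amount_ug: float) -> None:
        ds = self.drugs[drug]
        ds.m_ven += amount_ug
        ds.administered += amount_ug
        self.log_event(f"iv_bolus {drug} {amount_ug:g} ug")

    def start_infusion(self, drug: str, rate_ug_per_s: float, duration_s: float) -> None:
        ds = self.drugs[drug]
        ds.infusion_rate = rate_ug_per_s
        ds.infusion_end = self.t + duration_s
        self.log_event(f"iv_infusion {drug} {rate_ug_per_s:g} ug/s for {duration_s:g} s")

    def give_nasal(self, drug: str, dose_mg: float) -> None:
        ds = self.drugs[drug]
        if ds.nasal is None:
            ds.nasal = nz.NasalState()
        nz.administer_spray(ds.nasal, dose_mg, self.released_fraction)
        ds.administered += dose_mg * 1000.0
        self.log_event(f"nasal {drug} {dose_mg:g} mg")

    def set_inhaled_co2(self, FiCO2: float) -> None:
        self.FiCO2 = FiCO2
        self.log_event(f"FiCO2 {FiCO2:g}")

    # ------------------------------------------------------------------ ledger
    def total_mass(self, drug: str) -> float:
        """All drug mass accounted for: circulation + tissue + cleared + nasal."""
        ds = self.drugs[drug]
        m = ds.m_art + ds.m_ven + sum(ds.m_tis) + ds.cleared
        if ds.nasal is not None:
            m += ds.nasal.in_transit() + ds.nasal.cumulative_eliminated
        return m

    def plasma_concentration(self, drug: str) -> float:
        """Venous plasma concentration, ug/L (blood conc / gamma_BP)."""
        ds = self.drugs[drug]
        return ds.m_ven / self.patient.V_ven / ds.props.gamma_BP

    @property
    def state(self) -> PatientState:
        return PatientState(
            self.t, self.RR, self.VT, self.P_O2, self.P_CO2, self.EtCO2,
            self.SpO2, self.FiO2, self.FiCO2, self.alive,
        )

    # ------------------------------------------------------------------ core
    def _circulation_step(self, ds: _DrugState, dt: float) -> None:
        p = self.patient
        ti = self._ti
        Q = self._Q_Ls
        m_tis = ds.m_tis
        inv_KV = ds.inv_KV

        C_art = ds.m_art / p.V_art
        C_ven = ds.m_ven / p.V_ven
        out = [m_tis[i] * inv_KV[i] for i in range(len(m_tis))]

        i_lung, i_liv, i_gut, i_kid = ti["lung"], ti["liver"], ti["gut"], ti["kidney"]
        CO = self._CO_Ls

        # lung sits in series between the venous and arterial pools
        m_tis[i_lung] += dt * CO * (C_ven - out[i_lung])
        ds.m_art += dt * CO * (out[i_lung] - C_art)

        ven_gain = 0.0
        for i in range(len(m_tis)):
            if i in (i_lung, i_liv, i_gut):
                continue
            flux = Q[i] * (C_art - out[i])
            m_tis[i] += dt * flux
            ven_gain += Q[i] * out[i]
        # gut drains through the liver (portal inflow)
        m_tis[i_gut] += dt * Q[i_gut] * (C_art - out[i_gut])
        q_lt = self._Q_liver_total_Ls
        m_tis[i_liv] += dt * (
            Q[i_liv] * C_art + Q[i_gut] * out[i_gut] - q_lt * out[i_liv]
        )
        ven_gain += q_lt * out[i_liv]

        ds.m_ven += dt * (ven_gain - CO * C_ven)

        # nasal systemic input and IV infusion enter the venous pool
        if ds.nasal is not None:
            _, R = nz.nasal_step(ds.nasal, self.nasal_rates, dt)
            ds.m_ven += R * dt
        if ds.infusion_rate > 0.0:
            if self.t < ds.infusion_end:
                ds.m_ven += ds.infusion_rate * dt
                ds.administered += ds.infusion_rate * dt
            else:
                ds.infusion_rate = 0.0

        # hepatic (well-stirred) and renal clearance, clamped non-negative
        m_h = p.BW * ds.Cl_H_perkg_Ls * out[i_liv] * dt
        if m_h > m_tis[i_liv]:
            m_h = m_tis[i_liv]
        m_tis[i_liv] -= m_h
        m_r = p.BW * ds.Cl_renal_perkg_Ls * out[i_kid] * dt
        if m_r > m_tis[i_kid]:
            m_r = m_tis[i_kid]
        m_tis[i_kid] -= m_r
        ds.cleared += m_h + m_r

        # effect site fed by the brain-vascular concentration
        cp = out[ti["brain"]]
        ds.Ce = cp + (ds.Ce - cp) * math.exp(-ds.props.k_e * dt)

    def step(self, dt: Optional[float] = None) -> None:
        """Advance the whole coupled model one time step."""
        if not self.alive:
            # death freezes the physiology; only the clock advances
            self.t += dt if dt is not None else self.dt
            return
        dt = self.dt if dt is None else dt
        p = self.patient

        for ds in self.drugs.values():
            self._circulation_step(ds, dt)

        # pharmacodynamics of the agonist under competitive antagonism
        ag = self.drugs.get(self.agonist)
        an = self.drugs.get(self.antagonist)
        ce = ag.Ce if ag is not None else 0.0
        ci = an.Ce if an is not None else 0.0
        k_i = an.props.k_i if an is not None else 1.0
        d_rr = d_p = 0.0
        nu = 0.0
        if ag is not None:
            chans = ag.props.pd_effects
            if "respiration_rate" in chans:
                c = chans["respiration_rate"]
                d_rr = fx.competitive_effect(ce, ci, p.reflex.f_base, c.Emax, c.EC50, c.eta, k_i)
            if "driver_pressure" in chans:
                c = chans["driver_pressure"]
                d_p = fx.competitive_effect(ce, ci, p.reflex.P_max_base, c.Emax, c.EC50, c.eta, k_i)
            if "cns" in chans:
                nu = fx.cns_modifier(ce, ci, chans["cns"], k_i)
        self.nu = nu

        # chemoreflex: firing, attenuated inputs, effector relaxation
        rp, rs = p.reflex, self.reflex_state
        psi = chx.firing_target(self.P_O2, self.P_CO2, rp)
        rs.firing = psi + (rs.firing - psi) * math.exp(-dt / rp.tau_f)
        A_f = chx.afferent_attenuation(rs.firing, rp.A_set, nu, rp.cns_slope)
        C_f = chx.central_input(self.P_CO2, rp.P_CO2_set, nu, rp.cns_slope)
        chx.effector_step(rs, A_f, C_f, rp, dt)

        # respiratory driver tracks its targets
        f_t, P_t = chx.respiratory_targets(rp, rs, d_rr, d_p)
        self.RR = f_t + (self.RR - f_t) * math.exp(-dt / p.tau_rr)
        vt_t = min(p.VT_max, max(0.0, p.compliance * (P_t - p.P_thresh)))
        self.VT = vt_t + (self.VT - vt_t) * math.exp(-dt / p.tau_vt)

        # surrogate alveolar gas exchange (rates per minute)
        VA = max(0.0, self.VT - p.dead_space) * self.RR
        dtm = dt / 60.0
        P_ICO2 = self.FiCO2 * (p.P_B - 47.0)
        P_IO2 = self.FiO2 * (p.P_B - 47.0)
        self.P_CO2 += dtm * (863.0 * self.VCO2 - VA * (self.P_CO2 - P_ICO2)) / p.V_store_CO2
        vo2_eff = p.VO2 * min(1.0, self.SpO2 / 0.5)
        self.P_O2 += dtm * (VA * (P_IO2 - p.AaG - self.P_O2) - 863.0 * vo2_eff) / p.V_store_O2
        self.P_CO2 = min(700.0, max(1.0, self.P_CO2))
        self.P_O2 = min(700.0, max(1.0, self.P_O2))
        self.SpO2 = spo2_from_po2(self.P_O2, p.hill_n, p.P50)
        self.EtCO2 = max(0.0, self.P_CO2 - p.etco2_gap)

        # sustained-hypoxaemia death criterion
        if self.SpO2 < p.death_spo2_threshold:
            self._hypox_accum += dt
            if self._hypox_accum >= p.death_duration_s:
                self.alive = False
                self.death_time = self.t
                self.log_event("death: sustained SpO2 below threshold")
        else:
            self._hypox_accum = 0.0

        self.t += dt

    def record(self) -> None:
        """Append the current state to the trace (fixed column contract)."""
        f = self.drugs.get(self.agonist)
        n = self.drugs.get(self.antagonist)
        self.trace.append([
            self.t,
            self.plasma_concentration(self.agonist) if f else 0.0,
            self.plasma_concentration(self.antagonist) if n else 0.0,
            f.Ce if f else 0.0,
            n.Ce if n else 0.0,
            self.nu,
            self.RR,
            self.VT,
            self.SpO2,
            self.P_O2,
            self.P_CO2,
            self.EtCO2,
            ";".join(self._pending_events),
        ])
        self._pending_events = []

    # alias used by the rescue protocol's duck-typed model interface
    @property
    def spo2(self) -> float:
        return self.SpO2

    @property
    def rr(self) -> float:
        return self.RR

    def run(
        self,
        horizon_s: float,
        events: Optional[List[dict]] = None,
        record_interval: float = 1.0,
        stop_on_death: bool = True,
    ) -> SimulationTrace:
        """Integrate for ``horizon_s`` seconds applying scheduled dose events.

        ``events`` entries follow the scenario-config schema: dicts with
        ``time_s``, ``route`` (iv_bolus | iv_infusion | nasal), ``drug`` and
        the route's amount fields.  The trace is recorded every
        ``record_interval`` seconds.
        """
        pending = sorted(events or [], key=lambda e: e["time_s"])
        next_rec = 0.0
        self.record()
        next_rec += record_interval
        eps = 1e-9
        while self.t < horizon_s - eps:
            while pending and pending[0]["time_s"] <= self.t + eps:
                self._apply_event(pending.pop(0))
            self.step()
            if self.t + eps >= next_rec:
                self.record()
                next_rec += record_interval
            if stop_on_death and not self.alive:
                self.record()
                break
        return self.trace

    def _apply_event(self, ev: dict) -> None:
        route = ev["route"]
        drug = ev["drug"]
        if route == "iv_bolus":
            self.give_iv_bolus(drug, float(ev["amount_ug"]))
        elif route == "iv_infusion":
            rate_ug_s = float(ev["concentration_ug_mL"]) * float(ev["rate_mL_min"]) / 60.0
            self.start_infusion(drug, rate_ug_s, float(ev["duration_s"]))
        elif route == "nasal":
            self.give_nasal(drug, float(ev["amount_ug"]) / 1000.0)
        else:
            raise ConfigurationError(
                f"unsupported route '{route}' (supported: iv_bolus, iv_infusion, nasal)"
            )
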