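"""Central and peripheral chemoreceptor feedback on the respiratory driver.

Two additive feedback branches adjust the respiratory driver's target
frequency and driver pressure:

* the central branch integrates the arterial CO2 error against its set
  point with gain ``g_E_c`` and time constant ``tau_E_c``;
* the peripheral branch integrates the deviation of the carotid-body firing
  rate from its set point with gain ``g_E_p`` and time constant ``tau_E_p``.
  The firing rate itself relaxes toward a nonlinear target: an O2 sigmoid
  multiplying a logarithmic CO2 term.

Opioid depression enters through the CNS modifier nu in [0, 1]: afferent
firing is pulled toward its set point by the factor exp(-3.5 nu) and the
central CO2 error is scaled by the same factor, so full depression silences
both branches.  Parameter values follow the Ursino/Magosso chemoreflex
modelling tradition, retuned to this package's reduced physiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError, DomainError

_EXP_CLIP = 50.0


def _safe_exp(x: float) -> float:
    return math.exp(max(-_EXP_CLIP, min(_EXP_CLIP, x)))


@dataclass
class ChemoreflexParams:
    """Feedback parameters; time constants in s, pressures in mmHg.

    Gains: ``g_c_f``/``g_p_f`` act on driver frequency (1/min per mmHg and
    per spike/s); ``g_c_P``/``g_p_P`` on driver pressure (cmH2O per mmHg and
    per spike/s).  ``gamma_tune`` offsets the firing target so the baseline
    gas tensions are an exact equilibrium; pass None to have it solved from
    the set points (see :func:`tune_gamma`).
    """

    tau_E_c: float = 105.0
    tau_E_p: float = 20.0
    tau_f: float = 5.0
    g_c_f: float = 0.55
    g_p_f: float = 0.2
    g_c_P: float = 0.25
    g_p_P: float = 2.0
    f_max: float = 12.3
    f_min: float = 0.835
    P_O2_half: float = 45.0
    k_O2: float = 15.0
    K: float = 3.0
    gamma_tune: float | None = None
    P_CO2_set: float = 40.0
    f_set: float = 3.7
    A_set: float | None = None  # defaults to f_set
    f_base: float = 16.0
    P_max_base: float = 13.0
    cns_slope: float = 3.5
    f_floor: float = 2.0
    P_floor: float = 3.0

    def __post_init__(self) -> None:
        for name in ("tau_E_c", "tau_E_p", "tau_f"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"chemoreflex: {name} must be > 0")
        if self.f_min >= self.f_max:
            raise ConfigurationError("chemoreflex: f_min must be < f_max")
        if self.P_CO2_set <= 0:
            raise ConfigurationError("chemoreflex: P_CO2_set must be > 0")
        if self.A_set is None:
            self.A_set = self.f_set


@dataclass
class ChemoreflexState:
    """Effector deltas (frequency: 1/min, pressure: cmH2O) and firing (spikes/s)."""

    dE_c_f: float = 0.0
    dE_c_P: float = 0.0
    dE_p_f: float = 0.0
    dE_p_P: float = 0.0
    firing: float = 0.0


def o2_sigmoid(P_O2: float, params: ChemoreflexParams) -> float:
    """Hypoxia-sensitive prefactor: f_max at low P_O2, f_min at high P_O2."""
    e = _safe_exp((P_O2 - params.P_O2_half) / params.k_O2)
    return (params.f_max + params.f_min * e) / (1.0 + e)


def firing_target(P_O2: float, P_CO2: float, params: ChemoreflexParams) -> float:
    """Steady-state carotid firing psi = sigmoid(P_O2)*[K ln(P_CO2/set) + gamma].

    Clamped at >= 0.  Raises DomainError for non-positive P_CO2.
    """
    if P_CO2 <= 0:
        raise DomainError(f"firing_target: P_CO2 must be > 0, got {P_CO2}")
    if P_O2 <= 0:
        raise DomainError(f"firing_target: P_O2 must be > 0, got {P_O2}")
    if params.gamma_tune is None:
        raise ConfigurationError("gamma_tune is unset; call tune_gamma() first")
    psi = o2_sigmoid(P_O2, params) * (
        params.K * math.log(P_CO2 / params.P_CO2_set) + params.gamma_tune
    )
    return max(0.0, psi)


def tune_gamma(params: ChemoreflexParams, P_O2_base: float) -> float:
    """Solve gamma so the firing target equals f_set at the baseline gases.

    With psi(P_O2_base, P_CO2_set) == f_set the undrugged closed loop has an
    exact equilibrium at the set points.  Sets and returns ``gamma_tune``.
    """
    params.gamma_tune = params.f_set / o2_sigmoid(P_O2_base, params)
    return params.gamma_tune


def peripheral_firing(
    P_O2: float, P_CO2: float, params: ChemoreflexParams, state: ChemoreflexState, dt: float
) -> float:
    """Relax the firing rate toward its nonlinear target over ``dt`` seconds."""
    psi = firing_target(P_O2, P_CO2, params)
    state.firing = psi + (state.firing - psi) * math.exp(-dt / params.tau_f)
    return state.firing


def afferent_attenuation(psi: float, A_set: float, nu: float, slope: float = 3.5) -> float:
    """Opioid-attenuated afferent input A_f = psi e^(-s nu) + A_set (1 - e^(-s nu))."""
    w = _safe_exp(-slope * nu)
    return psi * w + A_set * (1.0 - w)


def central_input(P_CO2: float, P_CO2_set: float, nu: float, slope: float = 3.5) -> float:
    """Opioid-attenuated central CO2 error C_f = (P_CO2 - set) e^(-s nu)."""
    return (P_CO2 - P_CO2_set) * _safe_exp(-slope * nu)


def effector_step(
    state: ChemoreflexState, A_f: float, C_f: float, params: ChemoreflexParams, dt: float
) -> ChemoreflexState:
    """Advance the four effector deltas one step.

    Each delta relaxes first-order toward gain * input (central input C_f,
    peripheral input A_f - f_set) with its branch time constant; the update
    is the exact exponential for inputs frozen over the step.
    """
    ec = math.exp(-dt / params.tau_E_c)
    ep = math.exp(-dt / params.tau_E_p)
    tgt_c_f = params.g_c_f * C_f
    tgt_c_P = params.g_c_P * C_f
    perr = A_f - params.f_set
    tgt_p_f = params.g_p_f * perr
    tgt_p_P = params.g_p_P * perr
    state.dE_c_f = tgt_c_f + (state.dE_c_f - tgt_c_f) * ec
    state.dE_c_P = tgt_c_P + (state.dE_c_P - tgt_c_P) * ec
    state.dE_p_f = tgt_p_f + (state.dE_p_f - tgt_p_f) * ep
    state.dE_p_P = tgt_p_P + (state.dE_p_P - tgt_p_P) * ep
    return state


def respiratory_targets(
    params: ChemoreflexParams,
    state: ChemoreflexState,
    pd_frequency_delta: float = 0.0,
    pd_pressure_delta: float = 0.0,
) -> tuple[float, float]:
    """Driver targets (f_t 1/min, P_max cmH2O): baseline + feedback - drug.

    f_t = f_base + dE_c_f + dE_p_f - pd_frequency_delta, floored at
    ``f_floor``; the pressure target analogously, floored at ``P_floor``.
    The direct pharmacodynamic depression lowers the baseline drive while
    the chemoreflex deltas fight it.
    """
    f_t = params.f_base + state.dE_c_f + state.dE_p_f - pd_frequency_delta
    P_t = params.P_max_base + state.dE_c_P + state.dE_p_P - pd_pressure_delta
    return max(params.f_floor, f_t), max(params.P_floor, P_t)
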