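"""Effect-site kinetics and competitive-antagonist pharmacodynamics.

A hypothetical effect compartment lags the (brain-vascular) plasma
concentration with first-order rate ``k_e``.  The physiological effect of an
agonist at effect-site concentration Ce in the presence of a competitive
antagonist at Ci is a sigmoid Emax model with the apparent EC50 multiplied by
(1 + Ci/ki) -- surmountable antagonism: the antagonist shifts potency but
never the ceiling.
"""

from __future__ import annotations

import math

from .errors import DomainError
from .pbpk import EffectChannel


def effect_site_step(Ce: float, Cp: float, k_e: float, dt: float) -> float:
    """Advance dCe/dt = k_e (Cp - Ce) by ``dt`` with the exact exponential.

    Exact for piecewise-constant Cp over the step, unconditionally stable.
    """
    if k_e <= 0 or dt <= 0:
        raise DomainError("effect_site_step: k_e and dt must be > 0")
    return Cp + (Ce - Cp) * math.exp(-k_e * dt)


def effect_site_step_heun(Ce: float, Cp: float, k_e: float, dt: float) -> float:
    """Heun (improved Euler) variant of the effect-site update.

    Kept as an independent integration route for convergence testing of the
    exact-exponential update.
    """
    if k_e <= 0 or dt <= 0:
        raise DomainError("effect_site_step_heun: k_e and dt must be > 0")
    d1 = k_e * (Cp - Ce)
    d2 = k_e * (Cp - (Ce + dt * d1))
    return Ce + 0.5 * dt * (d1 + d2)


def competitive_effect(
    Ce: float,
    Ci: float,
    Eb: float,
    Emax: float,
    EC50: float,
    eta: float,
    k_i: float,
) -> float:
    """Effect delta of an agonist under competitive antagonism.

        dE = Eb * Emax * Ce^eta / (EC50^eta * (1 + Ci/ki)^eta + Ce^eta)

    ``Eb`` is the baseline the effect scales, ``Ci`` the antagonist
    effect-site concentration and ``k_i`` its inhibition constant.  The
    result is bounded by Eb*Emax for any Ci (surmountable antagonism).
    """
    if EC50 <= 0:
        raise DomainError(f"competitive_effect: EC50 must be > 0, got {EC50}")
    if eta < 1:
        raise DomainError(f"competitive_effect: eta must be >= 1, got {eta}")
    if Ce < 0 or Ci < 0:
        raise DomainError("competitive_effect: concentrations must be >= 0")
    if Ci > 0 and k_i <= 0:
        raise DomainError("competitive_effect: k_i must be > 0 when Ci > 0")
    if Ce == 0.0:
        return 0.0
    shift = 1.0 + (Ci / k_i if k_i > 0 else 0.0)
    ce_eta = Ce**eta
    return Eb * Emax * ce_eta / ((EC50 * shift) ** eta + ce_eta)


def hill_effect(Ce: float, Eb: float, Emax: float, EC50: float, eta: float) -> float:
    """Plain sigmoid Emax (Hill) effect -- the antagonist-free special case."""
    return competitive_effect(Ce, 0.0, Eb, Emax, EC50, eta, k_i=1.0)


def cns_modifier(
    Ce_agonist: float,
    Ci_antagonist: float,
    channel: EffectChannel,
    k_i: float,
) -> float:
    """Central-nervous-system depression modifier nu in [0, 1].

    nu is the competitive-effect output of the agonist's CNS channel with
    unit baseline (so channel.Emax <= 1 bounds nu in [0, 1]).  It increases
    with agonist and decreases with antagonist concentration, and drives the
    exponential attenuation of chemoreceptor afferents.
    """
    if channel.Emax > 1.0:
        raise DomainError(f"cns channel Emax must be <= 1, got {channel.Emax}")
    nu = competitive_effect(
        Ce_agonist, Ci_antagonist, 1.0, channel.Emax, channel.EC50, channel.eta, k_i
    )
    return min(1.0, max(0.0, nu))
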