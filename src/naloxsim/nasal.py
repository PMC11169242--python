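"""Six-compartment intranasal absorption model.

A spray deposits drug in the anterior nasal cavity, partly still suspended in
its carrier solution (upper-case states) and partly released (lower-case
states).  Unreleased drug is carried anterior -> posterior -> gastrointestinal
by mucociliary transport while releasing into the corresponding free pools;
released drug permeates the mucosa into systemic circulation or is lost to
local elimination.  All transfers are first-order with rate constants
k1..k15 (1/s):

    A -> P (k1), A -> a (k2)
    P -> G (k5), P -> p (k6), G -> g (k9), G -> eliminated (k14)
    a -> p (k3), a -> systemic (k4), a -> eliminated (k11)
    p -> g (k7), p -> systemic (k8), p -> eliminated (k12)
    g -> systemic (k10), g -> eliminated (k13 + k15)

The instantaneous systemic input rate is R = k4*a + k8*p + k10*g (ug/s).
The system is linear, so trajectories superpose and scale with dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Tuple

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

_RATE_NAMES = tuple(f"k{i}" for i in range(1, 16))


@dataclass
class NasalRateConstants:
    """First-order rate constants (1/s) of the nasal deposition network.

    The lumped totals alpha..epsilon are derived properties, recomputed from
    the individual constants and never stored independently.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k6: float = 0.0
    k7: float = 0.0
    k8: float = 0.0
    k9: float = 0.0
    k10: float = 0.0
    k11: float = 0.0
    k12: float = 0.0
    k13: float = 0.0
    k14: float = 0.0
    k15: float = 0.0

    def __post_init__(self) -> None:
        for name in _RATE_NAMES:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"nasal rate constant {name} must be >= 0")

    # total outflow rates per compartment
    @property
    def alpha(self) -> float:
        return self.k1 + self.k2

    @property
    def beta(self) -> float:
        return self.k5 + self.k6

    @property
    def gamma(self) -> float:
        return self.k9 + self.k14

    @property
    def delta(self) -> float:
        return self.k3 + self.k4 + self.k11

    @property
    def omega(self) -> float:
        return self.k7 + self.k8 + self.k12

    @property
    def epsilon(self) -> float:
        return self.k10 + self.k13 + self.k15

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "NasalRateConstants":
        unknown = set(d) - set(_RATE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown nasal rate constant(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in _RATE_NAMES}


@dataclass
class NasalState:
    """Drug masses (ug) in the nasal network plus cumulative ledgers.

    A, P, G -- unreleased (carrier-bound) mass in anterior, posterior and
    gastrointestinal compartments; a, p, g -- released mass in the same
    compartments.  ``cumulative_systemic`` and ``cumulative_eliminated``
    close the mass balance against ``total_administered``.
    """

    A: float = 0.0
    P: float = 0.0
    G: float = 0.0
    a: float = 0.0
    p: float = 0.0
    g: float = 0.0
    cumulative_systemic: float = 0.0
    cumulative_eliminated: float = 0.0
    total_administered: float = 0.0

    def in_transit(self) -> float:
        """Mass still inside the nasal/GI network."""
        return self.A + self.P + self.G + self.a + self.p + self.g

    def mass_balance_residual(self) -> float:
        """total administered minus everything accounted for (should be ~0)."""
        return self.total_administered - (
            self.in_transit() + self.cumulative_systemic + self.cumulative_eliminated
        )


def administer_spray(state: NasalState, dose_mg: float, released_fraction: float = 0.0) -> NasalState:
    """Deposit one spray of ``dose_mg`` mg into the anterior compartment.

    ``released_fraction`` of the dose is deposited directly into the released
    anterior pool; the remainder stays carrier-bound.  This hook lets
    different spray formulations / concentrations be emulated.  Mutates and
    returns ``state``.
    """
    if dose_mg <= 0:
        raise ConfigurationError(f"nasal dose must be > 0 mg, got {dose_mg}")
    if not (0.0 <= released_fraction <= 1.0):
        raise ConfigurationError(
            f"released_fraction must be in [0, 1], got {released_fraction}"
        )
    dose_ug = dose_mg * 1000.0
    state.A += dose_ug * (1.0 - released_fraction)
    state.a += dose_ug * released_fraction
    state.total_administered += dose_ug
    return state


def _derivatives(s: Tuple[float, ...], k: NasalRateConstants):
    A, P, G, a, p, g = s
    dA = -k.alpha * A
    dP = k.k1 * A - k.beta * P
    dG = k.k5 * P - k.gamma * G
    da = k.k2 * A - k.delta * a
    dp = k.k6 * P + k.k3 * a - k.omega * p
    dg = k.k9 * G + k.k7 * p - k.epsilon * g
    R = k.k4 * a + k.k8 * p + k.k10 * g
    elim = k.k11 * a + k.k12 * p + (k.k13 + k.k15) * g + k.k14 * G
    return (dA, dP, dG, da, dp, dg), R, elim


def nasal_step(state: NasalState, rates: NasalRateConstants, dt: float) -> Tuple[NasalState, float]:
    """Advance the nasal network by ``dt`` seconds (Heun / improved Euler).

    Returns ``(state, R)`` where R is the systemic input rate (ug/s) averaged
    over the step; ``cumulative_systemic`` and ``cumulative_eliminated`` are
    advanced with the same averaged rates so the mass balance is exact to
    rounding for any dt.  Any negative mass produced by a large step is
    clamped to zero with a logged warning.
    """
    if dt <= 0:
        raise ConfigurationError(f"nasal_step: dt must be > 0, got {dt}")
    y0 = (state.A, state.P, state.G, state.a, state.p, state.g)
    d1, R1, e1 = _derivatives(y0, rates)
    y1 = tuple(y + dt * d for y, d in zip(y0, d1))
    d2, R2, e2 = _derivatives(y1, rates)
    y_new = [y + 0.5 * dt * (da + db) for y, da, db in zip(y0, d1, d2)]
    R = 0.5 * (R1 + R2)
    elim = 0.5 * (e1 + e2)
    clamped = 0.0
    for i, v in enumerate(y_new):
        if v < 0.0:
            clamped += -v
            y_new[i] = 0.0
    if clamped > 1e-12 * max(1.0, state.total_administered):
        logger.warning(
            "nasal_step: clamped %.3g ug of negative mass (dt too large for rates)",
            clamped,
        )
    state.A, state.P, state.G, state.a, state.p, state.g = y_new
    state.cumulative_systemic += R * dt
    # fold clamp residue into elimination so the balance ledger stays closed
    state.cumulative_eliminated += elim * dt - clamped
    return state, R
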