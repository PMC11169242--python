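"""Physiochemical partition coefficients, perfusion-limited exchange and clearance.

The tissue-to-blood partition coefficient ``K_TB`` is computed from a drug's
physiochemical properties (ionisation class, pKa, lipophilicity, plasma
protein binding) and the composition of a lumped tissue (water, neutral
lipid, neutral phospholipid and acidic phospholipid fractions), following the
Rodgers–Rowland family of tissue-composition models, rescaled from plasma to
whole blood by the fraction unbound ``f_u`` and the blood:plasma ratio
``gamma_BP``.

Units convention used throughout the package: mass in ug, volume in L
(so concentrations are ug/L == ng/mL), time in seconds internally; flows and
clearances are stated in L/min in configuration and converted on load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

from .errors import ConfigurationError, DomainError

DRUG_CLASSES = ("acid", "weak_base", "strong_base", "neutral", "zwitterion")


@dataclass
class EffectChannel:
    """One pharmacodynamic effect channel (sigmoid Emax model).

    Emax   -- maximal fractional effect relative to the baseline it scales
    EC50   -- effect-site concentration of half-maximal effect, ug/L
    eta    -- Hill exponent (steepness), >= 1
    """

    Emax: float
    EC50: float
    eta: float = 1.0

    def __post_init__(self) -> None:
        if self.EC50 <= 0:
            raise ConfigurationError(f"EffectChannel.EC50 must be > 0, got {self.EC50}")
        if self.eta < 1:
            raise ConfigurationError(f"EffectChannel.eta must be >= 1, got {self.eta}")


@dataclass
class DrugProperties:
    """Physiochemical and PK/PD parameters for one substance.

    pKa_acid / pKa_base -- set exactly those required by ``drug_class``
    logP                -- effective octanol-water log partition coefficient
    f_u                 -- fraction unbound in plasma, (0, 1]
    gamma_BP            -- blood:plasma concentration ratio, > 0
    K_bind              -- tissue binding constant (acid/neutral/weak-base form)
    Ka_AP               -- association constant for acidic phospholipids
    Cl_I                -- intrinsic hepatic clearance, L/min per kg body weight
    Cl_renal            -- renal clearance, L/min per kg body weight
    k_e                 -- effect-site equilibration rate constant, 1/s
    k_i                 -- antagonist inhibition constant, ug/L (0 if never an
                           antagonist)
    pd_effects          -- effect name -> EffectChannel
    """

    name: str
    drug_class: str
    logP: float
    f_u: float
    gamma_BP: float
    pKa_acid: float | None = None
    pKa_base: float | None = None
    K_bind: float = 0.0
    Ka_AP: float = 0.0
    Cl_I: float = 0.0
    Cl_renal: float = 0.0
    k_e: float = 1e-3
    k_i: float = 0.0
    pd_effects: Dict[str, EffectChannel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise ConfigurationError(
                f"drug '{self.name}': unknown drug_class '{self.drug_class}' "
                f"(supported: {', '.join(DRUG_CLASSES)})"
            )
        if not (0.0 < self.f_u <= 1.0):
            raise ConfigurationError(f"drug '{self.name}': f_u must be in (0, 1], got {self.f_u}")
        if self.gamma_BP <= 0:
            raise ConfigurationError(f"drug '{self.name}': gamma_BP must be > 0")
        if self.K_bind < 0 or self.Ka_AP < 0:
            raise ConfigurationError(f"drug '{self.name}': K_bind and Ka_AP must be >= 0")
        needs_acid = self.drug_class in ("acid", "zwitterion")
        needs_base = self.drug_class in ("weak_base", "strong_base", "zwitterion")
        if needs_acid and self.pKa_acid is None:
            raise ConfigurationError(f"drug '{self.name}': pKa_acid required for class {self.drug_class}")
        if needs_base and self.pKa_base is None:
            raise ConfigurationError(f"drug '{self.name}': pKa_base required for class {self.drug_class}")
        if self.drug_class == "neutral" and (self.pKa_acid is not None or self.pKa_base is not None):
            raise ConfigurationError(f"drug '{self.name}': neutral drugs must not set pKa fields")

    @property
    def P(self) -> float:
        """Octanol-water partition coefficient, 10**logP."""
        return 10.0 ** self.logP


@dataclass
class TissueCompartment:
    """Composition, size and perfusion of one lumped tissue.

    Fractions are volume fractions of total tissue; ``AP_conc`` is the acidic
    phospholipid concentration (mg/g of tissue); ``Q_B`` is blood flow in
    L/min.  ``drug_mass`` maps drug name -> mass (ug) currently in the tissue.
    """

    name: str
    f_EW: float
    f_IW: float
    f_NL: float
    f_NP: float
    AP_conc: float
    pH_IW: float
    volume: float
    Q_B: float
    drug_mass: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fname in ("f_EW", "f_IW", "f_NL", "f_NP"):
            v = getattr(self, fname)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"tissue '{self.name}': {fname} must be in [0, 1], got {v}")
        if self.f_EW + self.f_IW + self.f_NL + self.f_NP > 1.0 + 1e-9:
            raise ConfigurationError(f"tissue '{self.name}': composition fractions sum to > 1")
        if self.volume <= 0:
            raise ConfigurationError(f"tissue '{self.name}': volume must be > 0")
        if self.Q_B < 0:
            raise ConfigurationError(f"tissue '{self.name}': Q_B must be >= 0")
        if any(m < 0 for m in self.drug_mass.values()):
            raise ConfigurationError(f"tissue '{self.name}': drug_mass entries must be >= 0")


@dataclass
class PlasmaEnvironment:
    """Plasma-side constants: pH, body weight and hepatic inflow."""

    pH_P: float = 7.4
    BW: float = 70.0
    Q_H: float = 1.54  # L/min, portal + hepatic-artery inflow

    def __post_init__(self) -> None:
        if not (6.8 <= self.pH_P <= 7.8):
            raise ConfigurationError(f"pH_P must be in [6.8, 7.8], got {self.pH_P}")
        if self.BW <= 0:
            raise ConfigurationError("BW must be > 0")
        if self.Q_H <= 0:
            raise ConfigurationError("Q_H must be > 0")


def compute_xy(drug_class: str, pKa: float | None, pH_IW: float, pH_P: float) -> Tuple[float, float]:
    """Ionisation factors (X, Y) for the intracellular-water and plasma sides.

    X is evaluated at the intracellular pH, Y at the plasma pH:

        acid:      1 + 10**(pH - pKa)
        weak base: 1 + 10**(pKa - pH)
        neutral:   1

    Strong bases and the basic moiety of zwitterions follow the weak-base
    form.  Raises ConfigurationError for an unknown class and DomainError for
    non-finite inputs.
    """
    if not (math.isfinite(pH_IW) and math.isfinite(pH_P)):
        raise DomainError("pH values must be finite")
    if drug_class == "neutral":
        return 1.0, 1.0
    if pKa is None or not math.isfinite(pKa):
        raise DomainError(f"pKa must be set and finite for drug class '{drug_class}'")
    if drug_class == "acid":
        return 1.0 + 10.0 ** (pH_IW - pKa), 1.0 + 10.0 ** (pH_P - pKa)
    if drug_class in ("weak_base", "strong_base", "zwitterion"):
        return 1.0 + 10.0 ** (pKa - pH_IW), 1.0 + 10.0 ** (pKa - pH_P)
    raise ConfigurationError(f"unknown drug_class '{drug_class}'")


def _neutral_lipid_term(P: float, f_NL: float, f_NP: float, Y: float) -> float:
    # shared neutral-lipid / neutral-phospholipid partitioning term
    return (P * f_NL + (0.3 * P - 0.7) * f_NP) / Y


def zwitterion_phospholipid_term(drug: DrugProperties, tissue: TissueCompartment, Y: float) -> float:
    """Acidic-phospholipid term of the zwitterion branch.

    Implemented literally as printed in the source model, with the subtracted
    acidic-moiety correction grouped inside the same numerator; isolated here
    so that an alternative grouping can be swapped in at a single point.
    """
    assert drug.pKa_base is not None and drug.pKa_acid is not None
    num = (
        drug.Ka_AP * tissue.AP_conc * 10.0 ** (drug.pKa_base - tissue.pH_IW)
        - 10.0 ** (tissue.pH_IW - drug.pKa_acid)
    )
    return num / Y


def partition_coefficient(
    drug: DrugProperties, tissue: TissueCompartment, env: PlasmaEnvironment
) -> float:
    """Tissue-to-blood partition coefficient K_TB (dimensionless, > 0).

    Dispatches on ``drug.drug_class``: strong bases use the acidic-
    phospholipid binding form, acids/neutrals/weak bases the tissue-binding
    (K_bind) form, and zwitterions a combined form.  The leading factor
    ``f_u / gamma_BP`` rescales the classical plasma-referenced coefficient
    to whole blood.
    """
    cls = drug.drug_class
    pKa = drug.pKa_base if cls in ("weak_base", "strong_base", "zwitterion") else drug.pKa_acid
    X, Y = compute_xy(cls, pKa, tissue.pH_IW, env.pH_P)
    if Y <= 0:
        raise DomainError(
            f"partition_coefficient: non-positive ionisation factor Y={Y} for "
            f"drug '{drug.name}' in tissue '{tissue.name}'"
        )
    lipid = _neutral_lipid_term(drug.P, tissue.f_NL, tissue.f_NP, Y)
    scale = drug.f_u / drug.gamma_BP
    if cls == "strong_base":
        assert drug.pKa_base is not None
        ap = drug.Ka_AP * tissue.AP_conc * 10.0 ** (drug.pKa_base - tissue.pH_IW) / Y
        inner = tissue.f_EW + (X / Y) * tissue.f_IW + ap + lipid
    elif cls in ("acid", "neutral", "weak_base"):
        inner = (
            tissue.f_EW
            + (X / Y) * tissue.f_IW
            + lipid
            + drug.K_bind * (1.0 / drug.f_u - 1.0 - lipid)
        )
    else:  # zwitterion
        inner = (
            tissue.f_EW
            + (X / Y) * tissue.f_IW
            + lipid
            + zwitterion_phospholipid_term(drug, tissue, Y)
        )
    k_tb = scale * inner
    if not (k_tb > 0):
        raise DomainError(
            f"partition_coefficient: K_TB={k_tb!r} is not positive for drug "
            f"'{drug.name}' in tissue '{tissue.name}' (inner={inner!r}); check "
            "composition fractions and binding constants"
        )
    return k_tb


def perfusion_flux(Q_B: float, C_B: float, C_T: float, K_TB: float) -> float:
    """Perfusion-limited exchange rate dm/dt = Q_B * (C_B - C_T / K_TB).

    Positive values move drug from blood into tissue.  Units: Q_B in
    volume/time, concentrations in mass/volume; the result is mass/time in
    the same units.
    """
    if K_TB <= 0:
        raise DomainError(f"perfusion_flux: K_TB must be > 0, got {K_TB}")
    if Q_B < 0:
        raise DomainError(f"perfusion_flux: Q_B must be >= 0, got {Q_B}")
    return Q_B * (C_B - C_T / K_TB)


def hepatic_clearance(Q_H: float, f_u: float, Cl_I: float) -> float:
    """Well-stirred hepatic clearance Cl_H = Q_H*f_u*Cl_I / (Q_H + f_u*Cl_I).

    Unit-agnostic provided Q_H and Cl_I share units; the result satisfies
    0 <= Cl_H < Q_H (flow-limited ceiling).
    """
    if Q_H <= 0:
        raise DomainError(f"hepatic_clearance: Q_H must be > 0, got {Q_H}")
    if f_u < 0 or Cl_I < 0:
        raise DomainError("hepatic_clearance: f_u and Cl_I must be >= 0")
    fc = f_u * Cl_I
    return Q_H * fc / (Q_H + fc)


def clearance_mass_step(
    BW: float, Cl_H: float, C_L: float, dt: float, available: float = math.inf
) -> float:
    """Mass removed by metabolism in one step: m = BW * Cl_H * C_L * dt.

    ``Cl_H`` is the per-kg clearance (volume/time/kg), ``C_L`` the liver
    vasculature concentration.  Clamped at ``available`` so a compartment can
    never go negative.
    """
    if BW < 0 or Cl_H < 0 or C_L < 0 or dt < 0:
        raise DomainError("clearance_mass_step: all arguments must be >= 0")
    return min(BW * Cl_H * C_L * dt, available)
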