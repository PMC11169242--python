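"""Configuration loading/validation and tabular output.

All configuration is JSON (diff-friendly, schema-checked field by field with
errors that name the offending key); time series are CSV with the fixed
column contract from :mod:`naloxsim.physiology`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .chemoreflex import ChemoreflexParams
from .errors import ValidationError
from .nasal import NasalRateConstants
from .pbpk import DrugProperties, EffectChannel, PlasmaEnvironment, TissueCompartment
from .physiology import TRACE_COLUMNS, Patient, SimulationTrace

SUPPORTED_ROUTES = ("iv_bolus", "iv_infusion", "nasal")

_EVENT_KEYS = {
    "iv_bolus": {"time_s", "route", "drug", "amount_ug", "amount_ug_per_kg"},
    "iv_infusion": {"time_s", "route", "drug", "concentration_ug_mL",
                    "rate_mL_min", "duration_s"},
    "nasal": {"time_s", "route", "drug", "amount_ug"},
}


@dataclass
class ScenarioConfig:
    """A validated simulation scenario."""

    patient: Patient
    drugs: Dict[str, DrugProperties]
    nasal_rates: NasalRateConstants
    events: List[dict] = field(default_factory=list)
    protocol: Optional[dict] = None
    horizon_s: float = 7200.0
    dt: float = 0.02


def _read_json(path) -> dict:
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"config file not found: {p}")
    try:
        return json.loads(p.read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"{p}: invalid JSON ({e})") from e


def load_drug(source) -> DrugProperties:
    """Build DrugProperties from a JSON file path or an already-parsed dict."""
    d = dict(_read_json(source)) if not isinstance(source, dict) else dict(source)
    effects = {
        name: EffectChannel(**spec) for name, spec in (d.pop("pd_effects", {}) or {}).items()
    }
    d = {k: v for k, v in d.items() if v is not None}
    try:
        return DrugProperties(pd_effects=effects, **d)
    except TypeError as e:
        raise ValidationError(f"drug config: {e}") from e


def load_nasal_rates(source) -> NasalRateConstants:
    d = _read_json(source) if not isinstance(source, dict) else source
    return NasalRateConstants.from_dict(d)


def load_patient(source) -> Patient:
    d = dict(_read_json(source)) if not isinstance(source, dict) else dict(source)
    try:
        tissues = {
            n: TissueCompartment(name=n, **spec) for n, spec in d.pop("tissues", {}).items()
        }
        env = PlasmaEnvironment(**d.pop("env", {}))
        reflex = ChemoreflexParams(**d.pop("reflex", {}))
        return Patient(tissues=tissues, env=env, reflex=reflex, **d)
    except TypeError as e:
        raise ValidationError(f"patient config: {e}") from e


def validate_events(events: List[dict], drugs: Dict[str, DrugProperties],
                    BW: float) -> List[dict]:
    """Check and normalise a dose-event list.

    Routes are restricted to the supported set, every referenced drug must be
    defined, quantities must be positive and the list time-ordered.  Per-kg
    bolus amounts are resolved to absolute ug using the patient body weight.
    """
    out = []
    prev_t = -float("inf")
    for i, ev in enumerate(events):
        ev = dict(ev)
        where = f"events[{i}]"
        route = ev.get("route")
        if route not in SUPPORTED_ROUTES:
            raise ValidationError(
                f"{where}.route: '{route}' unsupported "
                f"(supported routes: {', '.join(SUPPORTED_ROUTES)})"
            )
        unknown = set(ev) - _EVENT_KEYS[route]
        if unknown:
            raise ValidationError(f"{where}: unknown key(s) {sorted(unknown)} for route {route}")
        if "time_s" not in ev:
            raise ValidationError(f"{where}.time_s: missing")
        t = float(ev["time_s"])
        if t < prev_t:
            raise ValidationError(f"{where}.time_s: events must be time-ordered")
        prev_t = t
        drug = ev.get("drug")
        if drug not in drugs:
            raise ValidationError(
                f"{where}.drug: '{drug}' is not defined (known drugs: {sorted(drugs)})"
            )
        if route == "iv_bolus":
            if "amount_ug_per_kg" in ev:
                ev["amount_ug"] = float(ev.pop("amount_ug_per_kg")) * BW
            if "amount_ug" not in ev:
                raise ValidationError(f"{where}: iv_bolus needs amount_ug or amount_ug_per_kg")
        else:
            for key in _EVENT_KEYS[route] - {"time_s", "route", "drug"}:
                if key not in ev:
                    raise ValidationError(f"{where}.{key}: missing for route {route}")
        for key, val in ev.items():
            if key in ("route", "drug"):
                continue
            if float(val) < 0:
                raise ValidationError(f"{where}.{key}: must be >= 0, got {val}")
        out.append(ev)
    return out


def load_scenario(path, base_dir=None) -> ScenarioConfig:
    """Load and validate a scenario file.

    File references for patient/drugs/nasal rates are resolved relative to
    the scenario file; missing blocks fall back to the built-in fixtures.
    """
    from . import fixtures

    doc = _read_json(path)
    base = Path(base_dir) if base_dir is not None else Path(path).parent

    def resolve(ref):
        return base / ref if isinstance(ref, str) else ref

    known = {"patient", "drugs", "nasal_rates", "events", "protocol", "horizon_s", "dt"}
    unknown = set(doc) - known
    if unknown:
        raise ValidationError(f"scenario: unknown top-level key(s) {sorted(unknown)}")

    patient = (
        load_patient(resolve(doc["patient"])) if "patient" in doc else fixtures.default_patient()
    )
    if "drugs" in doc:
        drugs = {name: load_drug(resolve(ref)) for name, ref in doc["drugs"].items()}
    else:
        drugs = {"fentanyl": fixtures.default_fentanyl(),
                 "naloxone": fixtures.default_naloxone()}
    rates = (
        load_nasal_rates(resolve(doc["nasal_rates"]))
        if "nasal_rates" in doc else fixtures.default_nasal_rates()
    )
    events = validate_events(doc.get("events", []), drugs, patient.BW)
    horizon = float(doc.get("horizon_s", 7200.0))
    dt = float(doc.get("dt", 0.02))
    if dt <= 0 or horizon <= 0:
        raise ValidationError("scenario: dt and horizon_s must be > 0")
    return ScenarioConfig(
        patient=patient, drugs=drugs, nasal_rates=rates, events=events,
        protocol=doc.get("protocol"), horizon_s=horizon, dt=dt,
    )


def write_trace(trace: SimulationTrace, path) -> None:
    """Write a time-series CSV with the fixed column contract."""
    trace.to_csv(path)


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trace file {path}: missing column(s) {missing}")
    return df


def write_summary(result, path) -> None:
    """Write a sweep summary as JSON: per-dose totals plus bin statistics."""
    doc = {"records": result.records.to_dict(orient="records")}
    if result.bins is not None:
        doc["bins"] = result.bins.to_dict(orient="records")
        doc["adjacent_bin_p_values"] = result.p_values
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
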