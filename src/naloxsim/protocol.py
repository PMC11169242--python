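"""Goal-directed naloxone rescue protocol, fentanyl dose sweep and
CO2-challenge experiments.

The rescue automaton mirrors field practice driven solely by pulse-oximetry:
after an opioid bolus at t=0 and a responder transit delay, one standard
nasal naloxone dose is given; thereafter SpO2 is checked on a fixed cadence
and every check that finds SpO2 below the concern threshold triggers another
dose.  The patient counts as rescued after a sustained window above the
threshold; the window clock resets whenever SpO2 dips below it.

All experiments are deterministic: identical configuration produces a
bit-identical dosing-event log.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class RescueProtocol:
    """Parameters of the SpO2-driven repeat-dosing rescue algorithm."""

    transit_delay: float = 120.0  # s before the first naloxone dose
    dose_mg: float = 2.0          # mg per nasal administration
    check_interval: float = 50.0  # s between SpO2 evaluations
    spo2_threshold: float = 0.85  # concern level (fraction)
    rescued_window: float = 600.0  # s of sustained SpO2 above threshold
    max_total_mg: float = 40.0    # safety cap

    def __post_init__(self) -> None:
        for name in ("transit_delay", "dose_mg", "check_interval",
                     "rescued_window", "max_total_mg"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"protocol: {name} must be > 0")
        if not (0.0 < self.spo2_threshold < 1.0):
            raise ConfigurationError("protocol: spo2_threshold must be in (0, 1)")


@dataclass
class RescueRecord:
    """Outcome of one rescue run."""

    fentanyl_mg: float
    total_naloxone_mg: float
    n_doses: int
    rescued: bool
    died: bool
    capped: bool
    min_SpO2: float
    min_RR: float
    dose_times: List[float] = field(default_factory=list)
    events: List[Tuple[float, str]] = field(default_factory=list)
    trace: object = None


def run_rescue(
    model,
    fentanyl_mg: float,
    protocol: RescueProtocol = RescueProtocol(),
    dt: float = 0.1,
    horizon_s: float = 10800.0,
    agonist: str = "fentanyl",
    antagonist: str = "naloxone",
    give_fentanyl: bool = True,
    record_interval: float = 5.0,
) -> RescueRecord:
    """Run the goal-directed rescue automaton on a physiology model.

    ``model`` is duck-typed: it needs ``step(dt)``, ``spo2``, ``rr``,
    ``alive``, ``give_iv_bolus(drug, ug)`` and ``give_nasal(drug, mg)`` (and
    optionally ``record()``/``log_event``).  The opioid bolus is given at
    t=0 (unless ``give_fentanyl`` is False for pre-dosed mocks), the first
    naloxone dose after ``transit_delay``, and one further dose at every
    subsequent check that finds SpO2 below threshold.  Terminates rescued
    after ``rescued_window`` s of sustained SpO2 at/above threshold following
    the first dose, on death, when the safety cap is reached, or at
    ``horizon_s``.
    """
    if fentanyl_mg <= 0:
        raise ConfigurationError("run_rescue: fentanyl_mg must be > 0")
    if give_fentanyl:
        model.give_iv_bolus(agonist, fentanyl_mg * 1000.0)

    eps = 1e-9
    t = 0.0
    total_mg = 0.0
    n_doses = 0
    dose_times: List[float] = []
    first_dose_given = False
    next_check = math.inf
    above_since: Optional[float] = None
    min_spo2 = model.spo2
    min_rr = model.rr
    rescued = False
    capped = False
    next_rec = 0.0
    can_record = hasattr(model, "record")

    def log(msg: str) -> None:
        if hasattr(model, "log_event"):
            model.log_event(msg)
        logger.info("t=%.1f s: %s", t, msg)

    while t < horizon_s - eps:
        if not first_dose_given and t + eps >= protocol.transit_delay:
            model.give_nasal(antagonist, protocol.dose_mg)
            total_mg += protocol.dose_mg
            n_doses += 1
            dose_times.append(t)
            first_dose_given = True
            next_check = t + protocol.check_interval
            above_since = t if model.spo2 >= protocol.spo2_threshold else None
            log(f"protocol: initial naloxone dose ({protocol.dose_mg:g} mg)")
        elif first_dose_given and t + eps >= next_check:
            next_check += protocol.check_interval
            if model.spo2 < protocol.spo2_threshold:
                if total_mg + protocol.dose_mg > protocol.max_total_mg + eps:
                    capped = True
                    log("protocol: safety cap reached, terminating")
                    break
                model.give_nasal(antagonist, protocol.dose_mg)
                total_mg += protocol.dose_mg
                n_doses += 1
                dose_times.append(t)
                log(f"protocol: repeat naloxone dose (total {total_mg:g} mg)")

        model.step(dt)
        t += dt
        spo2 = model.spo2
        if spo2 < min_spo2:
            min_spo2 = spo2
        if model.rr < min_rr:
            min_rr = model.rr
        if can_record and t + eps >= next_rec:
            model.record()
            next_rec += record_interval

        if not model.alive:
            log("protocol: patient died")
            break
        if first_dose_given:
            if spo2 >= protocol.spo2_threshold:
                if above_since is None:
                    above_since = t
                elif t - above_since >= protocol.rescued_window - eps:
                    rescued = True
                    log("protocol: patient rescued (sustained SpO2)")
                    break
            else:
                above_since = None  # the rescue clock resets on every dip

    return RescueRecord(
        fentanyl_mg=fentanyl_mg,
        total_naloxone_mg=total_mg,
        n_doses=n_doses,
        rescued=rescued,
        died=not model.alive,
        capped=capped,
        min_SpO2=min_spo2,
        min_RR=min_rr,
        dose_times=dose_times,
        events=list(getattr(model, "events", [])),
        trace=getattr(model, "trace", None),
    )


@dataclass
class SweepResult:
    """Per-dose rescue records plus bin summaries for the fentanyl sweep."""

    records: pd.DataFrame
    bins: Optional[pd.DataFrame] = None
    p_values: Optional[List[float]] = None

    @property
    def doses(self) -> np.ndarray:
        return self.records["fentanyl_mg"].to_numpy()

    @property
    def totals(self) -> np.ndarray:
        return self.records["total_naloxone_mg"].to_numpy()


def dose_sweep(
    engine_factory: Callable[[], object],
    protocol: Optional[RescueProtocol] = None,
    doses_mg: Optional[Sequence[float]] = None,
    rescue: bool = True,
    dt: float = 0.1,
    horizon_s: float = 10800.0,
    with_stats: bool = True,
) -> SweepResult:
    """Run one independent rescue (or unrescued) scenario per fentanyl dose.

    ``engine_factory`` returns a fresh physiology model for every dose so the
    runs are fully independent and deterministic.  With ``rescue=False`` the
    protocol is disabled (no naloxone) and the sweep reads out survival.
    """
    from .fixtures import SWEEP_DOSES_MG  # local import avoids a cycle

    protocol = protocol or RescueProtocol()
    doses = list(doses_mg) if doses_mg is not None else list(SWEEP_DOSES_MG)
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ConfigurationError("dose_sweep: dose grid must be strictly increasing")

    rows = []
    for dose in doses:
        model = engine_factory()
        if rescue:
            rec = run_rescue(model, dose, protocol, dt=dt, horizon_s=horizon_s)
        else:
            rec = _run_unrescued(model, dose, dt=dt, horizon_s=horizon_s)
        rows.append({
            "fentanyl_mg": dose,
            "total_naloxone_mg": rec.total_naloxone_mg,
            "n_doses": rec.n_doses,
            "rescued": rec.rescued,
            "died": rec.died,
            "capped": rec.capped,
            "min_SpO2": rec.min_SpO2,
            "min_RR": rec.min_RR,
        })
    result = SweepResult(records=pd.DataFrame(rows))
    if with_stats and rescue and len(doses) % 3 == 0:
        bin_statistics(result)
    return result


def _run_unrescued(model, fentanyl_mg: float, dt: float, horizon_s: float) -> RescueRecord:
    model.give_iv_bolus("fentanyl", fentanyl_mg * 1000.0)
    t = 0.0
    min_spo2 = model.spo2
    min_rr = model.rr
    while t < horizon_s and model.alive:
        model.step(dt)
        t += dt
        min_spo2 = min(min_spo2, model.spo2)
        min_rr = min(min_rr, model.rr)
    return RescueRecord(
        fentanyl_mg=fentanyl_mg, total_naloxone_mg=0.0, n_doses=0,
        rescued=False, died=not model.alive, capped=False,
        min_SpO2=min_spo2, min_RR=min_rr,
        events=list(getattr(model, "events", [])),
        trace=getattr(model, "trace", None),
    )


def bin_statistics(result: SweepResult, n_bins: int = 3) -> SweepResult:
    """Partition the sweep into equal bins; mean/median/sd plus adjacent
    two-sided Welch t-tests.

    Degenerate zero-variance bin pairs are reported as an exact comparison of
    means (p = 1 if equal, p = 0 otherwise) with a warning.
    """
    totals = result.totals
    n = len(totals)
    if n % n_bins != 0:
        raise ConfigurationError(f"bin_statistics: {n} records not divisible into {n_bins} bins")
    size = n // n_bins
    groups = [totals[i * size:(i + 1) * size] for i in range(n_bins)]
    result.bins = pd.DataFrame({
        "bin": list(range(1, n_bins + 1)),
        "dose_lo": [result.doses[i * size] for i in range(n_bins)],
        "dose_hi": [result.doses[(i + 1) * size - 1] for i in range(n_bins)],
        "mean": [float(np.mean(g)) for g in groups],
        "median": [float(np.median(g)) for g in groups],
        "sd": [float(np.std(g, ddof=1)) for g in groups],
        "n": [size] * n_bins,
    })
    pvals = []
    for a, b in zip(groups, groups[1:]):
        if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
            warnings.warn("bin_statistics: zero-variance bins, p from exact mean comparison")
            pvals.append(1.0 if np.mean(a) == np.mean(b) else 0.0)
        else:
            with warnings.catch_warnings():
                # one-sided zero variance is fine for Welch; silence scipy's
                # precision-loss chatter for constant inputs
                warnings.simplefilter("ignore")
                pvals.append(float(stats.ttest_ind(a, b, equal_var=False).pvalue))
    result.p_values = pvals
    return result


def plateau_onset(doses: Sequence[float], totals: Sequence[float]) -> float:
    """Dose above which the naloxone requirement stops increasing.

    Returns the dose at the last strict increase of the totals curve, i.e.
    the dose at which the requirement first attains its final plateau value.
    If the curve never increases the first dose is returned.
    """
    doses = list(doses)
    totals = list(totals)
    last = 0
    for j in range(1, len(totals)):
        if totals[j] > totals[j - 1]:
            last = j
    return doses[last]


@dataclass
class CO2ChallengeResult:
    """Ventilatory CO2 response slope per fentanyl infusion step."""

    steps_ug_mL: List[float]
    slopes: List[Optional[float]]  # L/min per mmHg EtCO2; None if undefined
    baseline_slope: Optional[float] = None  # drug-free conditioning window
    table: Optional[pd.DataFrame] = None


def ventilation_co2_slope(ventilation: Sequence[float], etco2: Sequence[float]) -> Optional[float]:
    """Least-squares slope of total ventilation against EtCO2; None if EtCO2
    has no variance in the window."""
    v = np.asarray(ventilation, dtype=float)
    e = np.asarray(etco2, dtype=float)
    if len(v) < 2 or float(np.var(e)) == 0.0:
        return None
    return float(np.polyfit(e, v, 1)[0])


def _drift_corrected_slope(t, ventilation, etco2) -> Optional[float]:
    # least-squares slope on EtCO2 with a linear time term absorbing the
    # slow drift of the operating point while the infusion equilibrates
    v = np.asarray(ventilation, float)
    e = np.asarray(etco2, float)
    t = np.asarray(t, float)
    if len(v) < 3 or float(np.var(e)) == 0.0:
        return None
    X = np.column_stack([e, t - t[0], np.ones(len(v))])
    beta, _, rank, _ = np.linalg.lstsq(X, v, rcond=None)
    if rank < 3:  # EtCO2 collinear with time: fall back to the plain fit
        return ventilation_co2_slope(v, e)
    return float(beta[0])


def co2_challenge(
    engine,
    fentanyl_steps_ug_mL: Sequence[float] = (10, 20, 30, 40, 50, 60),
    FiCO2_step: float = 0.03,
    window_s: float = 600.0,
    co2_duration_s: float = 300.0,
    infusion_rate_mL_min: float = 0.5,
    dt: float = 0.1,
    conditioning_window: bool = True,
) -> CO2ChallengeResult:
    """Step-infusion CO2 rebreathing experiment.

    For each fentanyl concentration step: infuse at ``infusion_rate_mL_min``
    for the whole 10-minute window; over the last ``co2_duration_s`` of the
    window the inhaled CO2 fraction is raised to ``FiCO2_step`` (the first
    half lets the new plasma level approach steady state) and reverted at
    the window end.  The CO2 response at a step is the least-squares slope
    of total pulmonary ventilation (RR x VT, L/min) against the EtCO2
    perturbation over the window, with a linear time term absorbing the
    slow drift of the operating point.  A drug-free conditioning window is
    run first by default so every measured window sees the same carry-over
    from the preceding CO2 exposure.
    """
    steps = list(fentanyl_steps_ug_mL)
    if any(b <= a for a, b in zip(steps, steps[1:])):
        raise ConfigurationError("co2_challenge: steps must be ascending")
    baseline_fico2 = engine.FiCO2

    def run_window(conc: float) -> Optional[float]:
        if conc > 0:
            engine.start_infusion("fentanyl", conc * infusion_rate_mL_min / 60.0, window_s)
        t0 = engine.t
        co2_on = False
        ts: List[float] = []
        vent: List[float] = []
        etco2: List[float] = []
        while engine.t < t0 + window_s - 1e-9:
            engine.step(dt)
            if not co2_on and engine.t >= t0 + window_s - co2_duration_s:
                engine.set_inhaled_co2(FiCO2_step)
                co2_on = True
            ts.append(engine.t)
            vent.append(engine.RR * engine.VT)
            etco2.append(engine.EtCO2)
        engine.set_inhaled_co2(baseline_fico2)
        s = _drift_corrected_slope(ts, vent, etco2)
        if s is None:
            logger.warning("co2_challenge: EtCO2 variance zero at %g ug/mL", conc)
        return s

    baseline_slope = run_window(0.0) if conditioning_window else None
    slopes = [run_window(c) for c in steps]
    table = pd.DataFrame({"fentanyl_ug_mL": steps, "slope_L_min_per_mmHg": slopes})
    return CO2ChallengeResult(steps, slopes, baseline_slope, table)
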