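#!/usr/bin/env python
"""Calibration harness for the default virtual patient and drug parameters.

Evaluates the package's respiratory calibration anchors for the current
defaults (optionally with parameter overrides) and prints a report:

* resting respiration rate of the undrugged patient;
* minimum respiration rate after a receptor-saturating (1.9 mg) bolus;
* largest unrescued-survivable fentanyl dose on the 0.2-1.9 mg grid;
* rescue-sweep naloxone totals, their plateau onset and maximum fold of the
  2 mg standard dose;
* nasal 2 mg plasma peak time (target: 15-40 min);
* CO2-challenge slope monotonicity.

Usage: python scripts/calibrate.py [--fast] [--skip SECTION,...]
The defaults frozen in naloxsim.fixtures are the output of iterating this
script; it is shipped so the calibration is reproducible and documented.
"""

from __future__ import annotations

import argparse
import sys
import time

import numpy as np

import naloxsim as nx


def baseline_rr(dt=0.1):
    e = nx.make_engine(dt=dt)
    e.run(600, record_interval=5.0)
    df = e.trace.to_dataframe()
    return float(df.loc[df.time_s >= 300, "RR_per_min"].mean())


def min_rr_saturating(dt=0.1, dose_mg=1.9):
    e = nx.make_engine(dt=dt)
    e.give_iv_bolus("fentanyl", dose_mg * 1000)
    min_rr = e.RR
    while e.t < 10800 and e.alive:
        e.step()
        min_rr = min(min_rr, e.RR)
    return min_rr, e.alive, e.death_time


def unrescued_sweep(dt=0.1, doses=None):
    from naloxsim.protocol import dose_sweep

    res = dose_sweep(lambda: nx.make_engine(dt=dt), rescue=False, dt=dt,
                     doses_mg=doses, with_stats=False)
    df = res.records
    surv = df.loc[~df.died, "fentanyl_mg"]
    boundary = float(surv.max()) if len(surv) else float("nan")
    return df, boundary


def rescued_sweep(dt=0.1, doses=None):
    from naloxsim.protocol import dose_sweep, plateau_onset

    res = dose_sweep(lambda: nx.make_engine(dt=dt), rescue=True, dt=dt, doses_mg=doses)
    df = res.records
    onset = plateau_onset(df.fentanyl_mg, df.total_naloxone_mg)
    fold = float(df.total_naloxone_mg.max()) / 2.0
    return res, onset, fold


def nasal_peak_time(dt=0.1):
    e = nx.make_engine(dt=dt)
    e.give_nasal("naloxone", 2.0)
    best_t, best_c = 0.0, -1.0
    while e.t < 7200:
        e.step()
        c = e.plasma_concentration("naloxone")
        if c > best_c:
            best_c, best_t = c, e.t
    frac = e.drugs["naloxone"].nasal.cumulative_systemic / 2000.0
    return best_t / 60.0, best_c, frac


def co2_slopes(dt=0.1):
    from naloxsim.protocol import co2_challenge

    e = nx.make_engine(dt=dt)
    res = co2_challenge(e, dt=dt)
    return res.slopes


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--skip", default="", help="comma list: base,sat,unresc,resc,nasal,co2")
    ap.add_argument("--dt", type=float, default=0.1)
    args = ap.parse_args()
    skip = set(args.skip.split(",")) if args.skip else set()

    t0 = time.time()
    if "base" not in skip:
        print(f"baseline RR           : {baseline_rr(args.dt):.3f} /min (anchor ~16)")
    if "sat" not in skip:
        mr, alive, dtd = min_rr_saturating(args.dt)
        print(f"min RR @1.9mg         : {mr:.3f} /min (anchor ~2); alive={alive} death_t={dtd}")
    if "nasal" not in skip:
        pk, c, f = nasal_peak_time(args.dt)
        print(f"nasal 2mg peak        : {pk:.1f} min, {c:.2f} ug/L, systemic frac {f:.2f} (anchor 15-40 min)")
    if "unresc" not in skip:
        df, boundary = unrescued_sweep(args.dt)
        print(f"unrescued survival    : boundary {boundary} mg (anchor 1.5)")
        print(df[["fentanyl_mg", "died", "min_SpO2", "min_RR"]].to_string(index=False))
    if "resc" not in skip:
        res, onset, fold = rescued_sweep(args.dt)
        print(f"rescue plateau onset  : {onset} mg (anchor 1.2); max fold {fold:.1f} (anchor <= 8)")
        print(res.records.to_string(index=False))
        if res.p_values:
            print(f"adjacent-bin p-values : {res.p_values} (anchor: both < 0.05)")
    if "co2" not in skip:
        s = co2_slopes(args.dt)
        mono = all(b < a for a, b in zip(s, s[1:]) if a is not None and b is not None)
        print(f"co2 slopes            : {['%.3f' % x if x is not None else 'NA' for x in s]} monotone down: {mono}")
    print(f"[{time.time()-t0:.1f} s]")
    return 0


if __name__ == "__main__":
    sys.exit(main())
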