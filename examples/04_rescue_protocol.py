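"""The SpO2-guided repeat-dosing naloxone rescue for one overdose.

Runs the goal-directed protocol against a 1.5 mg fentanyl bolus: first
responders arrive after a 120 s transit delay and give one 2 mg nasal dose,
then re-evaluate the pulse-oximeter every 50 s and re-dose whenever SpO2 is
below the 85 % concern threshold.  The run ends once saturation has held
above threshold for 10 minutes.  The printed dose log is the protocol
automaton's decision record.
"""

from naloxsim import RescueProtocol, make_engine, run_rescue

record = run_rescue(make_engine(dt=0.1), fentanyl_mg=1.5,
                    protocol=RescueProtocol(), dt=0.1)

print(f"fentanyl dose:        {record.fentanyl_mg} mg IV bolus at t = 0")
print(f"naloxone doses given: {record.n_doses} x 2 mg at "
      f"{[f'{t:.0f} s' for t in record.dose_times]}")
print(f"total naloxone:       {record.total_naloxone_mg:.0f} mg "
      f"({record.total_naloxone_mg / 2:.0f}x the standard dose)")
print(f"minimum SpO2:         {record.min_SpO2:.3f}")
print(f"minimum RR:           {record.min_RR:.2f} breaths/min")
print(f"outcome:              rescued={record.rescued} died={record.died}")
print("\nprotocol event log:")
for t, msg in record.events:
    if "protocol" in msg:
        print(f"  t = {t:6.1f} s  {msg}")
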