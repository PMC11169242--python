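"""Respiratory depression after an IV fentanyl bolus with no intervention.

Gives the virtual patient a 1.0 mg bolus (a large recreational dose) and
prints the respiratory collapse and spontaneous recovery as the drug
redistributes: respiration rate falls toward its 2/min floor as mu-receptor
occupancy saturates, oxygen saturation crashes, and ventilation only
returns once the effect-site concentration decays.  At this dose the
patient survives; above 1.5 mg the sustained hypoxaemia criterion kills.
"""

from naloxsim import make_engine

engine = make_engine(dt=0.1)
engine.give_iv_bolus("fentanyl", 1000.0)  # 1.0 mg

min_rr, min_spo2 = engine.RR, engine.SpO2
for minute in (1, 2, 4, 6, 8, 10, 15, 20, 30, 45, 60):
    while engine.t < minute * 60.0 and engine.alive:
        engine.step()
        min_rr = min(min_rr, engine.RR)
        min_spo2 = min(min_spo2, engine.SpO2)
    print(
        f"t = {minute:3d} min  Ce = {engine.drugs['fentanyl'].Ce:5.1f} ug/L  "
        f"RR = {engine.RR:5.2f}/min  VT = {engine.VT:4.2f} L  "
        f"SpO2 = {engine.SpO2:5.3f}  nu = {engine.nu:5.3f}"
    )

print(f"\nminimum respiration rate: {min_rr:.2f} breaths/min")
print(f"minimum oxygen saturation: {min_spo2:.3f}")
print(f"patient alive at 1 h: {engine.alive}")
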