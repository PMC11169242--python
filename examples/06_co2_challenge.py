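"""Chemoreceptor buffering: the CO2 response fades as fentanyl rises.

Step-infuses fentanyl at increasing concentrations (10..60 ug/mL at
0.5 mL/min, one 10-minute window each) and exposes the patient to 3 %
inhaled CO2 for the last five minutes of every window.  The CO2-response
slope -- extra ventilation per mmHg of end-tidal CO2 -- shrinks
monotonically because the opioid attenuates the chemoreceptor afferents
(the e^{-3.5 nu} factor), so the feedback loop that normally defends
against hypercapnia is progressively silenced.
"""

from naloxsim import co2_challenge, make_engine

result = co2_challenge(make_engine(dt=0.1), dt=0.1)

print(f"drug-free conditioning window slope: "
      f"{result.baseline_slope:.3f} L/min per mmHg EtCO2")
print(f"\n{'fentanyl (ug/mL)':>18} {'CO2 slope (L/min/mmHg)':>24}")
for conc, slope in zip(result.steps_ug_mL, result.slopes):
    print(f"{conc:>18} {slope:>24.3f}")
print("\nmonotone decrease: chemoreceptor feedback is buffered by the opioid")
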