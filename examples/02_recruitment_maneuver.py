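"""Simulate the maximal recruitment strategy on fitted Patient A.

Loads the calibrated moderate-ARDS preset, runs the MRS with a final PEEP of
10 cm H2O (PEEP staircase 5->45, driving pressure 15, titration back to 10),
and prints the oxygenation response and barotrauma surrogate.
"""

from alveosim.config import load_preset
from alveosim.engine import run_protocol
from alveosim.protocols import build_named

patient = load_preset("A")
protocol = build_named("MRS-10", patient=patient.vent)
result = run_protocol(patient, protocol)

pre_end = protocol.segments[0].duration
d = result.data
print(f"protocol {protocol.label}: {protocol.total_duration / 60:.0f} min, "
      f"{len(d)} breaths")
print(f"pre-RM PaO2/FiO2:    {result.baseline_pf(pre_end):6.1f} mmHg "
      "(moderate ARDS)")
print(f"maximum PaO2/FiO2:   {d.pf_ratio.max():6.1f} mmHg (plateau after "
      "full recruitment)")
print(f"rise above baseline: {result.delta_po2(pre_end):6.1f} mmHg")
print(f"final recruitment:   {result.final_percent_recruited:6.1f} % of "
      "compartments open at PEEP 10")
print(f"P_peak:              {result.p_peak:6.1f} cm H2O (mean max pressure, "
      "top 20% of compartments)")
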