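"""Minimum necessary peak and end PEEP for the staircase maneuver.

Sweeps the MRS peak PEEP (how high must the staircase go to open the lung?)
and the end-maneuver PEEP (how much PEEP is needed to keep it open?) for the
fitted Patient A preset.
"""

from alveosim.config import load_preset
from alveosim.engine import sweep_peep_end, sweep_peep_max

patient = load_preset("A")

rec = sweep_peep_max(patient, [20, 25, 30, 35, 40, 45])
print("percent of compartments recruited at the end of the staircase:")
print(rec.round(1).to_string())

keep = sweep_peep_end(patient, [5, 10, 16, 20])
print("\npercent still open after titration to the end-maneuver PEEP:")
print(keep.round(1).to_string())
print("\nRecruitment saturates near a peak PEEP of 35 cm H2O, and an "
      "end-maneuver PEEP\nnear 16 cm H2O retains essentially all of it; "
      "dropping back to PEEP 5 loses it.")
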