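"""Regenerate the committed fitted-patient presets.

For each embedded record A-E this runs the full two-stage calibration:
static fit to the four blood-gas targets, then the dynamic tau_c fit against
a synthetic PaO2-versus-time reference whose baseline/plateau levels are the
fitted patient's own steady states at PEEP 5 and 15 (the reference emulates
the shape of the clinical PEEP-step response; rise/fall time constants are
the generator defaults).  Results are written to src/alveosim/presets/ with
a checksum, so the simulator test-suite and the maneuver experiments run
without re-fitting.

Usage: python scripts/make_presets.py [--budget 2500] [--seed 7]
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

from alveosim.engine import run_settled
from alveosim.fitting import fit_dynamic, fit_static, generate_dynamic_reference
from alveosim.patients import load_patients_table1

PRESET_DIR = Path(__file__).resolve().parents[1] / "src" / "alveosim" / "presets"


def make_preset(label: str, budget: int, seed: int, out_dir: Path) -> dict:
    rec = load_patients_table1(label)
    t0 = time.time()
    static = fit_static(rec, budget=budget, seed=seed)
    pat = static.patient(rec)
    base = run_settled(pat, 5.0, rec.dp)
    high = run_settled(pat, 15.0, rec.dp)
    ref = generate_dynamic_reference(
        baseline_pao2=base["pao2"], plateau_pao2=high["pao2"], seed=seed)
    dyn = fit_dynamic(static, rec, ref, seed=seed)
    patient = dyn.patient(rec)
    payload = {
        "patient": patient.to_dict(),
        "sha256": patient.checksum(),
        "static_fit": static.to_dict(),
        "dynamic_fit": dyn.to_dict(),
        "seed": seed,
        "budget": budget,
    }
    out = out_dir / f"patient_{label}.json"
    out.write_text(json.dumps(payload, indent=1))
    print(f"{label}: r={static.pearson_r:.4f} obj={static.objective:.4g} "
          f"tauc=({dyn.params.tauc_log_mean:.2f},{dyn.params.tauc_log_sd:.2f}) "
          f"[{time.time() - t0:.0f}s] -> {out}")
    return payload


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--budget", type=int, default=2500)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--labels", default="ABCDE")
    args = ap.parse_args()
    PRESET_DIR.mkdir(exist_ok=True)
    for lab in args.labels:
        make_preset(lab, args.budget, args.seed + ord(lab), PRESET_DIR)


if __name__ == "__main__":
    main()
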