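"""Run configuration, result serialization and fitted-patient presets.

Configs are YAML or JSON validated against a pydantic schema; results are
written as a breath-indexed CSV (column names carry units) plus a companion
JSON with the maneuver-level metrics and full provenance (config hash,
seeds, package version).  Fitted-patient presets are committed JSON files
produced by the calibration pipeline (``scripts/make_presets.py``) and
verified by checksum at load time.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__ as _version
from .engine import SimulationResult
from .patients import VirtualPatient

__all__ = ["RunConfig", "load_config", "write_result", "read_result",
           "preset_patients", "load_preset", "PresetError"]

_COLUMN_UNITS = {
    "time_s": "time_s", "pao2": "pao2_mmHg", "paco2": "paco2_mmHg",
    "pf_ratio": "pf_ratio_mmHg", "sao2": "sao2_frac", "pvo2": "pvo2_mmHg",
    "pvco2": "pvco2_mmHg", "qs_qt": "qs_qt_pct", "vt_ml": "vt_ml",
    "cdyn": "cdyn_ml_per_mbar", "pct_recruited": "pct_recruited",
    "p_peak_run": "p_peak_run_cmH2O", "peep": "peep_cmH2O",
    "dp": "dp_cmH2O", "seg": "segment_index",
}


class RunConfig(BaseModel):
    """Validated configuration for a simulation run."""

    model_config = dict(extra="forbid")

    schema_version: int = 1
    patient: str = "A"              # preset label A-E or a patient JSON path
    protocol: str = "MRS-10"        # protocol name or a protocol JSON/YAML path
    dt: float = Field(0.01, gt=0)
    seed: int = 0
    out: str = "results.csv"
    verbosity: int = 1

    @field_validator("patient")
    @classmethod
    def _patient_exists(cls, v: str) -> str:
        if len(v) > 1 and not Path(v).exists():
            raise ValueError(f"patient file {v!r} does not exist")
        return v

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig(**data)


def write_result(result: SimulationResult, path: str | Path,
                 config: RunConfig | None = None) -> Path:
    """Write a breath-indexed CSV plus a companion metrics/provenance JSON."""
    path = Path(path)
    df = result.data.rename(columns=_COLUMN_UNITS)
    df.to_csv(path, index=False)
    pre = None
    meta = {
        "label": result.label,
        "p_peak_cmH2O": result.p_peak,
        "final_pct_recruited": (result.final_percent_recruited
                                if len(result.data) else None),
        "max_pf_ratio_mmHg": (float(result.data.pf_ratio.max())
                              if len(result.data) else None),
        "provenance": {
            **result.provenance,
            "version": _version,
            "config_hash": config.content_hash() if config else None,
            "seed": config.seed if config else None,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_result(path: str | Path) -> pd.DataFrame:
    """Read back a result CSV with the original column names."""
    inv = {v: k for k, v in _COLUMN_UNITS.items()}
    return pd.read_csv(path).rename(columns=inv)


class PresetError(RuntimeError):
    """A committed preset fixture is missing or fails its checksum."""


def _preset_dir():
    return resources.files("alveosim") / "presets"


def load_preset(label: str) -> VirtualPatient:
    """Load one committed fitted-patient preset, verifying its checksum."""
    f = _preset_dir() / f"patient_{label.upper()}.json"
    try:
        data = json.loads(f.read_text())
    except FileNotFoundError as e:
        raise PresetError(f"preset for patient {label!r} not found") from e
    patient = VirtualPatient.from_dict(data["patient"])
    if patient.checksum() != data["sha256"]:
        raise PresetError(f"preset for patient {label!r} fails checksum")
    return patient


def preset_patients() -> dict[str, VirtualPatient]:
    """All five committed fitted virtual patients A-E."""
    return {lab: load_preset(lab) for lab in "ABCDE"}
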