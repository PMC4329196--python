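import numpy as np
import pytest

from alveosim.engine import EngineConfig
from alveosim.gasexchange import GasExchangeConfig
from alveosim.patients import (FitParameters, build_virtual_patient,
                               load_patients_table1)


@pytest.fixture(scope="session")
def records():
    return load_patients_table1()


@pytest.fixture(scope="session")
def patient_a(records):
    """Moderate-ARDS virtual patient built from record A with default
    population hyper-parameters (not the calibrated preset)."""
    rec = records["A"]
    fp = FitParameters(vr=rec.vr, ie=rec.ie, rq=rec.rq, vo2=rec.vo2,
                       collapsed_frac=rec.collapsed_pct / 100.0)
    return build_virtual_patient(rec, fp, seed=1)


@pytest.fixture(scope="session")
def healthy_patient(records):
    """A patient with no diseased compartments (always fully recruited)."""
    rec = records["A"]
    fp = FitParameters(vr=rec.vr, ie=rec.ie, rq=rec.rq, vo2=rec.vo2,
                       collapsed_frac=0.0)
    return build_virtual_patient(rec, fp, seed=2)


@pytest.fixture(scope="session")
def no_hpv_config():
    """Engine config with HPV and distension coupling disabled, for
    shunt-oracle checks."""
    return EngineConfig(gas=GasExchangeConfig(hpv_enabled=False,
                                              distension_enabled=False))
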