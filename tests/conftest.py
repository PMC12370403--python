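import numpy as np
import pandas as pd
import pytest

from mammodrl.records import FIELDS, CohortTable
from mammodrl.synth import SynthConfig, generate_cohort


def make_table(rows: list[dict]) -> CohortTable:
    """Build a cohort table from partial row dicts (defaults filled in)."""
    base = {
        "center_id": "C1",
        "exam_id": "E1",
        "patient_age": 50,
        "view": "CC",
        "laterality": "L",
        "cbt": 55.0,
        "mas": 60.0,
        "kvp": 29.0,
        "compression_force": 120.0,
        "implant_present": False,
        "agd": 1.5,
        "exposure_control_mode": "AUTOMATIC",
        "anode_target": "W",
        "filter_material": "Rh",
        "manufacturer": "VendorA",
        "model_name": "VendorA MammoUnit",
    }
    return CohortTable(pd.DataFrame([{**base, **r} for r in rows], columns=list(FIELDS)))


@pytest.fixture
def toy_table():
    """Two centers × few records, hand-checkable medians."""
    rows = []
    for i, agd in enumerate([1.0, 2.0, 3.0]):
        rows.append({"center_id": "C1", "exam_id": f"A{i}", "agd": agd, "cbt": 52.0})
    for i, agd in enumerate([2.0, 4.0]):
        rows.append({"center_id": "C2", "exam_id": f"B{i}", "agd": agd, "cbt": 53.0})
    return make_table(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic synthetic cohort shared across tests (~3.8k exams)."""
    cfg = SynthConfig(seed=7, size_factor=0.02)
    return generate_cohort(cfg)
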