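import numpy as np
import pytest

from mmpk.data import Dataset, DoseEvent, ObservationRecord, PatientRecord
from mmpk.synthetic import (CohortConfig5FU, CohortConfigSunitinib,
                            generate_5fu_cohort, generate_sunitinib_cohort)


@pytest.fixture(scope="session")
def fu5_cohort_small():
    """40-patient synthetic steady-state infusion cohort with ground truth."""
    return generate_5fu_cohort(CohortConfig5FU(n_patients=40), seed=3)


@pytest.fixture(scope="session")
def sunitinib_cohort_small():
    """8-patient synthetic oral cohort (2 cycles) with ground truth."""
    cfg = CohortConfigSunitinib(n_patients=8, max_cycles=2)
    return generate_sunitinib_cohort(cfg, seed=5)


@pytest.fixture
def toy_fu5_dataset():
    """Three hand-built patients on a single 24 h infusion of 4000 mg."""
    patients = []
    for i, values in enumerate([(0.70, 0.80), (0.55,), (0.90, 0.85, 0.75)]):
        pid = f"t{i + 1}"
        doses = [DoseEvent(pid, 0.0, 4000.0, 24.0, "iv_infusion")]
        obs = [ObservationRecord(pid, 18.0 + j, v, "parent")
               for j, v in enumerate(values)]
        cov = {"sex": float(i % 2), "age": 60.0 + i, "weight": 70.0 + 5 * i,
               "height": 170.0, "bsa": 1.9, "lbm": 55.0, "fm": 20.0}
        patients.append(PatientRecord(pid, cov, doses, obs))
    return Dataset(patients, "fu5", "toy")
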