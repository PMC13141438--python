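import numpy as np
import pandas as pd
import pytest

import cortiwin as cw
from cortiwin.windows import DynamicsPanel


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-patient null-effect cohort with missingness, shared across tests."""
    cfg = cw.scenario_config("null", 600, seed=42)
    return cw.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def complete_cohort():
    """A fully-observed null cohort (no laboratory missingness)."""
    cfg = cw.scenario_config("null-complete", 800, seed=7)
    return cw.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def complete_panel(complete_cohort):
    return DynamicsPanel(
        complete_cohort.dynamics,
        complete_cohort.patients["patient_id"].to_numpy(),
        complete_cohort.config.horizon_days,
    )


@pytest.fixture()
def toy_doses():
    """Hand-written dose events covering conversion, binning and pre-ARDS."""
    return pd.DataFrame(
        {
            "patient_id": [1, 1, 1, 2, 2, 3, 3, 3],
            "day_bin": [0, 1, 2, 0, 5, -3, -1, 4],
            "drug": [
                "prednisolone", "prednisolone", "prednisolone",
                "hydrocortisone", "dexamethasone",
                "methylprednisolone", "prednisone", "hydrocortisone",
            ],
            "dose_mg": [10.0, 10.0, 10.0, 200.0, 0.75, 40.0, 20.0, 100.0],
            "route": ["oral"] * 3 + ["intravenous"] * 2 + ["oral"] * 3,
        }
    )
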