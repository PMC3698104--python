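import numpy as np
import pytest

import hmbmtc as h


@pytest.fixture(scope="session")
def table1_net():
    return h.table1_fixture()


@pytest.fixture(scope="session")
def small_synthetic():
    """A small generated network with its ground truth."""
    cfg = h.GeneratorConfig(n_studies=10, seed=42)
    return h.generate_network(cfg)


@pytest.fixture(scope="session")
def small_fit(small_synthetic):
    """One desk-scale fit shared by summary/diagnostic tests."""
    net, truth = small_synthetic
    model = h.MTCModel.from_network(net, identifiability="corner")
    res = model.fit(chains=2, burn_in=800, draws=800, seed=7)
    return model, res, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def two_study_frame():
    """Well-formed 2-study, 4-arm CSV content used by I/O tests."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"study_id": "A", "class": "LNG_IUS", "time_months": 3, "scale": "MBL",
             "form": "COUNTS", "y": 20, "n": 25, "baseline_mean": 150.0},
            {"study_id": "A", "class": "TXA", "time_months": 3, "scale": "MBL",
             "form": "COUNTS", "y": 12, "n": 25, "baseline_mean": 180.0},
            {"study_id": "B", "class": "PLACEBO", "time_months": 3, "scale": "PBAC",
             "form": "COUNTS", "y": 4, "n": 30},
            {"study_id": "B", "class": "COC", "time_months": 3, "scale": "PBAC",
             "form": "COUNTS", "y": 18, "n": 30},
        ]
    )
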