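import json
from importlib import resources

import numpy as np
import pandas as pd
import pytest

from ewsbench.score_engine import load_default_definitions
from ewsbench.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def definitions():
    return load_default_definitions()


@pytest.fixture(scope="session")
def raw_definitions():
    """The JSON fixture dicts, for independent oracle reimplementations."""
    out = {}
    pkg = resources.files("ewsbench") / "definitions"
    for p in pkg.iterdir():
        if p.name.endswith(".json"):
            obj = json.loads(p.read_text())
            out[obj["name"]] = obj
    return out


@pytest.fixture(scope="session")
def default_cohort():
    """n=20000, seed=7 default synthetic cohort (complete, no missingness)."""
    return generate_cohort(CohortConfig(n=20000, seed=7)).records


@pytest.fixture(scope="session")
def default_scores(default_cohort, definitions):
    from ewsbench.score_engine import compute_all_scores

    return compute_all_scores(default_cohort, definitions)


@pytest.fixture
def normal_record():
    """All parameters in zero-point bands for the NEWS family."""
    return {
        "age": 85, "sex": "female", "hr": 80.0, "rr": 18.0, "sbp": 120.0,
        "dbp": 70.0, "map": np.nan, "temp": 36.8, "spo2": 97.0, "gcs": 15,
        "avpu": "A", "on_oxygen": False, "t2rf_risk": False,
        "outcome24h": False,
    }


def random_records(n, seed):
    """Uniform random records over the physiologic domains (grid oracle aid)."""
    rng = np.random.default_rng(seed)
    sbp = rng.uniform(40, 260, n).round(0)
    dbp = np.minimum(rng.uniform(20, 160, n).round(0), sbp - 1)
    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "age": rng.integers(80, 106, n),
        "sex": rng.choice(["female", "male"], n),
        "hr": rng.uniform(20, 220, n).round(0),
        "rr": rng.uniform(4, 60, n).round(0),
        "sbp": sbp,
        "dbp": dbp,
        "map": np.nan,
        "temp": rng.uniform(30, 42, n).round(1),
        "spo2": rng.uniform(50, 100, n).round(0),
        "gcs": rng.integers(3, 16, n),
        "avpu": rng.choice(["A", "V", "P", "U"], n),
        "on_oxygen": rng.random(n) < 0.3,
        "t2rf_risk": rng.random(n) < 0.3,
        "outcome24h": rng.random(n) < 0.1,
    })
    return df
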