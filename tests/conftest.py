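import numpy as np
import pandas as pd
import pytest

from aldpanel.cohort import CohortConfig, generate_cohort
from aldpanel.matrix import ProteinMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed fixed)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def biopsied_cohort():
    """Fully biopsied cohort (n=360) used by recovery-style tests."""
    cfg = CohortConfig(n_patients=360, seed=5)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def small_matrix(rng):
    """Random 20×10 linear matrix with a scattered missingness mask."""
    vals = np.exp2(rng.uniform(15, 25, size=(20, 10)))
    mask = rng.random((20, 10)) < 0.2
    vals[mask] = np.nan
    data = pd.DataFrame(
        vals,
        index=[f"P{i:02d}" for i in range(20)],
        columns=[f"S{j:02d}" for j in range(10)],
    )
    return ProteinMatrix(data, scale="linear")


def toy_meta(n=12, seed=0):
    """Small metadata table with covariates and all histology scores."""
    r = np.random.default_rng(seed)
    lob = r.integers(0, 4, n)
    bal = r.integers(0, 3, n)
    return pd.DataFrame(
        {
            "age": r.integers(30, 70, n),
            "bmi": np.round(r.uniform(20, 35, n), 1),
            "sex": r.choice(["male", "female"], n),
            "abstinent": r.random(n) < 0.5,
            "kleiner_f": r.integers(0, 5, n),
            "lobular": lob,
            "ballooning": bal,
            "activity_i": lob + bal,
            "steatosis_s": r.integers(0, 4, n),
        },
        index=pd.Index([f"S{i:02d}" for i in range(n)], name="sample_id"),
    )
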