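import numpy as np
import pandas as pd
import pytest

from tmscea.bundle import make_base_case_bundle
from tmscea.engine import ModelSettings


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def base_bundle():
    return make_base_case_bundle()


def random_alive_matrix(rng, diag_dominant=False):
    """Random 4x4 row-stochastic matrix."""
    m = rng.dirichlet(np.ones(4), size=4)
    if diag_dominant:
        m = 0.2 * m + 0.8 * np.eye(4)
    return m


def panel_from_states(states, visit_weeks):
    """Long panel frame from a (n_subjects, n_visits) state array."""
    states = np.asarray(states)
    n, k = states.shape
    return pd.DataFrame({
        "subject_id": np.repeat(np.arange(n), k),
        "visit_week": np.tile(visit_weeks, n),
        "state": states.ravel(),
    })
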