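import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from covnet import CohortConfig, fit_confound_model, generate_cohort, make_default_atlas, residualize_and_zscore


@pytest.fixture(scope="session")
def atlas():
    return make_default_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-structure cohort shared across tests."""
    cfg = CohortConfig(n_hc=40, n_svppa=15, n_nfvppa=15, seed=123)
    table, records = generate_cohort(cfg)
    return cfg, table, records


@pytest.fixture(scope="session")
def small_zscores(small_cohort):
    _, table, _ = small_cohort
    model = fit_confound_model(table)
    return residualize_and_zscore(table, model)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
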