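import numpy as np
import pytest

from netpercolate import Connectome, SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 12-subject cohort on 20 nodes for cheap smoke tests."""
    spec = SyntheticCohortSpec(n_subjects=12, n_nodes=20, n_modules=4, master_seed=5)
    return generate_cohort(spec)


@pytest.fixture()
def random_connectome():
    rng = np.random.default_rng(0)
    w = rng.random((20, 20))
    w = np.triu(w, 1)
    w = w + w.T
    return Connectome(W=w, subject_id="rand20")
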