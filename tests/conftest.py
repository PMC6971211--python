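import numpy as np
import pytest

import connlearn as cl


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic-condition cohort shared across tests."""
    spec = cl.CohortSpec(n_subjects=6, n_rois=30, n_scans=120, seed=3)
    return spec, cl.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_connectomes(small_cohort):
    _, cohort = small_cohort
    return [cl.build_connectome(ts) for ts in cohort]
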