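import warnings

import numpy as np
import pandas as pd
import pytest

from neuro1c import synthetic


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Library-level warnings (fallbacks, small families) are part of the
    contract being tested; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def cohort():
    """The default 136-subject five-group cohort."""
    return synthetic.generate_subjects(synthetic.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def null_assay(cohort):
    """Raw plates with no planted effects."""
    return synthetic.generate_raw_assay(cohort, [], seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_genotypes():
    subj = synthetic.generate_subjects(
        synthetic.CohortConfig(group_sizes={"HC-CN": 60, "PD-D": 60}, seed=3))
    specs = [synthetic.SNPSpec("snpA", 0.3), synthetic.SNPSpec("snpB", 0.25)]
    G = synthetic.generate_genotypes(subj, specs, seed=4)
    return subj, G
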