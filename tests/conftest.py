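import numpy as np
import pytest

from hetrobust.synth_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(seed=11, n_samples=6))


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """The same cohort written to disk as VCF/SEG/TSV fixtures."""
    outdir = tmp_path_factory.mktemp("cohort")
    generate_cohort(CohortConfig(seed=11, n_samples=6), outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
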