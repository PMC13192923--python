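import numpy as np
import pytest

from dynograph.cohort import CohortSpec, generate_cohort
from dynograph.pipeline import RunConfig, prepare_outcome


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-subject synthetic panel with planted ground truth."""
    spec = CohortSpec(n_subjects=150, seed=5)
    panel, truth = generate_cohort(spec)
    return panel, truth


@pytest.fixture(scope="session")
def prepared_continuous(small_cohort):
    """Preprocessed, graph-built, sequenced batches for the continuous outcome."""
    panel, _ = small_cohort
    config = RunConfig(out_dir="unused", simulate={})
    return prepare_outcome(panel, "continuous", config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
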