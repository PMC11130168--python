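import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsstyper import generate_cohort
from rsstyper.synthetic_cohort import CohortConfig

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# compact study conditions for unit tests; acceptance tests use the defaults
SMALL = dict(
    n_samples=90,
    n_genes=600,
    module_sizes=(50, 45, 40, 35, 30, 25),
    n_batches=3,
)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(seed=11, **SMALL)
    expr, ann, truth = generate_cohort(cfg)
    return cfg, expr, ann, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
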