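import numpy as np
import pytest

from eigenvault.synthetic import DEFAULT_PRESETS, CohortSpec, generate_cohort

COHORT_SEED = 1
N_PER_GROUP = 20


def build_default_cohort(seed=COHORT_SEED, n=N_PER_GROUP, with_params=False):
    """The standard three-group synthetic cohort (georgia/hungary/modern)."""
    cohort, params = [], []
    for offset, (group, dist) in enumerate(sorted(DEFAULT_PRESETS.items())):
        spec = CohortSpec(group=group, n=n, param_distributions=dist, seed=seed + offset)
        co, pa = generate_cohort(spec, return_params=True)
        cohort.extend(co)
        params.extend(pa)
    return (cohort, params) if with_params else cohort


@pytest.fixture(scope="session")
def default_cohort():
    return build_default_cohort()


@pytest.fixture(scope="session")
def whole_report(default_cohort):
    from eigenvault.pipeline import run_whole_outline

    return run_whole_outline(default_cohort, seed=COHORT_SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
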