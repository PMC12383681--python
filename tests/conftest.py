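import numpy as np
import pytest

from petctrad.preprocess import preprocess_sample
from petctrad.synthetic import (
    DEFAULT_CLASS_PARAMS,
    DEFAULT_SITES,
    CohortConfig,
    generate_cohort,
    make_case,
)


@pytest.fixture(scope="session")
def lesion_pair():
    """One preprocessed lesion per class (site internal, fixed seeds)."""
    out = {}
    for label in (0, 1):
        s = make_case(
            DEFAULT_CLASS_PARAMS[label],
            DEFAULT_SITES[0],
            (1.0, 1.0, 1.0),
            seed=100 + label,
            label=label,
            lesion_id=f"fixture_{label}",
        )
        out[label] = preprocess_sample(s)
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-site cohort (8 lesions/class/site), preprocessed."""
    config = CohortConfig(n_per_class_per_site=8, seed=42)
    return [preprocess_sample(s) for s in generate_cohort(config)]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
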