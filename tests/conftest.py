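import numpy as np
import pytest

from aanconn.connectivity import AdjacencyMatrix
from aanconn.synthetic import GenerativeSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def aan_spec():
    return GenerativeSpec(rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort(aan_spec):
    """Default 7-subject cohort without label volumes (fast)."""
    return generate_cohort(aan_spec, volumes=False)


@pytest.fixture(scope="session")
def volume_cohort():
    """Default cohort including NIfTI-style label volumes."""
    return generate_cohort(GenerativeSpec(rng_seed=11), volumes=True)


def make_adjacency(a, labels=None, th=0.5):
    a = np.asarray(a, dtype=np.int8)
    if labels is None:
        labels = [f"n{i}" for i in range(a.shape[0])]
    return AdjacencyMatrix(labels=labels, a=a, threshold_used=th)
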