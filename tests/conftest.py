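import numpy as np
import pytest

from tiseries.agents import (
    HUMAN_REPRESENTATIONAL,
    MONKEY_REPRESENTATIONAL,
    MONKEY_RT,
    generate_cohort,
)
from tiseries.schedule import HUMAN, MONKEY, Pair, make_items


@pytest.fixture(scope="session")
def items7():
    return {it.label: it for it in make_items(7)}


@pytest.fixture(scope="session")
def pair7(items7):
    def make(label: str) -> Pair:
        return Pair(items7[label[0]], items7[label[1]])

    return make


@pytest.fixture(scope="session")
def monkey_cohort(pair7):
    """Small monkey-like representational cohort with RTs (3 x 10 sessions)."""
    return generate_cohort(
        MONKEY, MONKEY_REPRESENTATIONAL, MONKEY_RT, n_subjects=3, seed=101,
        sessions_per_subject=10,
    )


@pytest.fixture(scope="session")
def human_cohort():
    """Task-naive human-like cohort: 33 subjects x 1 session, no RTs."""
    return generate_cohort(
        HUMAN, HUMAN_REPRESENTATIONAL, None, n_subjects=33, seed=202
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
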