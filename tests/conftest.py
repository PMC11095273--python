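import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from catlet.patterns import all_patterns
from catlet.synthetic import SyntheticCohortConfig, generate_cohort
from catlet.weights import SegmentWeightTable, illustrative_weight_table


@pytest.fixture(scope="session")
def weight_table() -> SegmentWeightTable:
    return illustrative_weight_table()


def toy_table(segments: dict[str, float], name: str = "toy") -> SegmentWeightTable:
    """Weight table using the same segment map for all 54 patterns."""
    import math

    return SegmentWeightTable(
        name=name,
        normalization=math.fsum(segments.values()),
        patterns={key: dict(segments) for key in all_patterns()},
    )


@pytest.fixture(scope="session")
def small_cohort(weight_table):
    """One fixed synthetic cohort shared across read-only tests."""
    config = SyntheticCohortConfig(n=400, seed=7)
    patients, outcomes, truth = generate_cohort(config, weight_table)
    return patients, outcomes, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240513)
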