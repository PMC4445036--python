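import numpy as np
import pytest

from oscal.overlap_core import OverlapCase
from oscal.synthetic_data import table1_cases


@pytest.fixture(scope="session")
def reference_cases() -> dict[str, OverlapCase]:
    return table1_cases()


@pytest.fixture(scope="session")
def random_cases():
    """10^5 random valid overlap cases as parallel integer arrays
    (m, n, d, N), d >= 1."""
    rng = np.random.default_rng(20240901)
    size = 100_000
    N = rng.integers(10, 100_000, size=size)
    m = rng.integers(1, N + 1)
    n = rng.integers(1, N + 1)
    d = rng.integers(1, np.minimum(m, n) + 1)
    return m, n, d, N


@pytest.fixture()
def toy_index():
    from oscal.relation_scoring import AnnotationIndex

    return AnnotationIndex(
        forward={
            "A": frozenset({"1", "2"}),
            "B": frozenset({"2", "3"}),
            "C": frozenset({"4"}),
        }
    )
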