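import numpy as np
import pytest

from metabias import MetaAnalysis


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def five_study_meta():
    """Hand-written meta-analysis: varied sizes, arms and exposure rates."""
    return MetaAnalysis.from_counts(
        [
            (12, 18, 8, 22),
            (30, 28, 45, 40),
            (60, 70, 90, 95),
            (9, 5, 11, 12),
            (100, 110, 80, 125),
        ]
    )


@pytest.fixture
def six_study_meta():
    """Six studies with a visible small-study trend for rank-test oracles."""
    return MetaAnalysis.from_counts(
        [
            (14, 6, 6, 14),
            (18, 12, 12, 18),
            (25, 20, 25, 30),
            (55, 45, 45, 55),
            (95, 85, 105, 115),
            (190, 180, 210, 220),
        ]
    )


@pytest.fixture
def size_ladder_meta():
    """Five studies with n1 = n2 in {20, 40, 80, 160, 320}."""
    return MetaAnalysis.from_counts(
        [
            (8, 5, 12, 15),
            (14, 12, 26, 28),
            (30, 24, 50, 56),
            (55, 50, 105, 110),
            (110, 100, 210, 220),
        ]
    )


@pytest.fixture
def equal_size_meta():
    """All studies share (n1, n2) = (30, 30): smoothed se is constant."""
    return MetaAnalysis.from_counts(
        [
            (12, 9, 18, 21),
            (15, 11, 15, 19),
            (10, 13, 20, 17),
            (14, 10, 16, 20),
        ]
    )


def random_table_counts(rng, max_arm=80):
    """Random (a, b, c, d) with strictly positive cells (logOR defined)."""
    n1 = int(rng.integers(2, max_arm))
    n2 = int(rng.integers(2, max_arm))
    a = int(rng.integers(1, n1))
    b = int(rng.integers(1, n2))
    return a, b, n1 - a, n2 - b
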