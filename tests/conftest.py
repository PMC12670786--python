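import math

import pytest

from platrand import (
    BrickTunnel,
    BrickTunnel2,
    CompleteRandomization,
    HanMinimization,
    IntegerRatio,
    PermutedBlock,
    map_equal_to_unequal,
    normalize_ratio,
)


@pytest.fixture
def ratio_557():
    return normalize_ratio((5, 5, 7))


@pytest.fixture
def ratio_12():
    return normalize_ratio((1, 2))


@pytest.fixture
def sqrt2_ratio():
    return normalize_ratio((1, 1, math.sqrt(2)))


def procedure_matrix():
    """Small, diverse set of (name, procedure, n) for cross-cutting checks."""
    return [
        ("cr-557", CompleteRandomization(normalize_ratio((5, 5, 7))), 8),
        ("pbr-223", PermutedBlock(IntegerRatio((2, 2, 3))), 8),
        ("mapped-12", map_equal_to_unequal(IntegerRatio((1, 2))), 9),
        ("han-12", HanMinimization(normalize_ratio((1, 2))), 9),
        ("btr2-12", BrickTunnel2(normalize_ratio((1, 2))), 9),
        ("btr-557", BrickTunnel(normalize_ratio((5, 5, 7))), 10),
    ]
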