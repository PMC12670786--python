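"""Target allocation ratios and their integer approximations.

An allocation ratio ``r_1 : ... : r_K`` over ``K >= 2`` arms may have
arbitrary positive real weights (``1:1:sqrt(2)`` is the canonical example:
the square-root rule that maximizes the joint power of K pairwise
comparisons against a shared control).  Internally every weight is carried
as an exact ``Fraction`` — integers exactly, floats as their exact binary
value — so allocation proportions sum to 1 exactly and downstream dynamic
programming stays in rational arithmetic.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Sequence

import numpy as np

__all__ = [
    "AllocationRatio",
    "IntegerRatio",
    "normalize_ratio",
    "integer_approximation",
    "parse_ratio",
]


@dataclass(frozen=True)
class AllocationRatio:
    """Target weights ``r_1..r_K`` and derived proportions ``rho_j = r_j / sum r``."""

    weights: tuple[Fraction, ...]

    def __post_init__(self):
        if len(self.weights) < 2:
            raise ValueError("an allocation ratio needs at least two arms")
        ws = tuple(Fraction(w) for w in self.weights)
        if any(w <= 0 for w in ws):
            raise ValueError("nonpositive weight: closed arms must be removed, not zero-weighted")
        object.__setattr__(self, "weights", ws)

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def proportions(self) -> tuple[Fraction, ...]:
        total = sum(self.weights)
        return tuple(w / total for w in self.weights)

    @property
    def proportions_float(self) -> np.ndarray:
        return np.array([float(p) for p in self.proportions])

    @property
    def is_rational(self) -> bool:
        """True when every weight was given as an exact rational (int/Fraction)."""
        return all(w.denominator < 10**6 for w in self.weights)

    def drop_arm(self, index: int) -> "AllocationRatio":
        """Ratio with one arm removed and the rest renormalized."""
        if self.k == 2:
            raise ValueError("cannot drop an arm from a two-arm ratio")
        ws = self.weights[:index] + self.weights[index + 1 :]
        return AllocationRatio(ws)

    def __repr__(self):
        def fmt(w: Fraction) -> str:
            return str(w.numerator) if w.denominator == 1 else f"{float(w):g}"

        return "AllocationRatio(" + ":".join(fmt(w) for w in self.weights) + ")"


@dataclass(frozen=True)
class IntegerRatio:
    """Reduced integer ratio ``Q_1 : ... : Q_K`` with block size ``S = sum Q_j``."""

    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) < 2:
            raise ValueError("an integer ratio needs at least two arms")
        if any(int(q) != q or q <= 0 for q in self.counts):
            raise ValueError("counts must be positive integers")
        cs = tuple(int(q) for q in self.counts)
        g = 0
        for q in cs:
            g = gcd(g, q)
        object.__setattr__(self, "counts", tuple(q // g for q in cs))

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def block_size(self) -> int:
        return sum(self.counts)

    def as_ratio(self) -> AllocationRatio:
        return AllocationRatio(tuple(Fraction(q) for q in self.counts))

    def __repr__(self):
        return "IntegerRatio(" + ":".join(str(q) for q in self.counts) + ")"


def normalize_ratio(weights: Sequence) -> AllocationRatio:
    """Build an :class:`AllocationRatio` from positive weights.

    Scale-invariant: ``normalize_ratio(w)`` and ``normalize_ratio(c*w)`` have
    identical proportions for any ``c > 0``.
    """
    return AllocationRatio(tuple(Fraction(w) for w in weights))


def integer_approximation(ratio: AllocationRatio, max_block: int) -> IntegerRatio:
    """Best integer approximation ``Q_1:...:Q_K`` with block size ``<= max_block``.

    Minimizes ``max_j |Q_j/S - rho_j|`` over all positive integer compositions
    with ``S = sum Q_j <= max_block``; ties are broken toward the smaller block
    size, then the lexicographically smallest counts.  ``1:1:sqrt(2)`` gives
    ``5:5:7`` at ``max_block=17`` and ``2:2:3`` at ``max_block=7``.
    """
    K = ratio.k
    if max_block < K:
        raise ValueError(f"max_block must be at least the number of arms ({K})")
    rho = ratio.proportions
    best = None  # (max deviation, block size, counts)
    for S in range(K, max_block + 1):
        # The minimax-optimal composition for a given S has each Q_j within 1
        # of S*rho_j; scan a +-1 window around the rounded values.
        windows = []
        for j in range(K):
            t = S * rho[j]
            lo = max(1, math.floor(t) - 1)
            hi = math.ceil(t) + 1
            windows.append(range(lo, hi + 1))
        for combo in itertools.product(*windows):
            if sum(combo) != S:
                continue
            dev = max(abs(Fraction(q, S) - rho[j]) for j, q in enumerate(combo))
            key = (dev, S, combo)
            if best is None or key < best:
                best = key
    assert best is not None
    return IntegerRatio(best[2])


_SQRT_RE = re.compile(r"^sqrt\(\s*([0-9.]+)\s*\)$")


def parse_ratio(text: str) -> AllocationRatio:
    """Parse a ratio string like ``"5:5:7"`` or ``"1:1:sqrt(2)"``.

    Accepted terms: integers, decimals, and ``sqrt(x)``.
    """
    weights = []
    for term in text.split(":"):
        term = term.strip()
        m = _SQRT_RE.match(term)
        if m:
            weights.append(Fraction(math.sqrt(float(m.group(1)))))
            continue
        try:
            weights.append(Fraction(term))
        except ValueError as exc:
            raise ValueError(f"cannot parse ratio term {term!r}") from exc
    return normalize_ratio(weights)
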