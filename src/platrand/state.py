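"""Trial state and the sequential-procedure contract.

Every randomization method in this package is a :class:`Procedure`: a rule
that, given its internal state, yields a finite set of transitions
``(arm, probability, next_state)``.  Exposing transitions (rather than only
arm probabilities) lets the diagnostics module run exact forward dynamic
programming over the internal chain — several internal states may emit the
same arm (e.g. pooled "fake" arms of a mapping construction), and exactness
requires following the chain, not just the emitted arms.

Transition probabilities are ``fractions.Fraction`` throughout, so the
unconditional allocation profile of a procedure can be certified exactly.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable

import numpy as np

from .ratio import AllocationRatio

__all__ = ["TrialState", "Procedure", "Transition"]


@dataclass(frozen=True)
class TrialState:
    """Arm totals ``N_i1..N_iK`` after the i-th allocation (step 0 = empty trial)."""

    totals: tuple[int, ...]

    def __post_init__(self):
        if any(int(n) != n or n < 0 for n in self.totals):
            raise ValueError("arm totals must be nonnegative integers")
        object.__setattr__(self, "totals", tuple(int(n) for n in self.totals))

    @property
    def step(self) -> int:
        return sum(self.totals)

    def allocate(self, arm: int) -> "TrialState":
        t = list(self.totals)
        t[arm] += 1
        return TrialState(tuple(t))


Transition = tuple[int, Fraction, Hashable]  # (arm, probability, next internal state)


class Procedure(ABC):
    """Sequential allocation rule over ``K`` arms.

    Subclasses define the internal-state chain; the base class provides
    simulation and conditional arm probabilities.  Internal states must be
    hashable; ``totals(state)`` maps a state to the emitted arm totals.
    """

    ratio: AllocationRatio
    is_fixed: bool = True  # schedule can be pre-generated

    @property
    def k(self) -> int:
        return self.ratio.k

    @abstractmethod
    def initial_state(self) -> Hashable:
        ...

    @abstractmethod
    def transitions(self, state: Hashable) -> list[Transition]:
        """All positive-probability moves from ``state``; probabilities sum to 1."""

    def totals(self, state: Hashable) -> tuple[int, ...]:
        """Arm totals associated with an internal state (default: the state itself)."""
        return state

    def conditional_probs(self, state: Hashable) -> np.ndarray:
        """Probability of each arm for the next allocation, given ``state``."""
        p = np.zeros(self.k)
        for arm, prob, _ in self.transitions(state):
            p[arm] += float(prob)
        return p

    def simulate(self, n: int, rng: np.random.Generator) -> list[int]:
        """Draw one allocation sequence of length ``n``; returns arm indices."""
        state = self.initial_state()
        arms = []
        for _ in range(n):
            trans = self.transitions(state)
            probs = np.array([float(p) for _, p, _ in trans])
            idx = rng.choice(len(trans), p=probs / probs.sum())
            arm, _, state = trans[idx]
            arms.append(arm)
        return arms
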