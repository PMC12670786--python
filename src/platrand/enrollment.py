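"""Synthetic enrollment streams for exercising eligibility and supply logic.

Participants arrive one at a time; each carries a subpopulation label (its
eligibility class under a two-step scheme), a set of arms it is eligible
for, and a center.  The generator is fully seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = ["Participant", "gen_enrollment"]


@dataclass(frozen=True)
class Participant:
    id: str
    subpopulation: str
    eligible: frozenset[str]
    center: str
    arrival: int

    def __post_init__(self):
        if not self.eligible:
            raise ValueError("a participant must be eligible for at least one arm")


def gen_enrollment(
    n: int,
    arms: Sequence[str],
    seed: int,
    subpop_mix: Optional[Mapping[str, float]] = None,
    center_mix: Optional[Mapping[str, float]] = None,
    ineligibility_rates: Optional[Mapping[str, float]] = None,
    subpop_eligibility: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[Participant]:
    """Generate a reproducible stream of ``n`` participants.

    ``subpop_mix`` and ``center_mix`` are probability vectors over labels
    (defaults: a single subpopulation / single center).  Eligibility is
    ``subpop_eligibility[subpop]`` when given; otherwise every arm is kept
    independently, dropped with its ``ineligibility_rates`` probability
    (redrawn if the set would come out empty).  Arrival order interleaves
    centers uniformly at random because centers are drawn i.i.d.
    """
    rng = np.random.default_rng(seed)
    if subpop_mix is None:
        subpop_mix = {"1": 1.0}
    if center_mix is None:
        center_mix = {"C01": 1.0}
    sp_labels = list(subpop_mix)
    sp_probs = np.array([subpop_mix[s] for s in sp_labels], dtype=float)
    if not np.isclose(sp_probs.sum(), 1.0):
        raise ValueError("subpop_mix must sum to 1")
    c_labels = list(center_mix)
    c_probs = np.array([center_mix[c] for c in c_labels], dtype=float)
    if not np.isclose(c_probs.sum(), 1.0):
        raise ValueError("center_mix must sum to 1")
    out = []
    for i in range(n):
        sp = sp_labels[rng.choice(len(sp_labels), p=sp_probs)]
        center = c_labels[rng.choice(len(c_labels), p=c_probs)]
        if subpop_eligibility is not None:
            elig = frozenset(subpop_eligibility[sp])
        elif ineligibility_rates:
            while True:
                elig = frozenset(
                    a for a in arms if rng.random() >= ineligibility_rates.get(a, 0.0)
                )
                if elig:
                    break
        else:
            elig = frozenset(arms)
        out.append(
            Participant(
                id=f"P{i + 1:05d}", subpopulation=sp, eligible=elig, center=center, arrival=i
            )
        )
    return out
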