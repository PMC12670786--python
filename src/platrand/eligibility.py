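"""Eligibility-aware randomization for arms with differing entry criteria.

Two mechanisms are provided:

**Two-step (batch) randomization.**  Each investigational arm is paired
with its own matching control in a *batch*; a participant is first
randomized to one of the batches it is eligible for (per-subpopulation
batch probabilities), then within the batch to treatment vs. control at a
fixed ratio (default 2:1, via an ARP mapped permuted block per batch).
When controls are pooled across batches for analysis, subpopulations can
end up disproportionately represented between an arm and its pooled
control; :func:`expected_composition` computes those expected counts and
control:treatment ratios exactly.

**Skip-and-backfill.**  Participants follow a single central schedule,
skipping slots whose arm they are not eligible for (or whose kit their
center lacks); bypassed slots stay open and are backfilled by later
eligible participants, earliest slot first.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .enrollment import Participant
from .procedures import map_equal_to_unequal
from .ratio import IntegerRatio
from .schedule import Schedule

__all__ = [
    "Batch",
    "TwoStepScheme",
    "TwoStepRandomizer",
    "two_step_randomize",
    "expected_composition",
    "example_scheme",
    "skip_and_backfill_assign",
]

F = Fraction


@dataclass(frozen=True)
class Batch:
    """An investigational arm with its matching control and within-batch ratio."""

    name: str
    treatment: str
    control: str
    ratio: IntegerRatio = IntegerRatio((2, 1))  # treatment : control

    @property
    def treatment_fraction(self) -> Fraction:
        q = self.ratio.counts
        return F(q[0], q[0] + q[1])

    @property
    def control_fraction(self) -> Fraction:
        return 1 - self.treatment_fraction


@dataclass(frozen=True)
class TwoStepScheme:
    """Batches plus per-subpopulation batch probabilities.

    ``batch_probs[subpop]`` maps batch names to probabilities; each
    subpopulation's probabilities must sum to 1 and be zero (absent) on
    batches it is not eligible for.
    """

    batches: tuple[Batch, ...]
    batch_probs: Mapping[str, Mapping[str, Fraction]]

    def __post_init__(self):
        names = {b.name for b in self.batches}
        for sp, probs in self.batch_probs.items():
            unknown = set(probs) - names
            if unknown:
                raise ValueError(f"subpopulation {sp!r} references unknown batches {unknown}")
            total = sum(F(p) for p in probs.values())
            if total != 1:
                raise ValueError(f"batch probabilities for subpopulation {sp!r} sum to {total}, not 1")
            if any(F(p) < 0 for p in probs.values()):
                raise ValueError("batch probabilities must be nonnegative")

    def batch(self, name: str) -> Batch:
        return next(b for b in self.batches if b.name == name)

    def eligible_batches(self, subpop: str) -> list[str]:
        if subpop not in self.batch_probs:
            raise KeyError(f"unknown subpopulation {subpop!r}")
        return [name for name, p in self.batch_probs[subpop].items() if F(p) > 0]

    @classmethod
    def from_json(cls, path) -> "TwoStepScheme":
        with open(path, encoding="utf-8") as fh:
            cfg = json.load(fh)
        batches = tuple(
            Batch(
                b["name"],
                b["treatment"],
                b["control"],
                IntegerRatio(tuple(b.get("ratio", (2, 1)))),
            )
            for b in cfg["batches"]
        )
        probs = {
            sp: {name: F(p) for name, p in mapping.items()}
            for sp, mapping in cfg["subpopulations"].items()
        }
        return cls(batches, probs)

    def to_json(self, path) -> None:
        cfg = {
            "batches": [
                {
                    "name": b.name,
                    "treatment": b.treatment,
                    "control": b.control,
                    "ratio": list(b.ratio.counts),
                }
                for b in self.batches
            ],
            "subpopulations": {
                sp: {name: str(F(p)) for name, p in mapping.items()}
                for sp, mapping in self.batch_probs.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(cfg, fh, indent=2)


def example_scheme() -> TwoStepScheme:
    """Three investigational arms, two eligibility subpopulations.

    Subpopulation 1 (eligible for everything) enters batch A with
    probability 1/2, B with 1/8, C with 3/8; subpopulation 2 (not eligible
    for E3) enters A with 6/8 and B with 2/8.  Within every batch the
    treatment:control ratio is 2:1.
    """
    batches = (
        Batch("A", "E1", "C1"),
        Batch("B", "E2", "C2"),
        Batch("C", "E3", "C3"),
    )
    probs = {
        "1": {"A": F(1, 2), "B": F(1, 8), "C": F(3, 8)},
        "2": {"A": F(6, 8), "B": F(2, 8)},
    }
    return TwoStepScheme(batches, probs)


class TwoStepRandomizer:
    """Stateful two-step randomizer.

    The first step draws a batch independently per participant from its
    subpopulation's probabilities; the second step allocates within the
    batch through a persistent ARP generator (a mapped permuted block at
    the batch's treatment:control ratio), so within each batch the
    unconditional ratio is preserved at every allocation.
    """

    def __init__(self, scheme: TwoStepScheme, seed: int):
        self.scheme = scheme
        self.rng = np.random.default_rng(seed)
        self._inner = {
            b.name: map_equal_to_unequal(b.ratio) for b in scheme.batches
        }
        self._inner_state = {name: proc.initial_state() for name, proc in self._inner.items()}

    def assign(self, p: Participant) -> tuple[str, str]:
        """Returns ``(batch name, arm label)`` for one participant."""
        probs = self.scheme.batch_probs.get(p.subpopulation)
        if probs is None:
            raise KeyError(f"unknown subpopulation {p.subpopulation!r}")
        names = list(probs)
        weights = np.array([float(F(probs[n])) for n in names])
        batch_name = names[self.rng.choice(len(names), p=weights / weights.sum())]
        batch = self.scheme.batch(batch_name)
        proc = self._inner[batch_name]
        state = self._inner_state[batch_name]
        trans = proc.transitions(state)
        tp = np.array([float(pr) for _, pr, _ in trans])
        idx = self.rng.choice(len(trans), p=tp / tp.sum())
        arm_idx, _, new_state = trans[idx]
        self._inner_state[batch_name] = new_state
        arm = batch.treatment if arm_idx == 0 else batch.control
        return batch_name, arm


def two_step_randomize(p: Participant, scheme: TwoStepScheme, seed: int) -> tuple[str, str]:
    """One-off two-step assignment (a fresh randomizer seeded per call)."""
    return TwoStepRandomizer(scheme, seed).assign(p)


def expected_composition(
    scheme: TwoStepScheme, subpop_counts: Mapping[str, int]
) -> pd.DataFrame:
    """Expected per-(subpopulation, arm) treatment and pooled-control counts.

    For a subpopulation with ``n`` enrollees and an investigational arm it
    is eligible for, the expected treatment count is
    ``n * P(own batch) * treatment fraction`` and the expected contribution
    to the arm's eligibility-matched pooled control is
    ``n * sum over its eligible batches of P(batch) * control fraction``
    (every control drawn from a batch the subpopulation can enter is
    eligible for the arm).  Arithmetic is exact; the ratio column is the
    control:treatment ratio normalized to ``1:x``.
    """
    if any(c < 0 for c in subpop_counts.values()):
        raise ValueError("subpopulation counts must be nonnegative")
    rows = []
    for sp, count in subpop_counts.items():
        probs = {k: F(v) for k, v in scheme.batch_probs[sp].items()}
        pooled_control = sum(
            probs[name] * scheme.batch(name).control_fraction for name in probs
        )
        for batch in scheme.batches:
            if batch.name not in probs:
                continue
            treat = count * probs[batch.name] * batch.treatment_fraction
            control = count * pooled_control
            ratio = "n/a" if treat == 0 else f"1:{float(treat / control):g}"
            rows.append(
                {
                    "subpopulation": sp,
                    "batch": batch.name,
                    "treatment": batch.treatment,
                    "expected_treatment": float(treat),
                    "expected_pooled_control": float(control),
                    "control_to_treatment": ratio,
                }
            )
    return pd.DataFrame(rows)


def skip_and_backfill_assign(
    p: Participant,
    sched: Schedule,
    inventory=None,
) -> Optional[int]:
    """Assign ``p`` to the earliest feasible open slot of the schedule.

    A slot is feasible when its arm is in ``p.eligible`` and, if a
    :class:`~platrand.supply.CenterInventory` is supplied, the kit for its
    arm is on hand at ``p``'s center.  Pending slots bypassed on the way
    are marked ``skipped-open`` and stay claimable.  Returns the assigned
    slot's seq, or ``None`` (with a warning) when no slot is feasible —
    the participant stays queued.
    """
    bypassed = []
    for slot in sched.open_slots():
        feasible = slot.arm in p.eligible and (
            inventory is None or inventory.available(slot.arm)
        )
        if feasible:
            for b in bypassed:
                if b.status == "pending":
                    b.status = "skipped-open"
            sched.assign(slot.seq, p.id)
            if inventory is not None:
                inventory.dispense(slot.arm, p.id)
            return slot.seq
        bypassed.append(slot)
    warnings.warn(f"no feasible slot for participant {p.id}; queued", stacklevel=2)
    return None
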