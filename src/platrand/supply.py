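"""Drug-supply-constrained allocation at trial centers.

Central randomization makes assignments at any one center unpredictable,
so naively every center must stock every arm's kit at all times.  Two
economical policies avoid that:

- **Block (modified Zelen) policy** — each center holds one full block of
  kits (one per arm).  Participants take the earliest open slot of the
  central schedule whose kit is on hand; slots a center cannot serve are
  skipped and backfilled from other centers.  A replacement block ships
  only once the center has used up its current block, so low-enrolling
  centers never receive a second block.

- **Partial-supply policy** — centers hold only ``c`` kits (``c`` smaller
  than the number of arms, e.g. 3 kits in a 7-arm trial).  Resupplies of
  ``c`` kits ship after every ``c`` randomizations at the center, their
  composition chosen to cover the earliest open central-schedule slots
  the center cannot currently serve.

Every shipment and dispensation is logged, and dispensed kits never exceed
shipped kits per center and arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .eligibility import skip_and_backfill_assign
from .enrollment import Participant
from .schedule import Schedule

__all__ = [
    "CenterInventory",
    "ZelenBlockPolicy",
    "PartialSupplyPolicy",
    "simulate_supply",
]


@dataclass
class CenterInventory:
    """Per-arm kit counts on hand at one center, with full traceability."""

    center: str
    on_hand: dict[str, int] = field(default_factory=dict)
    shipment_log: list[dict] = field(default_factory=list)
    dispense_log: list[dict] = field(default_factory=list)
    randomized: int = 0

    def available(self, arm: str) -> bool:
        return self.on_hand.get(arm, 0) > 0

    def receive(self, kits: dict[str, int], trigger: str) -> None:
        for arm, count in kits.items():
            self.on_hand[arm] = self.on_hand.get(arm, 0) + count
        self.shipment_log.append(
            {"center": self.center, "kits": dict(kits), "trigger": trigger}
        )

    def dispense(self, arm: str, participant_id: str) -> None:
        if self.on_hand.get(arm, 0) <= 0:
            raise ValueError(f"no {arm!r} kit on hand at center {self.center}")
        self.on_hand[arm] -= 1
        self.randomized += 1
        self.dispense_log.append(
            {"center": self.center, "arm": arm, "participant_id": participant_id}
        )

    @property
    def total_on_hand(self) -> int:
        return sum(self.on_hand.values())

    def resupplied_at(self, n: int) -> bool:
        return any(s.get("trigger") == f"after-{n}" for s in self.shipment_log)


class ZelenBlockPolicy:
    """One kit per arm initially; a full replacement block on exhaustion."""

    name = "zelen-block"

    def __init__(self, arms: Sequence[str]):
        self.arms = tuple(arms)

    def initial_shipment(self, inv: CenterInventory, sched: Schedule) -> dict[str, int]:
        return {arm: 1 for arm in self.arms}

    def resupply(self, inv: CenterInventory, sched: Schedule) -> Optional[dict[str, int]]:
        if inv.total_on_hand == 0:
            return {arm: 1 for arm in self.arms}
        return None


class PartialSupplyPolicy:
    """``c`` kits initially and after every ``c`` randomizations at a center.

    Shipment composition: one kit for each of the earliest open central
    slots whose arm the center cannot currently cover (counting kits
    already in the shipment being built); padded round-robin over the
    trial's arms if the open schedule does not need ``c`` kits.
    """

    name = "partial"

    def __init__(self, c: int, arms: Sequence[str]):
        if c < 1:
            raise ValueError("shipment size c must be positive")
        self.c = c
        self.arms = tuple(arms)

    def _cover(self, inv: CenterInventory, sched: Schedule) -> dict[str, int]:
        kits: dict[str, int] = {}
        virtual = dict(inv.on_hand)
        for slot in sched.open_slots():
            if sum(kits.values()) >= self.c:
                break
            if virtual.get(slot.arm, 0) > 0:
                virtual[slot.arm] -= 1
                continue
            kits[slot.arm] = kits.get(slot.arm, 0) + 1
        pad = 0
        while sum(kits.values()) < self.c:
            arm = self.arms[pad % len(self.arms)]
            kits[arm] = kits.get(arm, 0) + 1
            pad += 1
        return kits

    def initial_shipment(self, inv: CenterInventory, sched: Schedule) -> dict[str, int]:
        return self._cover(inv, sched)

    def resupply(self, inv: CenterInventory, sched: Schedule) -> Optional[dict[str, int]]:
        if inv.randomized > 0 and inv.randomized % self.c == 0 and not inv.resupplied_at(inv.randomized):
            return self._cover(inv, sched)
        return None


def simulate_supply(
    centers: Iterable[str],
    policy,
    stream: Sequence[Participant],
    sched: Schedule,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, CenterInventory]]:
    """Run supply-constrained central randomization over an enrollment stream.

    Each participant takes the earliest open slot of the central schedule
    whose arm is both in their eligible set and on hand at their center
    (skip-and-backfill); the policy decides shipments.  Returns the
    assignment log, the shipment log, and the final inventories.
    """
    invs = {c: CenterInventory(c) for c in centers}
    for inv in invs.values():
        inv.receive(policy.initial_shipment(inv, sched), trigger="initial")
    assignments = []
    for p in stream:
        if p.center not in invs:
            raise ValueError(f"participant {p.id} at unknown center {p.center!r}")
        inv = invs[p.center]
        seq = skip_and_backfill_assign(p, sched, inventory=inv)
        arm = None
        if seq is not None:
            arm = next(s.arm for s in sched.slots if s.seq == seq)
            kits = policy.resupply(inv, sched)
            if kits:
                inv.receive(kits, trigger=f"after-{inv.randomized}")
        assignments.append(
            {
                "participant_id": p.id,
                "center": p.center,
                "seq": seq,
                "arm": arm,
                "queued": seq is None,
            }
        )
    shipments = [s for inv in invs.values() for s in inv.shipment_log]
    return pd.DataFrame(assignments), pd.DataFrame(shipments), invs
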