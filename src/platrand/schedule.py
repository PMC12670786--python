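"""Randomization schedules: slots, segments, CSV round-trip.

A schedule is the ordered list of treatment assignments to be handed to
participants.  Platform-trial adaptations (arm addition, closure, ratio
changes) partition it into *segments* — maximal runs with a fixed active
arm set and target ratio — and the skip-and-backfill mechanics require
per-slot status beyond assigned/pending.

Slot statuses:
  ``pending``       not yet offered to anyone
  ``assigned``      taken by a participant (immutable thereafter)
  ``skipped-open``  bypassed by an ineligible/unsupplied participant,
                    still claimable by a later one
  ``void``          cancelled at a segment boundary, never to be issued
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .state import Procedure

__all__ = [
    "Slot",
    "Segment",
    "Schedule",
    "generate_schedule",
    "read_schedule",
    "write_schedule",
    "default_labels",
]

STATUSES = ("pending", "assigned", "skipped-open", "void")


@dataclass
class Slot:
    seq: int
    stratum: str
    segment: int
    arm: str
    status: str = "pending"
    participant_id: Optional[str] = None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown slot status {self.status!r}")


@dataclass(frozen=True)
class Segment:
    segment_id: int
    arms: tuple[str, ...]
    ratio: str  # display form, e.g. "5:5:7"
    reason: str = "initial"  # initial | arm-added | arm-closed | ratio-change


@dataclass
class Schedule:
    slots: list[Slot]
    segments: list[Segment] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        seen = set()
        last_seq = 0
        last_seg = None
        seg_ids = {s.segment_id: s for s in self.segments}
        for slot in self.slots:
            if slot.seq in seen or slot.seq <= last_seq:
                raise ValueError(f"sequence numbers must be strictly increasing at seq={slot.seq}")
            seen.add(slot.seq)
            last_seq = slot.seq
            if last_seg is not None and slot.segment < last_seg:
                raise ValueError(f"segment ids must be non-decreasing at seq={slot.seq}")
            last_seg = slot.segment
            if seg_ids and slot.segment in seg_ids and slot.arm not in seg_ids[slot.segment].arms:
                raise ValueError(
                    f"slot seq={slot.seq} carries arm {slot.arm!r} outside its segment's active set"
                )

    # -- queries ------------------------------------------------------------

    def counts(self, status: Optional[str] = None) -> dict[str, int]:
        out: dict[str, int] = {}
        for slot in self.slots:
            if status is None or slot.status == status:
                out[slot.arm] = out.get(slot.arm, 0) + 1
        return out

    def open_slots(self) -> list[Slot]:
        """Slots a participant could still take, in order."""
        return [s for s in self.slots if s.status in ("pending", "skipped-open")]

    def pending(self) -> list[Slot]:
        return [s for s in self.slots if s.status == "pending"]

    def assigned(self) -> list[Slot]:
        return [s for s in self.slots if s.status == "assigned"]

    def arms(self) -> list[str]:
        seen: list[str] = []
        for s in self.slots:
            if s.arm not in seen:
                seen.append(s.arm)
        return seen

    # -- mutation -----------------------------------------------------------

    def assign(self, seq: int, participant_id: str) -> Slot:
        slot = next(s for s in self.slots if s.seq == seq)
        if slot.status == "assigned":
            raise ValueError(f"slot seq={seq} is already assigned and immutable")
        if slot.status == "void":
            raise ValueError(f"slot seq={seq} is void")
        slot.status = "assigned"
        slot.participant_id = participant_id
        return slot

    def copy(self) -> "Schedule":
        return Schedule(
            [replace(s) for s in self.slots], list(self.segments), dict(self.metadata)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seq": s.seq,
                    "stratum": s.stratum,
                    "segment": s.segment,
                    "arm": s.arm,
                    "status": s.status,
                    "participant_id": s.participant_id or "",
                }
                for s in self.slots
            ],
            columns=["seq", "stratum", "segment", "arm", "status", "participant_id"],
        )


def default_labels(k: int) -> list[str]:
    """Arm labels A, B, C, ... falling back to T10, T11, ... beyond Z."""
    if k <= 26:
        return list(string.ascii_uppercase[:k])
    return [f"T{j + 1}" for j in range(k)]


def generate_schedule(
    proc: Procedure,
    n: int,
    seed: int,
    labels: Optional[Sequence[str]] = None,
    stratum: str = "all",
    segment: int = 0,
    reason: str = "initial",
) -> Schedule:
    """Pre-generate ``n`` assignments from a procedure with a seeded RNG."""
    if labels is None:
        labels = default_labels(proc.k)
    rng = np.random.default_rng(seed)
    arms = proc.simulate(n, rng)
    slots = [
        Slot(seq=i + 1, stratum=stratum, segment=segment, arm=labels[a])
        for i, a in enumerate(arms)
    ]
    seg = Segment(segment, tuple(labels), repr(proc.ratio), reason)
    return Schedule(slots, [seg], {"seed": seed, "procedure": type(proc).__name__, "n": n})


# -- CSV round-trip ---------------------------------------------------------

_COLUMNS = ["seq", "stratum", "segment", "arm", "status", "participant_id"]


def write_schedule(sched: Schedule, path) -> None:
    """Write a schedule CSV (UTF-8, comma-separated, '#' metadata header)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(sched.metadata):
            fh.write(f"# {key}: {sched.metadata[key]}\n")
        for seg in sched.segments:
            fh.write(
                f"# segment {seg.segment_id}: arms={','.join(seg.arms)}"
                f" ratio={seg.ratio} reason={seg.reason}\n"
            )
        df = sched.to_frame()
        df.to_csv(fh, index=False, lineterminator="\n")


def read_schedule(path) -> Schedule:
    """Read a schedule CSV; rejects duplicate seq and non-monotone segments."""
    meta: dict = {}
    segments: list[Segment] = []
    header_lines = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("segment "):
                head, _, rest = body.partition(":")
                seg_id = int(head.split()[1])
                fields = dict(kv.split("=", 1) for kv in rest.split())
                segments.append(
                    Segment(seg_id, tuple(fields["arms"].split(",")), fields["ratio"], fields["reason"])
                )
            elif ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str}, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"schedule CSV missing columns: {missing}")
    slots = []
    for offset, row in enumerate(df.itertuples(index=False)):
        line_no = header_lines + 2 + offset
        try:
            slots.append(
                Slot(
                    seq=int(row.seq),
                    stratum=str(row.stratum),
                    segment=int(row.segment),
                    arm=str(row.arm),
                    status=str(row.status),
                    participant_id=str(row.participant_id) or None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{line_no}: {exc}") from exc
    try:
        return Schedule(slots, segments, meta)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
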