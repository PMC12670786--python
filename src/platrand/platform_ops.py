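"""Mid-trial adaptations: arm addition, arm closure/reopening, ratio changes.

Adding an arm interleaves the *remaining* assignments of the in-flight
schedule with the new arm's slots through a two-arm brick tunnel sequence
(pooled old arms vs. new arm), so the new arm is spread evenly over the
rest of the randomization while the old arms keep their original relative
order — preserving whatever balance the original schedule carried.

Ratio changes and closures follow the regulatory bookkeeping rule: pending
slots of the old segment are voided and a fresh segment (new schedule) is
generated, so each run of the trial with a fixed arm set and ratio is
identifiable for segment-stratified analysis.  Assigned slots are never
touched by any adaptation.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import replace
from typing import Callable, Optional, Sequence

from .procedures import BrickTunnel, BrickTunnel2
from .ratio import AllocationRatio, normalize_ratio
from .schedule import Schedule, Segment, Slot, generate_schedule
from .state import Procedure

__all__ = ["add_arm", "update_active_arms", "AuditLog", "apply_action", "replay"]


def add_arm(
    old: Schedule,
    consumed: Optional[int],
    new_arm: str,
    new_count: int,
    seed: int,
) -> Schedule:
    """Add ``new_count`` slots of a new arm to an in-flight schedule.

    ``consumed`` is the number of assignments already made (defaults to the
    number of assigned slots).  The ``m`` remaining old assignments keep
    their original relative order; a two-arm brick tunnel sequence with
    exact ratio ``m : new_count`` (pooled old vs. new) decides the
    interleaving, so any prefix of the merged future segment contains a
    number of new-arm slots within 1 of its proportional share.
    """
    if new_count < 0:
        raise ValueError("new_count must be nonnegative")
    n_assigned = len(old.assigned())
    if consumed is None:
        consumed = n_assigned
    if consumed > n_assigned:
        raise ValueError(
            f"consumed={consumed} exceeds the {n_assigned} assigned slots"
        )
    if new_count == 0:
        warnings.warn("new_count=0: schedule unchanged", stacklevel=2)
        return old.copy()
    out = old.copy()
    future = out.pending()
    m = len(future)
    old_arm_seq = [s.arm for s in future]
    ratio = normalize_ratio((m, new_count))
    btr = BrickTunnel2(ratio)
    import numpy as np

    rng = np.random.default_rng(seed)
    pattern = btr.simulate(m + new_count, rng)  # 0 = pooled old, 1 = new arm
    seg_id = max((s.segment_id for s in out.segments), default=0) + 1
    stratum = future[0].stratum if future else "all"
    start_seq = max((s.seq for s in out.slots), default=0) + 1
    keep = [s for s in out.slots if s.status != "pending"]
    merged: list[Slot] = []
    it = iter(old_arm_seq)
    seq = start_seq
    # re-issue the future as a fresh segment; old pending slots are replaced
    # (not mutated) so the audit trail stays intact
    for draw in pattern:
        arm = new_arm if draw == 1 else next(it)
        merged.append(Slot(seq=seq, stratum=stratum, segment=seg_id, arm=arm))
        seq += 1
    old_seg = out.segments[-1] if out.segments else None
    arms = tuple(dict.fromkeys((old_seg.arms if old_seg else tuple(old.arms())) + (new_arm,)))
    ratio_str = f"{m}:{new_count}[pooled:{new_arm}]"  # no spaces: round-trips the CSV header
    segments = out.segments + [Segment(seg_id, arms, ratio_str, "arm-added")]
    meta = dict(out.metadata)
    meta[f"add_arm_seed_{seg_id}"] = seed
    return Schedule(keep + merged, segments, meta)


def update_active_arms(
    sched: Schedule,
    open_arms: Sequence[str] = (),
    close_arms: Sequence[str] = (),
    new_ratio: Optional[AllocationRatio] = None,
    n_new: Optional[int] = None,
    seed: int = 0,
    procedure_factory: Optional[Callable[[AllocationRatio], Procedure]] = None,
) -> Schedule:
    """Open/close arms and/or change the ratio; starts a fresh segment.

    Pending slots of the current segment are voided; ``n_new`` slots
    (default: as many as were voided) are generated for the new active set
    under ``procedure_factory`` (default: brick tunnel randomization at the
    new ratio).  Closing and later reopening an arm therefore leaves three
    segments in the record.
    """
    current = sched.segments[-1] if sched.segments else Segment(0, tuple(sched.arms()), "", "initial")
    active = [a for a in current.arms if a not in set(close_arms)]
    for a in open_arms:
        if a not in active:
            active.append(a)
    if not active:
        raise ValueError("cannot close all arms")
    if new_ratio is None:
        if set(active) != set(current.arms):
            raise ValueError("a new ratio must be supplied when the arm set changes")
        new_ratio_obj = None
    else:
        if new_ratio.k != len(active):
            raise ValueError(
                f"ratio has {new_ratio.k} arms but the active set has {len(active)}"
            )
        new_ratio_obj = new_ratio
    if set(active) == set(current.arms) and (
        new_ratio_obj is None or repr(new_ratio_obj) == current.ratio
    ):
        warnings.warn("active set and ratio unchanged: no new segment", stacklevel=2)
        return sched.copy()
    if new_ratio_obj is None:
        raise ValueError("a ratio must be supplied for the new segment")
    out = sched.copy()
    voided = 0
    for slot in out.slots:
        if slot.status in ("pending", "skipped-open"):
            slot.status = "void"
            voided += 1
    if n_new is None:
        n_new = voided
    factory = procedure_factory or BrickTunnel
    proc = factory(new_ratio_obj)
    seg_id = max((s.segment_id for s in out.segments), default=0) + 1
    reason = "arm-closed" if close_arms else ("arm-added" if open_arms else "ratio-change")
    start_seq = max((s.seq for s in out.slots), default=0) + 1
    piece = generate_schedule(
        proc, n_new, seed, labels=active, stratum=out.slots[0].stratum if out.slots else "all",
        segment=seg_id, reason=reason,
    )
    for s in piece.slots:
        s.seq += start_seq - 1
    segments = out.segments + [Segment(seg_id, tuple(active), repr(new_ratio_obj), reason)]
    meta = dict(out.metadata)
    meta[f"segment_seed_{seg_id}"] = seed
    return Schedule(out.slots + piece.slots, segments, meta)


class AuditLog:
    """Append-only JSONL log of adaptation actions.

    Replaying the log over the initial schedule reconstructs the final
    schedule exactly, because every action records its seed.
    """

    def __init__(self, path=None):
        self.path = path
        self.entries: list[dict] = []

    def record(self, action: dict) -> dict:
        entry = dict(action)
        entry.setdefault("timestamp", datetime.datetime.now(datetime.timezone.utc).isoformat())
        self.entries.append(entry)
        if self.path:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")
        return entry

    @classmethod
    def load(cls, path) -> "AuditLog":
        log = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    log.entries.append(json.loads(line))
        return log


def apply_action(sched: Schedule, action: dict) -> Schedule:
    """Apply one audit-log action; used to replay a log over a schedule."""
    kind = action["action"]
    if kind == "add_arm":
        return add_arm(
            sched,
            action.get("consumed"),
            action["arm"],
            action["count"],
            action["seed"],
        )
    if kind == "assign":
        out = sched.copy()
        out.assign(action["seq"], action["participant_id"])
        return out
    if kind == "update_active_arms":
        ratio = normalize_ratio(action["ratio"]) if action.get("ratio") else None
        return update_active_arms(
            sched,
            open_arms=action.get("open", ()),
            close_arms=action.get("close", ()),
            new_ratio=ratio,
            n_new=action.get("n_new"),
            seed=action["seed"],
        )
    raise ValueError(f"unknown action {kind!r}")


def replay(initial: Schedule, log: AuditLog) -> Schedule:
    sched = initial.copy()
    for entry in log.entries:
        sched = apply_action(sched, entry)
    return sched
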