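import math
from fractions import Fraction

import numpy as np
import pytest

from platrand import (
    Batch,
    IntegerRatio,
    Participant,
    PermutedBlock,
    TwoStepRandomizer,
    TwoStepScheme,
    example_scheme,
    expected_composition,
    gen_enrollment,
    generate_schedule,
    map_equal_to_unequal,
    skip_and_backfill_assign,
    unconditional_profile,
)

F = Fraction


def participant(subpop="1", eligible=("E1", "C1"), center="C01", i=0):
    return Participant(f"P{i:04d}", subpop, frozenset(eligible), center, i)


class TestScheme:
    def test_example_batch_probabilities(self):
        scheme = example_scheme()
        assert scheme.batch_probs["1"] == {"A": F(1, 2), "B": F(1, 8), "C": F(3, 8)}
        assert scheme.batch_probs["2"] == {"A": F(6, 8), "B": F(2, 8)}
        assert scheme.eligible_batches("2") == ["A", "B"]

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TwoStepScheme(
                (Batch("A", "E1", "C1"),), {"1": {"A": F(1, 2)}}
            )

    def test_json_round_trip(self, tmp_path):
        scheme = example_scheme()
        path = tmp_path / "scheme.json"
        scheme.to_json(path)
        loaded = TwoStepScheme.from_json(path)
        assert loaded.batches == scheme.batches
        assert {k: dict(v) for k, v in loaded.batch_probs.items()} == {
            k: dict(v) for k, v in scheme.batch_probs.items()
        }


class TestTwoStepRandomizer:
    def test_batch_frequencies_match_subpop_probabilities(self):
        scheme = example_scheme()
        rand = TwoStepRandomizer(scheme, seed=31)
        n = 4000
        hits = {"A": 0, "B": 0, "C": 0}
        for i in range(n):
            batch, _ = rand.assign(participant("1", ("E1", "E2", "E3", "C1", "C2", "C3"), i=i))
            hits[batch] += 1
        for name, p in (("A", 0.5), ("B", 0.125), ("C", 0.375)):
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(hits[name] / n - p) < 4 * sigma

    def test_ineligible_batches_never_drawn(self):
        rand = TwoStepRandomizer(example_scheme(), seed=8)
        for i in range(300):
            batch, arm = rand.assign(participant("2", ("E1", "E2", "C1", "C2"), i=i))
            assert batch in ("A", "B")
            assert arm in ("E1", "C1", "E2", "C2")

    def test_within_batch_ratio_exact_at_block_boundaries(self):
        """Second step is an ARP mapped block at 2:1, so every three
        within-batch allocations close at exactly 2 treatment : 1 control."""
        rand = TwoStepRandomizer(example_scheme(), seed=5)
        got = {"E1": 0, "C1": 0}
        drawn = 0
        for i in range(10**4):
            batch, arm = rand.assign(participant("1", ("E1", "E2", "E3", "C1", "C2", "C3"), i=i))
            if batch == "A":
                got[arm] += 1
                drawn += 1
                if drawn % 3 == 0:
                    assert got["E1"] == 2 * got["C1"]
            if drawn >= 30:
                break

    def test_unknown_subpopulation_rejected(self):
        rand = TwoStepRandomizer(example_scheme(), seed=1)
        with pytest.raises(KeyError):
            rand.assign(participant("9"))

    def test_single_batch_scheme_degenerates(self):
        scheme = TwoStepScheme(
            (Batch("A", "E1", "C1"),), {"1": {"A": F(1)}}
        )
        rand = TwoStepRandomizer(scheme, seed=2)
        arms = [rand.assign(participant("1", i=i))[1] for i in range(6)]
        assert arms.count("E1") == 4 and arms.count("C1") == 2


class TestExpectedComposition:
    def test_reference_cells(self):
        """(120, 24) enrollees: pooled controls 40 and 8, treatments 40 and
        12, subpopulation-2 ratio 1:1.5 — all exact."""
        df = expected_composition(example_scheme(), {"1": 120, "2": 24})
        a = df[df.batch == "A"].set_index("subpopulation")
        assert a.loc["1", "expected_pooled_control"] == 40
        assert a.loc["1", "expected_treatment"] == 40
        assert a.loc["1", "control_to_treatment"] == "1:1"
        assert a.loc["2", "expected_pooled_control"] == 8
        assert a.loc["2", "expected_treatment"] == 12
        assert a.loc["2", "control_to_treatment"] == "1:1.5"

    def test_zero_enrollment_gives_zero_cells(self):
        df = expected_composition(example_scheme(), {"1": 0, "2": 24})
        assert (df[df.subpopulation == "1"][["expected_treatment", "expected_pooled_control"]] == 0).all().all()

    def test_monte_carlo_agreement(self):
        """Mean counts over 2000 simulated trials of the example scheme fall
        within 4 sigma of the exact expectations."""
        scheme = example_scheme()
        n1, n2, n_trials = 120, 24, 2000
        rng_master = np.random.default_rng(1234)
        treat = np.zeros(n_trials)
        control = np.zeros(n_trials)
        all_arms = ("E1", "E2", "E3", "C1", "C2", "C3")
        for t in range(n_trials):
            rand = TwoStepRandomizer(scheme, seed=int(rng_master.integers(2**31)))
            for i in range(n2):
                batch, arm = rand.assign(participant("2", all_arms[:2] + all_arms[3:5], i=i))
                treat[t] += arm == "E1"
                control[t] += arm in ("C1", "C2")
        assert abs(treat.mean() - 12) < 4 * treat.std() / math.sqrt(n_trials)
        assert abs(control.mean() - 8) < 4 * control.std() / math.sqrt(n_trials)


class TestSkipAndBackfill:
    def _schedule(self, n=12, seed=3):
        proc = PermutedBlock(IntegerRatio((1, 1, 1)))
        return generate_schedule(proc, n, seed=seed, labels=["A", "B", "C"])

    def test_all_eligible_follows_schedule_exactly(self):
        sched = self._schedule()
        order = [s.arm for s in sched.slots]
        for i in range(12):
            p = participant("1", ("A", "B", "C"), i=i)
            seq = skip_and_backfill_assign(p, sched)
            assert seq == i + 1
        assert [s.arm for s in sched.assigned()] == order

    def test_ineligible_skips_and_slot_stays_claimable(self):
        sched = self._schedule()
        first_arm = sched.slots[0].arm
        others = tuple(a for a in ("A", "B", "C") if a != first_arm)
        p1 = participant("1", others, i=1)
        seq1 = skip_and_backfill_assign(p1, sched)
        assert seq1 > 1
        assert sched.slots[0].status == "skipped-open"
        p2 = participant("1", (first_arm,), i=2)
        assert skip_and_backfill_assign(p2, sched) == 1

    def test_no_feasible_slot_queues_with_warning(self):
        sched = self._schedule(n=3)
        for i in range(3):
            skip_and_backfill_assign(participant("1", ("A", "B", "C"), i=i), sched)
        with pytest.warns(UserWarning):
            assert skip_and_backfill_assign(participant("1", ("A",), i=9), sched) is None

    def test_small_ineligible_fraction_keeps_totals_close(self):
        """10% of participants ineligible for one arm: final totals differ
        from the schedule's targets by at most the terminally unfilled
        skipped slots."""
        proc = PermutedBlock(IntegerRatio((1, 1, 1)))
        sched = generate_schedule(proc, 90, seed=17, labels=["A", "B", "C"])
        target = sched.counts()
        stream = gen_enrollment(
            90, ["A", "B", "C"], seed=23, ineligibility_rates={"C": 0.1}
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for p in stream:
                skip_and_backfill_assign(p, sched)
        unfilled = len(sched.open_slots())
        achieved = sched.counts(status="assigned")
        for arm in ("A", "B", "C"):
            assert abs(achieved.get(arm, 0) - target[arm]) <= unfilled


def test_stratified_by_eligibility_preserves_arp_within_stratum():
    """Independent ARP schedules per subpopulation keep each stratum's
    unconditional profile at its own target ratio."""
    for iratio in (IntegerRatio((2, 1)), IntegerRatio((1, 2))):
        proc = map_equal_to_unequal(iratio)
        prof = unconditional_profile(proc, 9)
        assert prof.max_deviation() == 0
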