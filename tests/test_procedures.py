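import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from platrand import (
    BrickTunnel,
    BrickTunnel2,
    CompleteRandomization,
    HanMinimization,
    IntegerRatio,
    PermutedBlock,
    btr_sqrt_control,
    equal_block,
    map_equal_to_unequal,
    normalize_ratio,
    state_probabilities,
    unconditional_profile,
)
from platrand.procedures import _admissible

from conftest import procedure_matrix

F = Fraction


class TestCompleteRandomization:
    def test_seeded_sequence_reproducible(self):
        proc = CompleteRandomization(normalize_ratio((1, 1)))
        rng1, rng2 = np.random.default_rng(42), np.random.default_rng(42)
        assert proc.simulate(50, rng1) == proc.simulate(50, rng2)

    def test_empirical_frequencies_match_target(self):
        """Chi-square check on 10^4 draws at 5:5:7."""
        ratio = normalize_ratio((5, 5, 7))
        proc = CompleteRandomization(ratio)
        arms = proc.simulate(10**4, np.random.default_rng(7))
        obs = np.bincount(arms, minlength=3)
        chi2 = stats.chisquare(obs, f_exp=10**4 * ratio.proportions_float)
        assert chi2.pvalue > 1e-4

    def test_single_draw_matches_target_exactly(self):
        proc = CompleteRandomization(normalize_ratio((5, 5, 7)))
        prof = unconditional_profile(proc, 1)
        assert prof.exact[0] == proc.ratio.proportions


class TestPermutedBlock:
    def test_block_closure_557(self):
        proc = PermutedBlock(IntegerRatio((5, 5, 7)))
        arms = proc.simulate(17, np.random.default_rng(0))
        assert tuple(arms.count(j) for j in range(3)) == (5, 5, 7)

    def test_every_completed_block_exact_12(self):
        proc = PermutedBlock(IntegerRatio((1, 2)))
        arms = proc.simulate(9, np.random.default_rng(1))
        for m in (1, 2, 3):
            prefix = arms[: 3 * m]
            assert (prefix.count(0), prefix.count(1)) == (m, 2 * m)

    def test_prefix_distribution_is_hypergeometric(self):
        """P(totals = (3,3,4) after 10 of one 5:5:7 block) equals the
        multivariate hypergeometric mass C(5,3)C(5,3)C(7,4)/C(17,10)."""
        proc = PermutedBlock(IntegerRatio((5, 5, 7)))
        dist = state_probabilities(proc, 10)
        mh = stats.multivariate_hypergeom(m=[5, 5, 7], n=10)
        for totals, prob in dist.items():
            assert float(prob) == pytest.approx(mh.pmf(list(totals)), abs=1e-12)
        closed = F(math.comb(5, 3) * math.comb(5, 3) * math.comb(7, 4), math.comb(17, 10))
        assert dist[(3, 3, 4)] == closed

    def test_prefix_distribution_matches_permutation_enumeration(self):
        """Exhaustive enumeration of all distinct (2,2,3)-block orderings."""
        proc = PermutedBlock(IntegerRatio((2, 2, 3)))
        dist = state_probabilities(proc, 4)
        block = [0, 0, 1, 1, 2, 2, 2]
        counts: dict = {}
        perms = set(itertools.permutations(block))
        for perm in perms:
            prefix = perm[:4]
            t = tuple(prefix.count(j) for j in range(3))
            counts[t] = counts.get(t, 0) + 1
        for t, c in counts.items():
            assert dist[t] == F(c, len(perms))


class TestMapping:
    def test_group_structure_123(self):
        mapped = map_equal_to_unequal(IntegerRatio((1, 2, 3)))
        assert mapped.groups == ((0,), (1, 2), (3, 4, 5))

    def test_identity_mapping(self):
        mapped = map_equal_to_unequal(IntegerRatio((1, 1, 1)))
        inner = equal_block(3)
        state = mapped.initial_state()
        assert mapped.transitions(state) == inner.transitions(state)

    def test_mapped_pbr_is_arp(self):
        """Pooling fake arms of an equal PBR yields 1/3 unconditionally at
        every step across two full blocks."""
        mapped = map_equal_to_unequal(IntegerRatio((1, 2)))
        prof = unconditional_profile(mapped, 6)
        assert all(row == (F(1, 3), F(2, 3)) for row in prof.exact)

    def test_arity_mismatch_rejected(self):
        with pytest.raises(ValueError):
            map_equal_to_unequal(IntegerRatio((1, 2)), inner=equal_block(4))


class TestHanMinimization:
    def test_equal_allocation_is_arp_by_symmetry(self):
        proc = HanMinimization(normalize_ratio((1, 1)))
        prof = unconditional_profile(proc, 10)
        assert all(row == (F(1, 2), F(1, 2)) for row in prof.exact)

    def test_unequal_allocation_oscillates(self):
        """1:2 with coin 0.9: P(arm 1) is low (0.1-0.2) at steps 1,3,4,6,7,9
        and high at 2,5,8 — the hallmark non-ARP pattern."""
        proc = HanMinimization(normalize_ratio((1, 2)), coin_p=F(9, 10))
        prof = unconditional_profile(proc, 9)
        p1 = [float(row[0]) for row in prof.exact]
        for step in (1, 3, 4, 6, 7, 9):
            assert 0.1 <= p1[step - 1] <= 0.2
        for step in (2, 5, 8):
            assert p1[step - 1] > 0.7

    def test_fair_coin_is_complete_randomization(self):
        proc = HanMinimization(normalize_ratio((1, 2)), coin_p=F(1, 2))
        prof = unconditional_profile(proc, 6)
        assert all(row == (F(1, 2), F(1, 2)) for row in prof.exact)

    def test_three_arms_rejected(self):
        with pytest.raises(ValueError):
            HanMinimization(normalize_ratio((1, 1, 1)))


class TestBrickTunnel2:
    def test_equal_allocation_alternates(self):
        proc = BrickTunnel2(normalize_ratio((1, 1)))
        for N, forced in [((1, 0), 1), ((0, 1), 0)]:
            trans = proc.transitions(N)
            assert len(trans) == 1 and trans[0][0] == forced

    def test_37_60_admissible_states_flank_the_ray(self):
        """At every step the reachable totals are the <=2 lattice points
        around (37u, 60u)."""
        ratio = normalize_ratio((37, 60))
        proc = BrickTunnel2(ratio)
        reachable = {(0, 0)}
        for i in range(97):
            nxt = set()
            for N in reachable:
                for _, p, M in proc.transitions(N):
                    if p > 0:
                        nxt.add(M)
            reachable = nxt
            assert reachable <= set(_admissible(i + 1, ratio.proportions))
            assert len(reachable) <= 2
        assert reachable == {(37, 60)}

    def test_irrational_ratio_states_match_brute_force(self):
        """5:sqrt(5) pooled-vs-control: reachable states equal the lattice
        cells pierced by the allocation ray."""
        ratio = normalize_ratio((5, math.sqrt(5)))
        proc = BrickTunnel2(ratio)
        dist = {(0, 0): F(1)}
        for i in range(30):
            nxt: dict = {}
            for N, w in dist.items():
                for _, p, M in proc.transitions(N):
                    nxt[M] = nxt.get(M, F(0)) + w * p
            dist = {N: w for N, w in nxt.items() if w > 0}
            assert set(dist) == set(_admissible(i + 1, ratio.proportions))

    def test_arp_exact(self):
        proc = BrickTunnel2(normalize_ratio((1, math.sqrt(2))))
        prof = unconditional_profile(proc, 12)
        assert prof.max_deviation() == 0


class TestBrickTunnelMulti:
    def test_example_state_set_at_10(self, ratio_557):
        dist = state_probabilities(BrickTunnel(ratio_557), 10)
        assert set(dist) == {(3, 3, 4), (3, 2, 5), (2, 3, 5)}

    def test_example_concentration_at_10(self, ratio_557):
        dist = state_probabilities(BrickTunnel(ratio_557), 10)
        assert dist[(3, 3, 4)] == F(15, 17)  # prints as 0.88
        assert dist[(3, 2, 5)] == dist[(2, 3, 5)] == F(1, 17)

    def test_two_arm_reduction_matches_closed_form(self):
        """The general LP construction at K=2 equals the closed form."""
        for weights in [(1, 2), (37, 60), (1, math.sqrt(2))]:
            ratio = normalize_ratio(weights)
            lp, closed = BrickTunnel(ratio), BrickTunnel2(ratio)
            dist = {(0, 0): F(1)}
            for _ in range(12):
                nxt: dict = {}
                for N, w in dist.items():
                    a = sorted(lp.transitions(N))
                    b = sorted(closed.transitions(N))
                    assert a == b, (weights, N)
                    for _, p, M in a:
                        nxt[M] = nxt.get(M, F(0)) + w * p
                dist = nxt

    def test_tunnel_bound_strict_to_200(self, ratio_557):
        assert BrickTunnel(ratio_557).max_deviation(200) < 1

    def test_block_closure_forced(self, ratio_557):
        btr = BrickTunnel(ratio_557)
        assert btr.occupancy(17) == {(5, 5, 7): F(1)}
        assert btr.occupancy(34) == {(10, 10, 14): F(1)}

    def test_arp_exact_irrational(self, sqrt2_ratio):
        prof = unconditional_profile(BrickTunnel(sqrt2_ratio), 12)
        assert prof.max_deviation() == 0


class TestSqrtControlComposite:
    def test_first_stage_ratio_and_labels(self):
        sched = btr_sqrt_control(5, 30, seed=3)
        assert sched.segments[0].arms == ("T1", "T2", "T3", "T4", "T5", "Control")

    def test_rejects_single_arm(self):
        with pytest.raises(ValueError):
            btr_sqrt_control(1, 10, seed=0)

    def test_investigational_arms_balanced_within_one(self):
        """After every prefix, each investigational total is within 1 of
        (pooled total)/K, by inner-block closure."""
        k, n = 4, 100
        sched = btr_sqrt_control(k, n, seed=11)
        counts = {f"T{j + 1}": 0 for j in range(k)}
        pooled = 0
        for slot in sched.slots:
            if slot.arm != "Control":
                counts[slot.arm] += 1
                pooled += 1
            for j in range(k):
                assert abs(counts[f"T{j + 1}"] - pooled / k) < 1 + 1e-12

    def test_control_proportion_tracks_target(self):
        k, n = 5, 200
        sched = btr_sqrt_control(k, n, seed=2)
        target = math.sqrt(k) / (k + math.sqrt(k))
        ctrl = 0
        for i, slot in enumerate(sched.slots, start=1):
            ctrl += slot.arm == "Control"
            assert abs(ctrl - i * target) < 1


@pytest.mark.parametrize("name,proc,n", procedure_matrix())
def test_conditional_probabilities_sum_to_one(name, proc, n):
    """Walk all reachable states to depth min(n, 12): every state's
    transition probabilities form a probability vector with no zero-mass
    moves emitted."""
    states = {proc.initial_state()}
    for _ in range(min(n, 12)):
        nxt = set()
        for s in states:
            trans = proc.transitions(s)
            assert sum(p for _, p, _ in trans) == 1
            assert all(p > 0 for _, p, _ in trans)
            nxt.update(ns for _, _, ns in trans)
        states = nxt
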