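"""Randomization procedures for unequal allocation in platform trials.

Implemented methods
-------------------
- :class:`CompleteRandomization` — i.i.d. draws at the target proportions.
- :class:`PermutedBlock` — uniform permutations of blocks of composition
  ``Q_1..Q_K``; exact ratio at block boundaries, loose inside a block.
- :class:`MappedProcedure` — expansion of any equal-allocation procedure over
  ``S`` "fake" arms to a ``Q_1:...:Q_K`` allocation by pooling consecutive
  fake arms; allocation-ratio preserving (ARP) by symmetry of the inner rule.
- :class:`HanMinimization` — a two-arm minimization whose preferred arm is
  the one minimizing the post-allocation imbalance ``|N_1/rho_1 - N_2/rho_2|``.
  Deliberately included as the classical *non-ARP* comparator: with unequal
  target ratio its unconditional allocation probabilities oscillate by step.
- :class:`BrickTunnel2` / :class:`BrickTunnel` — brick tunnel randomization
  (BTR): allocation paths are confined to the chain of unit lattice cells
  pierced by the allocation ray ``(i*rho_1, ..., i*rho_K)``, so every arm
  total stays strictly within 1 of its ideal value, while the conditional
  probabilities are derived so that the unconditional ratio equals the
  target at every step (ARP).

All probabilities are exact rationals (``fractions.Fraction``).
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from typing import Optional

import numpy as np

from ._exactlp import lp_max
from .ratio import AllocationRatio, IntegerRatio, normalize_ratio
from .state import Procedure, Transition

__all__ = [
    "CompleteRandomization",
    "PermutedBlock",
    "MappedProcedure",
    "HanMinimization",
    "BrickTunnel2",
    "BrickTunnel",
    "map_equal_to_unequal",
    "btr_two_arm",
    "btr_multi_arm",
    "btr_sqrt_control",
    "equal_block",
]

F = Fraction


class CompleteRandomization(Procedure):
    """Independent allocation at fixed probabilities ``rho``; no restriction."""

    is_fixed = True

    def __init__(self, ratio: AllocationRatio):
        self.ratio = ratio

    def initial_state(self):
        return (0,) * self.k

    def transitions(self, state) -> list[Transition]:
        out = []
        for j, p in enumerate(self.ratio.proportions):
            nxt = list(state)
            nxt[j] += 1
            out.append((j, p, tuple(nxt)))
        return out


class PermutedBlock(Procedure):
    """Permuted block randomization with block composition ``Q_1..Q_K``.

    Each block is an independent uniform permutation of the multiset with
    ``Q_j`` copies of arm ``j``; the chain continues over as many blocks as
    requested.  Within one block the totals follow the multivariate
    hypergeometric law.
    """

    is_fixed = True

    def __init__(self, iratio: IntegerRatio):
        self.iratio = iratio
        self.ratio = iratio.as_ratio()

    def initial_state(self):
        return (0,) * self.k

    def transitions(self, state) -> list[Transition]:
        i = sum(state)
        S = self.iratio.block_size
        done_blocks = i // S
        left_in_block = S - (i - done_blocks * S)
        out = []
        for j, q in enumerate(self.iratio.counts):
            used = state[j] - done_blocks * q
            remaining = q - used
            if remaining > 0:
                nxt = list(state)
                nxt[j] += 1
                out.append((j, F(remaining, left_in_block), tuple(nxt)))
        return out


def equal_block(s: int) -> PermutedBlock:
    """Equal-allocation permuted block over ``s`` arms with block size ``s``."""
    return PermutedBlock(IntegerRatio((1,) * s))


class MappedProcedure(Procedure):
    """Unequal allocation built from an equal-allocation inner procedure.

    The inner procedure allocates to ``S`` fake arms ``F_1..F_S``; the first
    ``Q_1`` fake arms are pooled into target arm 1, the next ``Q_2`` into
    arm 2, and so on.  When the inner rule is symmetric in its fake arms,
    each fake arm has unconditional probability ``1/S`` at every step, so
    the pooled procedure is ARP with ratio ``Q_1:...:Q_K`` by construction.
    """

    def __init__(self, inner: Procedure, iratio: IntegerRatio):
        if inner.k != iratio.block_size:
            raise ValueError(
                f"inner procedure has {inner.k} arms but the mapping needs "
                f"S = {iratio.block_size}"
            )
        self.inner = inner
        self.iratio = iratio
        self.ratio = iratio.as_ratio()
        self.is_fixed = inner.is_fixed
        groups = []
        start = 0
        for q in iratio.counts:
            groups.append(range(start, start + q))
            start += q
        self._group_of = {f: j for j, g in enumerate(groups) for f in g}
        self.groups = tuple(tuple(g) for g in groups)

    @property
    def k(self) -> int:
        return self.iratio.k

    def initial_state(self):
        return self.inner.initial_state()

    def transitions(self, state) -> list[Transition]:
        return [
            (self._group_of[fake_arm], p, nxt)
            for fake_arm, p, nxt in self.inner.transitions(state)
        ]

    def totals(self, state):
        fake = self.inner.totals(state)
        return tuple(sum(fake[f] for f in g) for g in self.groups)


def map_equal_to_unequal(iratio: IntegerRatio, inner: Optional[Procedure] = None) -> MappedProcedure:
    """Expand an equal-allocation procedure to a ``Q_1:...:Q_K`` allocation.

    The caller asserts the inner procedure is symmetric in its ``S`` arms
    (true for the default, an equal permuted block of size ``S``); symmetry
    is what makes the mapped procedure ARP.
    """
    if inner is None:
        inner = equal_block(iratio.block_size)
    return MappedProcedure(inner, iratio)


class HanMinimization(Procedure):
    """Two-arm unequal-allocation minimization with a biased coin.

    For the next participant, each arm's hypothetical imbalance
    ``|(N+e_j)_1/rho_1 - (N+e_j)_2/rho_2|`` is evaluated; the arm yielding
    the smaller value is chosen with probability ``coin_p`` (fair split on
    ties).  With equal allocation the rule is symmetric, hence ARP; with
    unequal allocation it is *not* ARP — its unconditional allocation
    probabilities swing far from the target in the early steps.
    """

    is_fixed = False

    def __init__(self, ratio: AllocationRatio, coin_p=F(9, 10)):
        if ratio.k != 2:
            raise ValueError("this minimization rule is defined for two arms only")
        coin_p = F(coin_p)
        if not (F(1, 2) <= coin_p < 1):
            raise ValueError("coin_p must lie in [0.5, 1)")
        self.ratio = ratio
        self.coin_p = coin_p

    def initial_state(self):
        return (0, 0)

    def transitions(self, state) -> list[Transition]:
        rho = self.ratio.proportions
        imb = []
        for j in range(2):
            m = (state[0] + (j == 0), state[1] + (j == 1))
            imb.append(abs(F(m[0]) / rho[0] - F(m[1]) / rho[1]))
        if imb[0] == imb[1]:
            probs = (F(1, 2), F(1, 2))
        elif imb[0] < imb[1]:
            probs = (self.coin_p, 1 - self.coin_p)
        else:
            probs = (1 - self.coin_p, self.coin_p)
        out = []
        for j in range(2):
            if probs[j] > 0:
                m = (state[0] + (j == 0), state[1] + (j == 1))
                out.append((j, probs[j], m))
        return out


# ---------------------------------------------------------------------------
# Brick tunnel randomization
# ---------------------------------------------------------------------------


def _admissible(i: int, rho: tuple[Fraction, ...]) -> list[tuple[int, ...]]:
    """Lattice points with ``sum N = i`` and ``|N_j - i*rho_j| < 1`` (strict)."""
    ranges = []
    for p in rho:
        t = i * p
        lo = max(0, math.floor(t - 1) + 1)
        hi = math.ceil(t + 1) - 1
        ranges.append([n for n in range(lo, hi + 1) if abs(F(n) - t) < 1])
    return [c for c in itertools.product(*ranges) if sum(c) == i]


class BrickTunnel2(Procedure):
    """Two-arm brick tunnel randomization, in closed form.

    At step ``i`` the only admissible first-arm totals are
    ``floor(i*rho_1)`` and (when fractional) ``ceil(i*rho_1)``; the ARP
    requirement ``E[N_i1] = i*rho_1`` pins the occupancy of the two states,
    and the transition probabilities follow uniquely.  Irrational target
    proportions are handled exactly via their binary-rational values.
    """

    is_fixed = True

    def __init__(self, ratio: AllocationRatio):
        if ratio.k != 2:
            raise ValueError("BrickTunnel2 is the two-arm special case")
        self.ratio = ratio

    def initial_state(self):
        return (0, 0)

    def transitions(self, state) -> list[Transition]:
        i = sum(state)
        rho1 = self.ratio.proportions[0]
        a = math.floor(i * rho1)
        f = i * rho1 - a
        t1 = (i + 1) * rho1
        a1 = math.floor(t1)
        f1 = t1 - a1
        n1 = state[0]
        up = (state[0] + 1, state[1])
        stay = (state[0], state[1] + 1)
        if f == 0:
            # unique state on the ray: split at the target proportions
            return [(0, rho1, up), (1, 1 - rho1, stay)]
        if a1 == a:
            # no carry: the upper state is frozen, the lower one tops it up
            if n1 == a:
                p_up = rho1 / (1 - f)
                return [(0, p_up, up), (1, 1 - p_up, stay)]
            return [(1, F(1), stay)]
        # carry (f + rho1 >= 1): the lower state is forced up
        if n1 == a:
            return [(0, F(1), up)]
        if f1 == 0:
            return [(1, F(1), stay)]
        p_up = f1 / f
        return [(0, p_up, up), (1, 1 - p_up, stay)]


class BrickTunnel(Procedure):
    """Brick tunnel randomization for ``K >= 2`` arms.

    Transition probabilities are derived step by step: flows between
    admissible totals vectors must (a) keep all mass inside the tunnel
    ``|N_j - i*rho_j| < 1``, and (b) give each arm its target marginal
    probability ``rho_j`` at every step (the ARP equations).  Where those
    constraints leave freedom, mass is concentrated on the admissible
    state nearest (Euclidean) to the ideal totals ``i*rho`` — states are
    ranked by distance then lexicographically and their occupancies
    maximized in order; residual freedom in the flows is then pinned by
    maximizing each flow in lexicographic (state, arm) order.  All linear
    programs are solved in exact rational arithmetic.

    For rational ratios the tunnel closes exactly at multiples of the block
    size ``S`` (the totals are forced to ``i*rho``), so transitions are
    periodic with period ``S`` and only one period is ever computed.
    """

    is_fixed = True

    def __init__(self, ratio: AllocationRatio):
        self.ratio = ratio
        self._rho = ratio.proportions
        # exact block size when the ratio is rational: proportions have a
        # common denominator D and counts Q_j = rho_j * D
        if ratio.is_rational:
            D = 1
            for p in self._rho:
                D = D * p.denominator // math.gcd(D, p.denominator)
            self._period = D
            self._counts = tuple(int(p * D) for p in self._rho)
        else:
            self._period = None
            self._counts = None
        self._trans: dict[int, dict[tuple, list[tuple[int, Fraction]]]] = {}
        self._occ: dict[int, dict[tuple, Fraction]] = {0: {(0,) * self.k: F(1)}}

    # -- exact per-step solver ---------------------------------------------

    def _solve_step(self, i: int) -> None:
        """Compute flows for step i -> i+1 from the cached occupancy at i."""
        rho = self._rho
        K = self.k
        pi = self._occ[i]
        states = sorted(N for N, w in pi.items() if w > 0)
        adm = set(_admissible(i + 1, rho))
        edges = []
        for N in states:
            for j in range(K):
                M = tuple(N[k] + (k == j) for k in range(K))
                if M in adm:
                    edges.append((N, j, M))
        if not edges:
            raise RuntimeError(f"brick tunnel empty at step {i + 1}")
        A, b = [], []
        for N in states:
            A.append([F(int(e[0] == N)) for e in edges])
            b.append(pi[N])
        for j in range(K - 1):
            A.append([F(int(e[1] == j)) for e in edges])
            b.append(rho[j])
        tgt = [(i + 1) * p for p in rho]
        ranked = sorted(
            adm, key=lambda M: (sum((F(Mj) - t) ** 2 for Mj, t in zip(M, tgt)), M)
        )
        for M in ranked:
            c = [F(int(e[2] == M)) for e in edges]
            if not any(c):
                continue
            v, _ = lp_max(c, A, b)
            A.append(c)
            b.append(v)
        flows = None
        for idx in range(len(edges)):
            c = [F(0)] * len(edges)
            c[idx] = F(1)
            v, flows = lp_max(c, A, b)
            A.append(c)
            b.append(v)
        table: dict[tuple, list[tuple[int, Fraction]]] = {}
        occ_next: dict[tuple, Fraction] = {}
        for (N, j, M), fl in zip(edges, flows):
            if fl > 0:
                table.setdefault(N, []).append((j, fl / pi[N]))
                occ_next[M] = occ_next.get(M, F(0)) + fl
        self._trans[i] = table
        self._occ[i + 1] = occ_next

    def _ensure(self, step: int) -> None:
        limit = min(step, self._period) if self._period else step
        for i in range(len(self._trans), limit):
            self._solve_step(i)

    def _lookup(self, i: int, totals: tuple) -> list[tuple[int, Fraction]]:
        if self._period:
            q, r = divmod(i, self._period)
            self._ensure(r + 1 if r else 1)
            if r == 0:
                base = self._trans[0]
                key = (0,) * self.k
            else:
                base = self._trans[r]
                key = tuple(t - q * c for t, c in zip(totals, self._counts))
            return base[key]
        self._ensure(i + 1)
        return self._trans[i][totals]

    # -- Procedure interface ------------------------------------------------

    def initial_state(self):
        return (0,) * self.k

    def transitions(self, state) -> list[Transition]:
        i = sum(state)
        out = []
        for j, p in self._lookup(i, state):
            nxt = list(state)
            nxt[j] += 1
            out.append((j, p, tuple(nxt)))
        return out

    # -- tunnel introspection -----------------------------------------------

    def occupancy(self, i: int) -> dict[tuple, Fraction]:
        """Exact distribution of arm totals after ``i`` allocations."""
        if self._period:
            q, r = divmod(i, self._period)
            self._ensure(r if r else 1)
            base = self._occ[r] if r else {(0,) * self.k: F(1)}
            return {
                tuple(t + q * c for t, c in zip(N, self._counts)): w
                for N, w in base.items()
            }
        self._ensure(i)
        return dict(self._occ[i])

    def max_deviation(self, n: int) -> Fraction:
        """Max over steps 1..n and reachable states of ``|N_j - i*rho_j|``."""
        worst = F(0)
        for i in range(1, n + 1):
            for N, w in self.occupancy(i).items():
                if w > 0:
                    for Nj, p in zip(N, self._rho):
                        worst = max(worst, abs(F(Nj) - i * p))
        return worst


def btr_sqrt_control(k: int, n: int, seed: int):
    """Schedule for ``K`` investigational arms vs. control in ``1:...:1:sqrt(K)``.

    Stage 1 draws a two-arm brick tunnel sequence at ratio ``K : sqrt(K)``
    (pooled investigational vs. control), so the control proportion tracks
    ``sqrt(K)/(K + sqrt(K))`` within 1 at every step.  Stage 2 fills the
    pooled slots, in order, with an equal permuted block over the ``K``
    investigational arms (block size ``K``), so after every completed inner
    block the investigational totals are exactly equal.

    Returns a :class:`~platrand.schedule.Schedule` with arms
    ``T1..TK, Control``.
    """
    if k < 2:
        raise ValueError("the square-root-control design needs at least two investigational arms")
    from .schedule import Schedule, Segment, Slot

    rng = np.random.default_rng(seed)
    pooled = BrickTunnel2(normalize_ratio((k, math.sqrt(k))))
    stage1 = pooled.simulate(n, rng)  # 0 = pooled investigational, 1 = control
    inner = equal_block(k)
    state = inner.initial_state()
    labels = [f"T{j + 1}" for j in range(k)] + ["Control"]
    slots = []
    for i, draw in enumerate(stage1):
        if draw == 1:
            arm = "Control"
        else:
            trans = inner.transitions(state)
            probs = np.array([float(p) for _, p, _ in trans])
            idx = rng.choice(len(trans), p=probs / probs.sum())
            j, _, state = trans[idx]
            arm = labels[j]
        slots.append(Slot(seq=i + 1, stratum="all", segment=0, arm=arm))
    ratio_str = ":".join(["1"] * k) + f":sqrt({k})"
    seg = Segment(0, tuple(labels), ratio_str, "initial")
    return Schedule(slots, [seg], {"seed": seed, "procedure": "btr_sqrt_control", "n": n})


def btr_two_arm(ratio: AllocationRatio) -> BrickTunnel2:
    """Two-arm brick tunnel randomization (closed-form transitions)."""
    return BrickTunnel2(ratio)


def btr_multi_arm(ratio: AllocationRatio) -> BrickTunnel:
    """Brick tunnel randomization for any number of arms (exact LP transitions)."""
    return BrickTunnel(ratio)
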