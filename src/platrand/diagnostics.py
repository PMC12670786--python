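"""Exact probabilistic diagnostics for randomization procedures.

The central question for any unequal-allocation procedure is whether it is
allocation-ratio preserving (ARP): does the *unconditional* probability of
each arm equal the target proportion at every allocation step?  These
diagnostics answer it exactly, by forward dynamic programming over the
procedure's internal chain in rational arithmetic, and also provide the
distribution of arm totals and of the Euclidean imbalance

    Imb_i = sqrt( sum_j (N_ij - i*rho_j)^2 ),

the distance of the realized totals from the ideal point on the allocation
ray after ``i`` allocations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .ratio import AllocationRatio
from .state import Procedure

__all__ = [
    "UnconditionalProfile",
    "StateSpaceError",
    "unconditional_profile",
    "is_arp",
    "state_probabilities",
    "imbalance",
    "imbalance_tail",
    "tail_curve",
    "exhaustive_oracle",
    "monte_carlo_profile",
    "plot_imbalance_tail",
]

F = Fraction


class StateSpaceError(RuntimeError):
    """Raised when exact enumeration would exceed the state budget.

    Fall back to :func:`monte_carlo_profile` for an approximate profile.
    """


@dataclass
class UnconditionalProfile:
    """Per-step, per-arm unconditional allocation probabilities (exact)."""

    exact: list[tuple[Fraction, ...]]  # row i-1 = marginals of allocation i
    ratio: AllocationRatio

    @property
    def values(self) -> np.ndarray:
        return np.array([[float(p) for p in row] for row in self.exact])

    @property
    def n(self) -> int:
        return len(self.exact)

    def max_deviation(self) -> Fraction:
        rho = self.ratio.proportions
        dev = F(0)
        for row in self.exact:
            for p, r in zip(row, rho):
                dev = max(dev, abs(p - r))
        return dev

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": i + 1, "arm": j, "probability": float(p)}
            for i, row in enumerate(self.exact)
            for j, p in enumerate(row)
        ]
        return pd.DataFrame(rows)


def _forward(proc: Procedure, n: int, max_states: int = 10**6):
    """Yield (step, {internal state: exact probability}) for steps 0..n."""
    dist = {proc.initial_state(): F(1)}
    yield 0, dist
    for i in range(n):
        nxt: dict = {}
        marg = [F(0)] * proc.k
        for state, w in dist.items():
            for arm, p, ns in proc.transitions(state):
                nxt[ns] = nxt.get(ns, F(0)) + w * p
                marg[arm] += w * p
        if len(nxt) > max_states:
            raise StateSpaceError(
                f"state space exceeds {max_states} at step {i + 1}; "
                "use monte_carlo_profile instead"
            )
        dist = nxt
        yield i + 1, (dist, marg)


def unconditional_profile(proc: Procedure, n: int, max_states: int = 10**6) -> UnconditionalProfile:
    """Exact unconditional allocation probabilities for steps ``1..n``."""
    rows = []
    for step, payload in _forward(proc, n, max_states):
        if step == 0:
            continue
        _, marg = payload
        rows.append(tuple(marg))
    return UnconditionalProfile(rows, proc.ratio)


def is_arp(proc: Procedure, n: int, tol: float = 1e-9) -> tuple[bool, float]:
    """Test the ARP property: profile equals ``rho`` at every step ``1..n``.

    Returns ``(flag, max_deviation)``; the deviation is exact, the flag
    compares it against ``tol``.
    """
    prof = unconditional_profile(proc, n)
    dev = prof.max_deviation()
    return float(dev) <= tol, float(dev)


def state_probabilities(proc: Procedure, i: int, max_states: int = 10**6) -> dict[tuple, Fraction]:
    """Exact distribution of the arm totals ``N_i`` after ``i`` allocations."""
    for step, payload in _forward(proc, i, max_states):
        pass
    dist = payload[0] if step > 0 else payload
    out: dict[tuple, Fraction] = {}
    for state, w in dist.items():
        t = proc.totals(state)
        out[t] = out.get(t, F(0)) + w
    return out


def imbalance(totals: Iterable[int], ratio: AllocationRatio) -> float:
    """Euclidean distance of totals from the ideal point ``i*rho``."""
    totals = tuple(totals)
    i = sum(totals)
    rho = ratio.proportions
    return math.sqrt(sum(float(F(nj) - i * p) ** 2 for nj, p in zip(totals, rho)))


def _imb_sq(totals: tuple, ratio: AllocationRatio) -> Fraction:
    i = sum(totals)
    return sum((F(nj) - i * p) ** 2 for nj, p in zip(totals, ratio.proportions))


def imbalance_tail(proc: Procedure, i: int, x: float) -> float:
    """``P(Imb_i > x)``, strict, from the exact totals distribution."""
    if x < 0:
        return 1.0
    xsq = F(x) ** 2
    dist = state_probabilities(proc, i)
    return float(sum(w for t, w in dist.items() if _imb_sq(t, proc.ratio) > xsq))


def tail_curve(proc: Procedure, i: int, xs: Iterable[float]) -> pd.DataFrame:
    """Tail probabilities ``P(Imb_i > x)`` on a grid, for plotting or export."""
    dist = state_probabilities(proc, i)
    pairs = sorted((_imb_sq(t, proc.ratio), w) for t, w in dist.items())
    rows = []
    for x in xs:
        xsq = F(x) ** 2
        rows.append({"x": x, "tail": float(sum(w for s, w in pairs if s > xsq))})
    return pd.DataFrame(rows)


def exhaustive_oracle(proc: Procedure, n: int, max_paths: int = 5 * 10**7):
    """Independent verification by full path enumeration (depth-first).

    Enumerates every positive-probability path of the internal chain to
    depth ``n``, weighting each by its product of transition probabilities,
    and aggregates (a) per-step arm marginals and (b) the distribution of
    final totals.  Must agree exactly with the dynamic program; kept
    deliberately separate from it.
    """
    if n > 12:
        raise ValueError("exhaustive enumeration is limited to n <= 12")
    branching = max(1, len(proc.transitions(proc.initial_state())))
    if branching**n > max_paths:
        raise ValueError("path space too large for exhaustive enumeration")
    marg = [[F(0)] * proc.k for _ in range(n)]
    final: dict[tuple, Fraction] = {}

    def recurse(state, depth, weight):
        if depth == n:
            t = proc.totals(state)
            final[t] = final.get(t, F(0)) + weight
            return
        for arm, p, ns in proc.transitions(state):
            marg[depth][arm] += weight * p
            recurse(ns, depth + 1, weight * p)

    recurse(proc.initial_state(), 0, F(1))
    profile = UnconditionalProfile([tuple(row) for row in marg], proc.ratio)
    return profile, final


def simulate_state_counts(
    proc: Procedure, i: int, n_sim: int, rng: np.random.Generator
) -> dict[tuple, int]:
    """Simulate ``n_sim`` trials to step ``i``; counts of final arm totals.

    Equivalent to ``n_sim`` independent :meth:`Procedure.simulate` runs but
    propagates aggregate counts with per-state multinomial draws, so large
    Monte Carlo checks stay cheap.
    """
    counts = {proc.initial_state(): n_sim}
    for _ in range(i):
        nxt: dict = {}
        for state, c in counts.items():
            trans = proc.transitions(state)
            probs = np.array([float(p) for _, p, _ in trans])
            draw = rng.multinomial(c, probs / probs.sum())
            for (arm, p, ns), d in zip(trans, draw):
                if d:
                    nxt[ns] = nxt.get(ns, 0) + int(d)
        counts = nxt
    out: dict[tuple, int] = {}
    for state, c in counts.items():
        t = proc.totals(state)
        out[t] = out.get(t, 0) + c
    return out


def monte_carlo_profile(
    proc: Procedure, n: int, n_sim: int, seed: int
) -> np.ndarray:
    """Simulated per-step arm frequencies; fallback for huge state spaces."""
    rng = np.random.default_rng(seed)
    counts = np.zeros((n, proc.k))
    for _ in range(n_sim):
        for step, arm in enumerate(proc.simulate(n, rng)):
            counts[step, arm] += 1
    return counts / n_sim


def plot_imbalance_tail(
    procs: dict[str, Procedure],
    i: int,
    xs: Optional[Iterable[float]] = None,
    path: Optional[str] = None,
):
    """Step plot of ``P(Imb_i > x)`` for several procedures (one figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if xs is None:
        xs = np.linspace(0, 4, 161)
    xs = list(xs)
    fig, ax = plt.subplots()
    for name, proc in procs.items():
        curve = tail_curve(proc, i, xs)
        ax.step(curve["x"], curve["tail"], where="post", label=name)
    ax.set_xlabel("x")
    ax.set_ylabel(f"P(Imb_{i} > x)")
    ax.legend()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
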