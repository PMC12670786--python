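"""Exact rational linear programming over ``fractions.Fraction``.

The brick-tunnel transition solver certifies the allocation-ratio-preserving
property exactly, so its per-step linear programs must be solved in rational
arithmetic.  The problems are tiny (at most a few dozen variables), so a
textbook two-phase simplex with Bland's anti-cycling rule is both fast and
deterministic.

All inputs must be ``Fraction`` (or int); outputs are ``Fraction``.
"""

from __future__ import annotations

from fractions import Fraction

__all__ = ["lp_max", "LPInfeasible", "LPUnbounded"]


class LPInfeasible(ValueError):
    """The equality system A x = b, x >= 0 has no solution."""


class LPUnbounded(ValueError):
    """The objective is unbounded above on the feasible region."""


def _pivot(T, basis, r, c):
    piv = T[r][c]
    T[r] = [v / piv for v in T[r]]
    row_r = T[r]
    for k, row in enumerate(T):
        if k != r and row[c] != 0:
            f = row[c]
            T[k] = [a - f * b for a, b in zip(row, row_r)]
    basis[r] = c


def _simplex(T, basis, ncols):
    """Run simplex on tableau T (objective row last, maximized); Bland's rule.

    Only columns < ncols are eligible to enter the basis.
    """
    m = len(T) - 1
    while True:
        obj = T[m]
        col = -1
        for j in range(ncols):
            if obj[j] > 0:
                col = j
                break
        if col < 0:
            return
        best = None
        for r in range(m):
            if T[r][col] > 0:
                ratio = T[r][-1] / T[r][col]
                if best is None or ratio < best[0] or (
                    ratio == best[0] and basis[r] < basis[best[1]]
                ):
                    best = (ratio, r)
        if best is None:
            raise LPUnbounded("objective unbounded above")
        _pivot(T, basis, best[1], col)


def lp_max(c, A, b):
    """Maximize ``c . x`` subject to ``A x = b``, ``x >= 0``, exactly.

    Parameters
    ----------
    c : sequence of Fraction
        Objective coefficients (length n).
    A : sequence of rows (each length n) of Fraction
        Equality-constraint matrix.
    b : sequence of Fraction
        Right-hand sides (length m).

    Returns
    -------
    (value, x) : (Fraction, list[Fraction])
        Optimal objective value and one optimal vertex.  With Bland's rule
        and fixed input ordering the returned vertex is deterministic.
    """
    m, n = len(A), len(c)
    c = [Fraction(v) for v in c]
    # Phase 1: minimize the sum of artificial variables.
    T = []
    for i in range(m):
        row = [Fraction(v) for v in A[i]]
        bi = Fraction(b[i])
        if bi < 0:
            row = [-v for v in row]
            bi = -bi
        art = [Fraction(0)] * m
        art[i] = Fraction(1)
        T.append(row + art + [bi])
    obj = [Fraction(0)] * (n + m + 1)
    for i in range(m):
        for j in range(n + m + 1):
            obj[j] += T[i][j]
    for i in range(m):
        obj[n + i] = Fraction(0)
    T.append(obj)
    basis = [n + i for i in range(m)]
    _simplex(T, basis, n)
    if T[m][-1] != 0:
        raise LPInfeasible("equality system has no nonnegative solution")
    # Drive any degenerate artificials out of the basis.
    for r in range(m):
        if basis[r] >= n:
            for j in range(n):
                if T[r][j] != 0:
                    _pivot(T, basis, r, j)
                    break
    # Phase 2 on the original columns.
    T2 = [row[:n] + [row[-1]] for row in T[:m]]
    obj2 = c + [Fraction(0)]
    for r in range(m):
        bv = basis[r]
        if bv < n and obj2[bv] != 0:
            f = obj2[bv]
            obj2 = [a - f * g for a, g in zip(obj2, T2[r])]
    T2.append(obj2)
    basis2 = list(basis)
    _simplex(T2, basis2, n)
    x = [Fraction(0)] * n
    for r in range(m):
        if basis2[r] < n:
            x[basis2[r]] = T2[r][-1]
    return sum(ci * xi for ci, xi in zip(c, x)), x
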