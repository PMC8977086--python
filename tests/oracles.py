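"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's own computation paths: extent
analysis is redone in exact rational arithmetic with ``fractions``,
possibility degrees come from an exact line-intersection of the two
membership edges (located first by a coarse grid scan), the principal
eigenvalue from numpy's dense eigensolver, and the paired t-test from
``scipy.stats.ttest_rel``.
"""

from fractions import Fraction

import numpy as np


def _frac(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    return Fraction(float(x))  # exact binary-float conversion


def _triple(s):
    return s.as_tuple() if hasattr(s, "as_tuple") else tuple(s)


def rational_extents(matrix):
    """Synthetic extents recomputed exactly from the float entries."""
    A, M, B = matrix.components()
    n = matrix.n
    rows = []
    for i in range(n):
        ra = sum(_frac(A[i, j]) for j in range(n))
        rm = sum(_frac(M[i, j]) for j in range(n))
        rb = sum(_frac(B[i, j]) for j in range(n))
        rows.append((ra, rm, rb))
    ta = sum(r[0] for r in rows)
    tm = sum(r[1] for r in rows)
    tb = sum(r[2] for r in rows)
    return [(ra / tb, rm / tm, rb / ta) for ra, rm, rb in rows]


def intersection_possibility(s2, s1):
    """V(s2 >= s1) as the height of the sup-min of the two memberships.

    A coarse grid scan of ``min(mu1, mu2)`` brackets the maximizer, then
    the crossing of the falling edge of ``s2`` with the rising edge of
    ``s1`` is solved exactly in rational arithmetic.
    """
    a2, m2, b2 = (_frac(x) for x in _triple(s2))
    a1, m1, b1 = (_frac(x) for x in _triple(s1))
    if m2 >= m1:
        return 1.0
    if a1 >= b2:
        return 0.0
    if b2 == m2:  # vertical falling edge: height is mu1 at b2
        return float((b2 - a1) / (m1 - a1))
    if m1 == a1:  # vertical rising edge: height is mu2 at a1
        return float((b2 - a1) / (b2 - m2))
    # falling edge of s2: mu = (b2 - x)/(b2 - m2); rising edge of s1:
    # mu = (x - a1)/(m1 - a1).  Equate and solve for x exactly.
    denom = (b2 - m2) + (m1 - a1)
    x = (b2 * (m1 - a1) + a1 * (b2 - m2)) / denom
    h = (b2 - x) / (b2 - m2)
    assert 0 <= h <= 1
    return float(h)


def rational_extent_weights(matrix):
    """Extent-analysis weights in exact arithmetic (returns floats)."""
    S = rational_extents(matrix)
    n = len(S)
    V = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for k in range(n):
            if i != k:
                V[i][k] = intersection_possibility(S[i], S[k])
    d = [min(V[i][k] for k in range(n) if k != i) for i in range(n)]
    total = sum(d)
    return (
        [(float(s[0]), float(s[1]), float(s[2])) for s in S],
        np.array(V),
        np.array(d),
        np.array([x / total for x in d]),
    )


def eig_lambda_max(C: np.ndarray) -> float:
    """Principal eigenvalue via the dense eigensolver."""
    return float(np.max(np.linalg.eigvals(C).real))


def eig_consistency_ratio(C: np.ndarray, random_index: dict) -> float:
    n = C.shape[0]
    if n <= 2:
        return 0.0
    ci = (eig_lambda_max(C) - n) / (n - 1)
    return ci / random_index[n]
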