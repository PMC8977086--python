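"""Fuzzy pairwise-comparison matrices and extent-analysis weighting.

Implements the extent-analysis route to FAHP criterion weights:

1. fuzzy synthetic extent of each criterion,
   ``S_i = (row-sum of row i) (x) (grand total)^(-1)``;
2. degrees of possibility ``V(S_i >= S_k)`` between all extents;
3. minimum degree ``d'(A_i) = min_{k != i} V(S_i >= S_k)``;
4. normalization of the ``d'`` vector to the weight vector.

Judgment consistency is screened with Saaty's consistency ratio computed
on the crisp matrix of modal values; CR < 0.1 accepts a matrix.

Multi-expert panels are merged by the componentwise geometric mean of
the individual matrices, which preserves reciprocity exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateWeightsError, MatrixError, ZeroWeightWarning
from .fuzzy import TFN, TriangularFuzzyNumber

__all__ = [
    "FuzzyPairwiseMatrix",
    "ExtentAnalysisResult",
    "ConsistencyReport",
    "synthetic_extents",
    "possibility_degree",
    "extent_weights",
    "consistency_ratio",
    "aggregate_matrices",
    "RANDOM_INDEX",
]

_RECIP_RTOL = 1e-9

#: Saaty's random consistency index by matrix order.
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
    8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56,
    14: 1.57, 15: 1.59,
}


class FuzzyPairwiseMatrix:
    """One expert's (or an aggregated panel's) reciprocal matrix of TFNs.

    Internally the lower, modal and upper components are stored as three
    ``n x n`` float arrays.  The diagonal is the crisp ``(1, 1, 1)``; the
    lower triangle is the fuzzy reciprocal of the upper triangle.
    """

    def __init__(self, labels, entries) -> None:
        labels = [str(x) for x in labels]
        n = len(labels)
        if n < 2:
            raise MatrixError(f"need at least 2 criteria, got {n}")
        if len(set(labels)) != n:
            raise MatrixError(f"duplicate criterion labels in {labels}")
        rows = list(entries)
        if len(rows) != n or any(len(r) != n for r in rows):
            raise MatrixError(f"entries must form an {n}x{n} grid")
        A = np.empty((n, n))
        M = np.empty((n, n))
        B = np.empty((n, n))
        for i, row in enumerate(rows):
            for j, t in enumerate(row):
                A[i, j], M[i, j], B[i, j] = t.a, t.m, t.b
        self.labels = tuple(labels)
        self._a, self._m, self._b = A, M, B
        self._validate()

    # -- construction --------------------------------------------------

    @classmethod
    def from_upper(cls, labels, upper: dict) -> "FuzzyPairwiseMatrix":
        """Build from upper-triangle entries keyed by label pairs.

        ``upper`` maps ``(row_label, col_label)`` to a TFN for each pair
        with ``row`` before ``col`` in ``labels``; reciprocals and the
        diagonal are filled in.
        """
        labels = [str(x) for x in labels]
        n = len(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        one = TFN(1.0, 1.0, 1.0)
        grid = [[one for _ in range(n)] for _ in range(n)]
        seen = set()
        for (r, c), t in upper.items():
            if r not in idx or c not in idx:
                raise MatrixError(f"unknown label in pair ({r!r}, {c!r})")
            i, j = idx[r], idx[c]
            if i >= j:
                raise MatrixError(
                    f"pair ({r!r}, {c!r}) is not in the upper triangle"
                )
            grid[i][j] = t
            grid[j][i] = t.inverse()
            seen.add((i, j))
        missing = [
            (labels[i], labels[j])
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in seen
        ]
        if missing:
            raise MatrixError(f"missing upper-triangle comparisons: {missing}")
        return cls(labels, grid)

    @classmethod
    def _from_arrays(cls, labels, A, M, B) -> "FuzzyPairwiseMatrix":
        obj = cls.__new__(cls)
        obj.labels = tuple(str(x) for x in labels)
        obj._a, obj._m, obj._b = (
            np.asarray(A, float),
            np.asarray(M, float),
            np.asarray(B, float),
        )
        obj._validate()
        return obj

    def _validate(self) -> None:
        A, M, B = self._a, self._m, self._b
        n = self.n
        if np.any(A <= 0):
            raise MatrixError("all entry supports must be strictly positive")
        if np.any(A > M + 1e-12) or np.any(M > B + 1e-12):
            raise MatrixError("entry ordering a <= m <= b violated")
        d = np.arange(n)
        if not (
            np.allclose(A[d, d], 1.0)
            and np.allclose(M[d, d], 1.0)
            and np.allclose(B[d, d], 1.0)
        ):
            raise MatrixError("diagonal entries must be (1, 1, 1)")
        # reciprocity: entry[j][i] == inverse(entry[i][j])
        if not (
            np.allclose(A.T * B, 1.0, rtol=_RECIP_RTOL)
            and np.allclose(M.T * M, 1.0, rtol=_RECIP_RTOL)
        ):
            raise MatrixError(
                "reciprocity violated: entries[j][i] must equal "
                "1 / entries[i][j] componentwise"
            )

    # -- access --------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def entry(self, i: int, j: int) -> TriangularFuzzyNumber:
        return TFN(
            float(self._a[i, j]), float(self._m[i, j]), float(self._b[i, j])
        )

    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Copies of the (lower, modal, upper) component arrays."""
        return self._a.copy(), self._m.copy(), self._b.copy()

    def modal_matrix(self) -> np.ndarray:
        """Crisp matrix of modal values (used for the consistency ratio)."""
        return self._m.copy()

    def permuted(self, order) -> "FuzzyPairwiseMatrix":
        """Reorder criteria; useful for permutation-invariance checks."""
        order = list(order)
        ix = np.asarray(order)
        return FuzzyPairwiseMatrix._from_arrays(
            [self.labels[i] for i in order],
            self._a[np.ix_(ix, ix)],
            self._m[np.ix_(ix, ix)],
            self._b[np.ix_(ix, ix)],
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"FuzzyPairwiseMatrix(n={self.n}, labels={list(self.labels)})"


# ---------------------------------------------------------------------
# Extent analysis
# ---------------------------------------------------------------------

@dataclass
class ExtentAnalysisResult:
    """All intermediates of one extent-analysis run, kept for audit."""

    labels: tuple[str, ...]
    synthetic_extents: list[TriangularFuzzyNumber]
    possibility_matrix: np.ndarray  # V(S_i >= S_k) at [i, k]
    min_degrees: np.ndarray  # d'(A_i)
    weights: np.ndarray

    def weight_of(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])


def synthetic_extents(matrix: FuzzyPairwiseMatrix) -> list[TriangularFuzzyNumber]:
    """Fuzzy synthetic extent of each criterion.

    ``S_i`` is the fuzzy row sum of row ``i`` multiplied by the fuzzy
    reciprocal of the grand total of all entries, so its components are
    ``(row_a / total_b, row_m / total_m, row_b / total_a)``.
    """
    A, M, B = matrix._a, matrix._m, matrix._b
    row_a, row_m, row_b = A.sum(axis=1), M.sum(axis=1), B.sum(axis=1)
    tot_a, tot_m, tot_b = row_a.sum(), row_m.sum(), row_b.sum()
    return [
        TFN(row_a[i] / tot_b, row_m[i] / tot_m, row_b[i] / tot_a)
        for i in range(matrix.n)
    ]


def possibility_degree(
    s2: TriangularFuzzyNumber, s1: TriangularFuzzyNumber
) -> float:
    """Degree of possibility ``V(s2 >= s1)``.

    Equals 1 when the modal value of ``s2`` is at least that of ``s1``,
    0 when the supports are disjoint with ``s1`` entirely to the right,
    and otherwise the height of the intersection point of the falling
    edge of ``s2`` with the rising edge of ``s1``.
    """
    if s2.m >= s1.m:
        return 1.0
    if s1.a >= s2.b:
        return 0.0
    return (s1.a - s2.b) / ((s2.m - s2.b) - (s1.m - s1.a))


def extent_weights(
    matrix: FuzzyPairwiseMatrix, zero_floor: float | None = None
) -> ExtentAnalysisResult:
    """Criterion weights by extent analysis, with all intermediates.

    ``d'(A_i) = min_{k != i} V(S_i >= S_k)`` is normalized to sum one.
    Zero weights (the documented pathology of the method) are permitted
    but trigger :class:`ZeroWeightWarning`; passing ``zero_floor``
    substitutes that floor for zero degrees before normalization.
    """
    S = synthetic_extents(matrix)
    n = matrix.n
    V = np.ones((n, n))
    for i in range(n):
        for k in range(n):
            if i != k:
                V[i, k] = possibility_degree(S[i], S[k])
    mask = ~np.eye(n, dtype=bool)
    d = np.array([V[i][mask[i]].min() for i in range(n)])
    if np.all(d == 0):
        raise DegenerateWeightsError(
            "all minimum possibility degrees are zero; the panel is too "
            "polarized for extent analysis to produce weights"
        )
    dd = d.copy()
    if zero_floor is not None:
        dd[dd == 0] = zero_floor
    w = dd / dd.sum()
    if np.any(w == 0):
        zero_labels = [matrix.labels[i] for i in np.flatnonzero(w == 0)]
        warnings.warn(
            f"extent analysis assigned zero weight to {zero_labels}; this "
            "is the known pathology of the method for strongly dominated "
            "criteria",
            ZeroWeightWarning,
            stacklevel=2,
        )
    return ExtentAnalysisResult(
        labels=matrix.labels,
        synthetic_extents=S,
        possibility_matrix=V,
        min_degrees=d,
        weights=w,
    )


# ---------------------------------------------------------------------
# Consistency
# ---------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    """Saaty consistency screen of one comparison matrix."""

    n: int
    lambda_max: float
    consistency_index: float
    random_index: float
    consistency_ratio: float
    consistent: bool


def _principal_eigenvalue(C: np.ndarray, tol: float = 1e-10,
                          max_iter: int = 100_000) -> float:
    """Perron eigenvalue of a positive matrix by power iteration."""
    n = C.shape[0]
    x = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(max_iter):
        y = C @ x
        lam_new = y.sum()
        y /= lam_new
        if abs(lam_new - lam) < tol and np.max(np.abs(y - x)) < tol:
            return lam_new
        x, lam = y, lam_new
    return lam


def consistency_ratio(matrix: FuzzyPairwiseMatrix) -> ConsistencyReport:
    """Saaty consistency ratio of the crisp modal-value projection.

    The fuzzy matrix is projected to the crisp matrix of its modal
    values; ``lambda_max`` is its principal eigenvalue, ``CI = (lambda_max
    - n)/(n - 1)`` and ``CR = CI / RI(n)``.  Orders 1 and 2 are
    consistent by construction (CR = 0).
    """
    n = matrix.n
    if n not in RANDOM_INDEX:
        raise MatrixError(
            f"no random index for matrix order {n}; supported orders are "
            f"2..{max(RANDOM_INDEX)}"
        )
    C = matrix.modal_matrix()
    lam = _principal_eigenvalue(C)
    if n <= 2:
        ci = cr = 0.0
    else:
        ci = (lam - n) / (n - 1)
        if -1e-9 < ci < 0:  # numerical jitter below the lambda_max >= n bound
            ci = 0.0
        cr = ci / RANDOM_INDEX[n]
    return ConsistencyReport(
        n=n,
        lambda_max=lam,
        consistency_index=ci,
        random_index=RANDOM_INDEX[n],
        consistency_ratio=cr,
        consistent=cr < 0.1,
    )


# ---------------------------------------------------------------------
# Panel aggregation
# ---------------------------------------------------------------------

def aggregate_matrices(matrices) -> FuzzyPairwiseMatrix:
    """Panel consensus matrix: componentwise geometric mean across experts.

    All matrices must share the same criterion labels in the same order.
    The geometric mean commutes with the fuzzy reciprocal, so the
    aggregate is reciprocal whenever the inputs are.
    """
    matrices = list(matrices)
    if not matrices:
        raise MatrixError("need at least one matrix to aggregate")
    ref = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != ref:
            diff = set(ref).symmetric_difference(m.labels)
            raise MatrixError(
                f"matrices disagree on criterion labels; symmetric "
                f"difference: {sorted(diff) or 'same set, different order'}"
            )
    logs_a = np.mean([np.log(m._a) for m in matrices], axis=0)
    logs_m = np.mean([np.log(m._m) for m in matrices], axis=0)
    logs_b = np.mean([np.log(m._b) for m in matrices], axis=0)
    return FuzzyPairwiseMatrix._from_arrays(
        ref, np.exp(logs_a), np.exp(logs_m), np.exp(logs_b)
    )
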