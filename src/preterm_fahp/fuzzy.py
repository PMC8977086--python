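"""Triangular fuzzy numbers and linguistic scales.

A triangular fuzzy number (TFN) is the triple ``(a, m, b)`` with
``a <= m <= b``: membership rises linearly from 0 at ``a`` to 1 at the
modal value ``m`` and falls back to 0 at ``b``.  Shoulder TFNs with
``a == m`` (or ``m == b``) saturate at the domain boundary, so edge terms
of a linguistic scale keep full membership at the ends of the domain.

Linguistic scales map expert vocabulary ("low", "medium", ...) to TFNs.
The default case-judgment scale is an evenly spaced Ruspini partition of
[0, 1] (adjacent memberships sum to one everywhere), which makes
fuzzification of a crisp risk score a proper probability-like split over
at most two adjacent terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .errors import ScaleError

__all__ = [
    "TriangularFuzzyNumber",
    "TFN",
    "LinguisticTerm",
    "LinguisticScale",
    "default_case_scale",
    "default_comparison_scale",
    "saaty_intensity_tfn",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (report-display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A triangular fuzzy number ``(a, m, b)`` with ``a <= m <= b``."""

    a: float
    m: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a <= self.m <= self.b):
            raise ValueError(
                f"TFN ordering violated: need a <= m <= b, got "
                f"({self.a}, {self.m}, {self.b})"
            )

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return TriangularFuzzyNumber(
            self.a + other.a, self.m + other.m, self.b + other.b
        )

    def scaled(self, k: float) -> "TriangularFuzzyNumber":
        """Multiply by a nonnegative crisp scalar."""
        if k < 0:
            raise ValueError(f"scaling factor must be nonnegative, got {k}")
        return TriangularFuzzyNumber(k * self.a, k * self.m, k * self.b)

    def __mul__(self, k: float) -> "TriangularFuzzyNumber":
        return self.scaled(k)

    __rmul__ = __mul__

    def inverse(self) -> "TriangularFuzzyNumber":
        """Fuzzy reciprocal ``(1/b, 1/m, 1/a)``; requires positive support."""
        if self.a <= 0:
            raise ValueError(
                f"cannot invert TFN with nonpositive support: "
                f"({self.a}, {self.m}, {self.b})"
            )
        return TriangularFuzzyNumber(1.0 / self.b, 1.0 / self.m, 1.0 / self.a)

    # -- evaluation ----------------------------------------------------

    def membership(self, v: float) -> float:
        """Piecewise-linear membership degree of crisp ``v`` in [0, 1].

        Zero outside the open support, except at shoulders: if ``a == m``
        the left edge carries full membership, symmetrically for
        ``m == b``.  A degenerate singleton ``a == m == b`` has
        membership one exactly at that point.
        """
        if v < self.a or v > self.b:
            return 0.0
        if v <= self.m:
            if self.m == self.a:
                return 1.0
            return (v - self.a) / (self.m - self.a)
        if self.b == self.m:
            return 1.0
        return (self.b - v) / (self.b - self.m)

    def centroid(self) -> float:
        """Centroid defuzzification ``(a + m + b) / 3``."""
        return (self.a + self.m + self.b) / 3.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.m, self.b)


TFN = TriangularFuzzyNumber


def _normalize_label(label: str) -> str:
    """Case-insensitive, whitespace-trimmed label key ('LOW ' -> 'low')."""
    return "_".join(label.strip().lower().split())


@dataclass(frozen=True)
class LinguisticTerm:
    """A named fuzzy set on the judgment domain."""

    label: str
    tfn: TriangularFuzzyNumber

    def __post_init__(self) -> None:
        if not self.label or not self.label.strip():
            raise ScaleError("linguistic term label must be nonempty")


class LinguisticScale:
    """An ordered family of linguistic terms covering a closed domain.

    Parameters
    ----------
    terms:
        Terms ordered by strictly increasing modal value.
    domain:
        Closed interval the scale covers; every point of the domain must
        have positive membership in at least one term.
    aliases:
        Extra labels resolving directly to a TFN without being terms of
        the partition (e.g. ``"equal" -> (1, 1, 1)`` on the pairwise
        comparison scale, where the graded intensity-1 term is ``(1, 1, 2)``).
    """

    def __init__(
        self,
        terms: list[LinguisticTerm] | tuple[LinguisticTerm, ...],
        domain: tuple[float, float] = (0.0, 1.0),
        aliases: dict[str, TriangularFuzzyNumber] | None = None,
    ) -> None:
        self.terms = tuple(terms)
        self.domain = (float(domain[0]), float(domain[1]))
        self.aliases = {
            _normalize_label(k): v for k, v in (aliases or {}).items()
        }
        self._by_label = {}
        for t in self.terms:
            key = _normalize_label(t.label)
            if key in self._by_label:
                raise ScaleError(f"duplicate term label {t.label!r} in scale")
            self._by_label[key] = t
        self._validate()

    def _validate(self) -> None:
        if not self.terms:
            raise ScaleError("a linguistic scale needs at least one term")
        modes = [t.tfn.m for t in self.terms]
        if any(m2 <= m1 for m1, m2 in zip(modes, modes[1:])):
            raise ScaleError(
                f"term modal values must be strictly increasing, got {modes}"
            )
        lo, hi = self.domain
        if not lo < hi:
            raise ScaleError(f"empty scale domain {self.domain}")
        # Coverage: every domain point must activate some term.
        import numpy as np

        grid = np.linspace(lo, hi, 1001)
        for x in grid:
            if all(t.tfn.membership(float(x)) == 0.0 for t in self.terms):
                raise ScaleError(
                    f"scale does not cover its domain: no term active at {x:g}"
                )

    # -- lookups -------------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    def __contains__(self, label: str) -> bool:
        key = _normalize_label(label)
        return key in self._by_label or key in self.aliases

    def term(self, label: str) -> LinguisticTerm:
        key = _normalize_label(label)
        try:
            return self._by_label[key]
        except KeyError:
            raise ScaleError(
                f"unknown linguistic term {label!r}; scale terms are "
                f"{list(self.labels)}"
            ) from None

    def term_index(self, label: str) -> int:
        key = _normalize_label(label)
        for i, t in enumerate(self.terms):
            if _normalize_label(t.label) == key:
                return i
        raise ScaleError(
            f"unknown linguistic term {label!r}; scale terms are "
            f"{list(self.labels)}"
        )

    def tfn_for(self, label: str) -> TriangularFuzzyNumber:
        """Resolve a label (term or alias) to its TFN."""
        key = _normalize_label(label)
        if key in self.aliases:
            return self.aliases[key]
        return self.term(label).tfn

    def value_of(self, label: str) -> float:
        """Crisp (modal) judgment value associated with a term label."""
        return self.term(label).tfn.m

    # -- fuzzification -------------------------------------------------

    def fuzzify(self, v: float) -> dict[str, float]:
        """Membership degree of crisp ``v`` in every term of the scale."""
        lo, hi = self.domain
        if not lo <= v <= hi:
            raise ScaleError(
                f"value {v!r} outside the scale domain [{lo:g}, {hi:g}]"
            )
        return {t.label: t.tfn.membership(v) for t in self.terms}

    def is_ruspini(self, tol: float = 1e-9, n_grid: int = 1001) -> bool:
        """True if term memberships sum to one across the whole domain."""
        import numpy as np

        lo, hi = self.domain
        for x in np.linspace(lo, hi, n_grid)[1:-1]:
            s = sum(t.tfn.membership(float(x)) for t in self.terms)
            if abs(s - 1.0) > tol:
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LinguisticScale({list(self.labels)}, domain={self.domain})"


# ---------------------------------------------------------------------
# Default scales
# ---------------------------------------------------------------------

def default_case_scale() -> LinguisticScale:
    """Six-term case-judgment scale on [0, 1].

    An evenly spaced triangular Ruspini partition with modal points at
    multiples of 0.2.  The two edge terms are shoulders so the scale
    saturates at 0 and 1.
    """
    mk = TriangularFuzzyNumber
    terms = [
        LinguisticTerm("none", mk(0.0, 0.0, 0.2)),
        LinguisticTerm("low", mk(0.0, 0.2, 0.4)),
        LinguisticTerm("medium", mk(0.2, 0.4, 0.6)),
        LinguisticTerm("high", mk(0.4, 0.6, 0.8)),
        LinguisticTerm("very_high", mk(0.6, 0.8, 1.0)),
        LinguisticTerm("extreme", mk(0.8, 1.0, 1.0)),
    ]
    return LinguisticScale(terms, domain=(0.0, 1.0))


def saaty_intensity_tfn(i: int) -> TriangularFuzzyNumber:
    """Fuzzy Saaty intensity ``i`` in 1..9: ``(max(1, i-1), i, min(9, i+1))``."""
    if not 1 <= i <= 9:
        raise ValueError(f"comparison intensity must be in 1..9, got {i}")
    return TriangularFuzzyNumber(max(1, i - 1), i, min(9, i + 1))


_COMPARISON_LABELS = {
    1: "equally_important",
    2: "weakly_more_important",
    3: "moderately_more_important",
    4: "moderately_to_strongly",
    5: "strongly_more_important",
    6: "strongly_to_very_strongly",
    7: "very_strongly_more_important",
    8: "very_to_extremely",
    9: "extremely_more_important",
}


def default_comparison_scale() -> LinguisticScale:
    """Fuzzy Saaty 1-9 pairwise-comparison scale on [1, 9].

    Graded intensities are triangular with unit spread; the alias
    ``"equal"`` maps to the crisp ``(1, 1, 1)`` used on matrix diagonals
    and for exact indifference.  Integer aliases ``"1"``..``"9"`` resolve
    to the corresponding graded intensity.
    """
    terms = [
        LinguisticTerm(_COMPARISON_LABELS[i], saaty_intensity_tfn(i))
        for i in range(1, 10)
    ]
    aliases: dict[str, TriangularFuzzyNumber] = {
        "equal": TriangularFuzzyNumber(1.0, 1.0, 1.0),
    }
    aliases.update({str(i): saaty_intensity_tfn(i) for i in range(1, 10)})
    return LinguisticScale(terms, domain=(1.0, 9.0), aliases=aliases)
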