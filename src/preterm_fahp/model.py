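"""Risk hierarchy, case-judgment aggregation and model-based diagnosis.

The risk model is a two-level weighted hierarchy: the goal (preterm-birth
risk) splits into risk dimensions with weights ``W_j``, each dimension
into risk factors with local weights ``w_ij``.  For a case ``k`` judged
by a panel of obstetricians, each factor's linguistic judgments are
aggregated into the triple ``e_agg = (min, geometric mean, max)`` of the
experts' crisp judgment values, defuzzified to a degree, and combined
into the model-based diagnosis score

    MBD_k = sum_j W_j * sum_i w_ij * degree_{k, i, j}

which lies in [0, 1] when the weights are normalized.  The score is then
fuzzified back onto the case scale and labelled with the maximal-degree
term (ties resolved toward the higher-risk term -- the clinically
conservative choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConsistencyError,
    HierarchyError,
    JudgmentError,
    ZeroJudgmentWarning,
)
from .fahp import (
    ConsistencyReport,
    FuzzyPairwiseMatrix,
    consistency_ratio,
    extent_weights,
)
from .fuzzy import LinguisticScale, TFN, TriangularFuzzyNumber

__all__ = [
    "Factor",
    "Dimension",
    "RiskHierarchy",
    "ExpertCaseJudgment",
    "AggregatedJudgment",
    "Classification",
    "CaseAssessment",
    "OVERALL_FACTOR",
    "build_hierarchy",
    "aggregate_case",
    "mbd",
    "classify",
    "assess_case",
    "rank_cases",
]

#: Reserved factor name carrying an expert's overall case diagnosis;
#: ignored by the hierarchy model, consumed by the validation protocol.
OVERALL_FACTOR = "overall"

_WEIGHT_SUM_TOL = 0.01
ZERO_JUDGMENT_FLOOR = 1e-6


@dataclass(frozen=True)
class Factor:
    name: str
    local_weight: float


@dataclass(frozen=True)
class Dimension:
    name: str
    weight: float
    factors: tuple[Factor, ...]


@dataclass
class RiskHierarchy:
    """Goal -> risk dimensions -> risk factors, each node with a weight.

    Dimension weights and, within each dimension, factor local weights
    must each sum to one within 0.01 (published weight tables are
    rounded, so exact unity cannot be required).  The ``audit`` slot
    optionally retains the extent-analysis and consistency intermediates
    of the panel run that produced the weights.
    """

    goal: str
    dimensions: tuple[Dimension, ...]
    audit: dict | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.dimensions = tuple(
            Dimension(d.name, d.weight, tuple(d.factors))
            for d in self.dimensions
        )
        if not self.dimensions:
            raise HierarchyError("hierarchy needs at least one dimension")
        dsum = sum(d.weight for d in self.dimensions)
        if abs(dsum - 1.0) > _WEIGHT_SUM_TOL:
            raise HierarchyError(
                f"dimension weights sum to {dsum:.6f}, expected 1 "
                f"within {_WEIGHT_SUM_TOL}"
            )
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise HierarchyError(f"duplicate dimension names in {names}")
        seen: set[str] = set()
        for d in self.dimensions:
            if not d.factors:
                raise HierarchyError(f"dimension {d.name!r} has no factors")
            fsum = sum(f.local_weight for f in d.factors)
            if abs(fsum - 1.0) > _WEIGHT_SUM_TOL:
                raise HierarchyError(
                    f"local factor weights of dimension {d.name!r} sum to "
                    f"{fsum:.6f}, expected 1 within {_WEIGHT_SUM_TOL}"
                )
            for f in d.factors:
                if f.name in seen or f.name == OVERALL_FACTOR:
                    raise HierarchyError(
                        f"factor name {f.name!r} duplicated or reserved"
                    )
                seen.add(f.name)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for d in self.dimensions for f in d.factors)

    def global_weights(self) -> dict[str, float]:
        """Factor name -> global weight (dimension weight x local weight)."""
        return {
            f.name: d.weight * f.local_weight
            for d in self.dimensions
            for f in d.factors
        }

    def dimension_weights(self) -> dict[str, float]:
        return {d.name: d.weight for d in self.dimensions}


@dataclass(frozen=True)
class ExpertCaseJudgment:
    """One expert's linguistic judgments for one case.

    ``judgments`` maps factor names to linguistic labels of the case
    scale; the reserved key ``"overall"`` may carry the expert's holistic
    diagnosis of the case.
    """

    case_id: str
    expert_id: str
    judgments: dict[str, str]


@dataclass(frozen=True)
class AggregatedJudgment:
    """Panel consensus for one factor: ``e_agg = (min, geomean, max)``."""

    factor: str
    e_agg: TriangularFuzzyNumber
    degree: float


@dataclass(frozen=True)
class Classification:
    fuzzified: dict[str, float]
    diagnosis: str


@dataclass(frozen=True)
class CaseAssessment:
    """Full model output for one case, intermediates retained."""

    case_id: str
    judgments: tuple[AggregatedJudgment, ...]
    mbd: float
    fuzzified: dict[str, float]
    diagnosis: str


# ---------------------------------------------------------------------
# Hierarchy construction from expert matrices
# ---------------------------------------------------------------------

def build_hierarchy(
    dimension_matrix: FuzzyPairwiseMatrix,
    factor_matrices: dict[str, FuzzyPairwiseMatrix],
    goal: str = "preterm birth risk",
    force: bool = False,
    zero_floor: float | None = None,
) -> RiskHierarchy:
    """Derive a weighted hierarchy from pairwise-comparison matrices.

    ``factor_matrices`` must supply one matrix per dimension label of
    ``dimension_matrix``.  Every matrix must pass the CR < 0.1 screen
    unless ``force`` is set.  All extent-analysis and consistency
    intermediates are retained on ``hierarchy.audit``.
    """
    dims = dimension_matrix.labels
    missing = [d for d in dims if d not in factor_matrices]
    if missing:
        raise HierarchyError(f"missing factor matrices for dimensions {missing}")
    extra = [d for d in factor_matrices if d not in dims]
    if extra:
        raise HierarchyError(
            f"factor matrices given for unknown dimensions {extra}"
        )

    audit: dict = {"consistency": {}, "extent": {}}

    def check(name: str, matrix: FuzzyPairwiseMatrix) -> ConsistencyReport:
        rep = consistency_ratio(matrix)
        audit["consistency"][name] = rep
        if not rep.consistent and not force:
            raise ConsistencyError(
                f"matrix {name!r} has CR = {rep.consistency_ratio:.4f} >= 0.1; "
                "judgments are not consistent (CR < 0.1 required)"
            )
        return rep

    check("dimensions", dimension_matrix)
    dim_res = extent_weights(dimension_matrix, zero_floor=zero_floor)
    audit["extent"]["dimensions"] = dim_res

    dimensions = []
    for i, dname in enumerate(dims):
        fm = factor_matrices[dname]
        check(dname, fm)
        res = extent_weights(fm, zero_floor=zero_floor)
        audit["extent"][dname] = res
        factors = tuple(
            Factor(lab, float(w)) for lab, w in zip(fm.labels, res.weights)
        )
        dimensions.append(
            Dimension(dname, float(dim_res.weights[i]), factors)
        )
    return RiskHierarchy(goal=goal, dimensions=tuple(dimensions), audit=audit)


# ---------------------------------------------------------------------
# Case aggregation and scoring
# ---------------------------------------------------------------------

def _judgment_values(
    labels: list[str], scale: LinguisticScale, context: str
) -> np.ndarray:
    """Crisp judgment values for a list of labels, flooring lone zeros.

    Zeros are floored only in a *mixed* panel, where a single
    bottom-of-scale judgment would annihilate the geometric mean; a
    unanimous zero panel keeps its honest value of zero.
    """
    vals = np.array([scale.value_of(lab) for lab in labels], float)
    if np.any(vals == 0.0) and np.any(vals > 0.0):
        warnings.warn(
            f"zero judgment value(s) for {context} floored to "
            f"{ZERO_JUDGMENT_FLOOR:g} before the geometric mean",
            ZeroJudgmentWarning,
            stacklevel=3,
        )
        vals = np.where(vals == 0.0, ZERO_JUDGMENT_FLOOR, vals)
    return vals


def aggregate_case(
    judgments: list[ExpertCaseJudgment],
    scale: LinguisticScale,
    defuzz: str = "modal",
) -> list[AggregatedJudgment]:
    """Aggregate a panel's per-factor judgments for one case.

    Each expert label is mapped to its crisp judgment value (the term's
    modal value); the panel consensus per factor is the triple
    ``e_agg = (min, geometric mean, max)`` of those values.  The degree
    entering the MBD sum is ``e_agg.m`` (``defuzz="modal"``) or the TFN
    centroid (``defuzz="centroid"``).

    With two or more experts, zero values are floored at ``1e-6`` (with
    a warning) so a single bottom-of-scale judgment cannot annihilate
    the geometric mean.
    """
    if not judgments:
        raise JudgmentError("need at least one expert judgment")
    if defuzz not in ("modal", "centroid"):
        raise ValueError(f"unknown defuzzification method {defuzz!r}")
    case_ids = {j.case_id for j in judgments}
    if len(case_ids) > 1:
        raise JudgmentError(
            f"judgments mix several cases: {sorted(case_ids)}"
        )
    factor_sets = [
        frozenset(k for k in j.judgments if k != OVERALL_FACTOR)
        for j in judgments
    ]
    if len(set(factor_sets)) > 1:
        raise JudgmentError("experts do not cover the same factor set")

    out = []
    for factor in sorted(factor_sets[0]):
        vals = _judgment_values(
            [j.judgments[factor] for j in judgments], scale,
            f"factor {factor!r}",
        )
        # zeros survive the floor only for a single-expert panel
        gm = float(np.exp(np.log(vals).mean())) if np.all(vals > 0) else 0.0
        lo, hi = float(vals.min()), float(vals.max())
        gm = min(max(gm, lo), hi)  # guard log/exp round-off at the bounds
        e_agg = TFN(lo, gm, hi)
        degree = e_agg.m if defuzz == "modal" else e_agg.centroid()
        out.append(AggregatedJudgment(factor, e_agg, degree))
    return out


def mbd(hierarchy: RiskHierarchy, degrees: dict[str, float]) -> float:
    """Model-based diagnosis: the weights-times-degrees double sum.

    ``MBD = sum_j W_j sum_i w_ij degree_ij`` over every factor of the
    hierarchy; with normalized weights this is a convex combination of
    the degrees and therefore lies in [0, 1].
    """
    missing = [f for f in hierarchy.factor_names if f not in degrees]
    if missing:
        raise JudgmentError(f"degrees missing for factors {missing}")
    bad = {
        f: degrees[f]
        for f in hierarchy.factor_names
        if not 0.0 <= degrees[f] <= 1.0
    }
    if bad:
        raise JudgmentError(f"degrees outside [0, 1]: {bad}")
    total = 0.0
    for d in hierarchy.dimensions:
        inner = sum(f.local_weight * degrees[f.name] for f in d.factors)
        total += d.weight * inner
    return total


def classify(mbd_value: float, scale: LinguisticScale) -> Classification:
    """Fuzzify a crisp MBD score and pick the linguistic diagnosis.

    The diagnosis is the term with maximal membership; exact ties are
    broken toward the later (higher-risk) term.
    """
    fuzzified = scale.fuzzify(mbd_value)
    best = max(enumerate(fuzzified.items()), key=lambda t: (t[1][1], t[0]))
    return Classification(fuzzified=fuzzified, diagnosis=best[1][0])


def assess_case(
    hierarchy: RiskHierarchy,
    judgments: list[ExpertCaseJudgment],
    scale: LinguisticScale,
    defuzz: str = "modal",
) -> CaseAssessment:
    """End-to-end assessment of one case: aggregate, score, classify."""
    agg = aggregate_case(judgments, scale, defuzz=defuzz)
    known = set(hierarchy.factor_names)
    unknown = sorted(a.factor for a in agg if a.factor not in known)
    if unknown:
        raise JudgmentError(
            f"judged factors not present in the hierarchy: {unknown}"
        )
    degrees = {a.factor: a.degree for a in agg}
    score = mbd(hierarchy, degrees)
    cls = classify(score, scale)
    return CaseAssessment(
        case_id=judgments[0].case_id,
        judgments=tuple(agg),
        mbd=score,
        fuzzified=cls.fuzzified,
        diagnosis=cls.diagnosis,
    )


def rank_cases(assessments: list[CaseAssessment]) -> list[CaseAssessment]:
    """Cases in descending MBD order; ties keep their input order."""
    if not assessments:
        raise JudgmentError("need at least one assessment to rank")
    return sorted(assessments, key=lambda a: -a.mbd)
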