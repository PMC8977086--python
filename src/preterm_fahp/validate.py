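"""Expert-versus-model validation of the risk scores.

The validation protocol has three steps: (1) aggregate the panel's
holistic ("overall") diagnoses of each case into an expert reference
score via the same ``(min, geometric mean, max)`` consensus used for
factor judgments; (2) score the same cases with the fuzzy model; and
(3) run a paired two-sided Student t-test on the per-case differences.
The model is declared concordant with the panel when the test finds no
significant difference at the 5% level (p >= 0.05).

Score-level agreement can mask categorical disagreement, so the report
also compares the model's linguistic diagnosis with the panel's modal
(most frequent) overall label per case.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import JudgmentError
from .fuzzy import LinguisticScale
from .model import (
    CaseAssessment,
    ExpertCaseJudgment,
    OVERALL_FACTOR,
    RiskHierarchy,
    assess_case,
)
from .model import _judgment_values

__all__ = [
    "CaseComparison",
    "ValidationReport",
    "expert_reference_score",
    "paired_t_test",
    "validate_cases",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CaseComparison:
    case_id: str
    expert_score: float
    model_score: float
    expert_label: str
    model_label: str
    labels_agree: bool


@dataclass
class ValidationReport:
    n_cases: int
    mean_difference: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    concordant: bool
    per_case: list[CaseComparison] = field(default_factory=list)

    @property
    def label_agreement_rate(self) -> float:
        if not self.per_case:
            return float("nan")
        return sum(c.labels_agree for c in self.per_case) / len(self.per_case)


def expert_reference_score(
    judgments: list[ExpertCaseJudgment], scale: LinguisticScale
) -> float:
    """Panel consensus score for one case's overall diagnoses.

    The geometric mean (the modal component of ``e_agg``) of the crisp
    values of the experts' ``"overall"`` labels.
    """
    if not judgments:
        raise JudgmentError("need at least one expert judgment")
    labels = []
    for j in judgments:
        if OVERALL_FACTOR not in j.judgments:
            raise JudgmentError(
                f"expert {j.expert_id!r} gave no overall diagnosis for "
                f"case {j.case_id!r}"
            )
        labels.append(j.judgments[OVERALL_FACTOR])
    vals = _judgment_values(labels, scale, "the overall diagnosis")
    if np.any(vals == 0.0):
        return 0.0
    return float(np.exp(np.log(vals).mean()))


def paired_t_test(
    expert_scores, model_scores, alpha: float = ALPHA
) -> ValidationReport:
    """Two-sided paired t-test of expert versus model scores.

    Differences ``d_i = expert_i - model_i`` are tested against mean
    zero with the sample standard deviation (n - 1 denominator) and a
    Student t reference with n - 1 degrees of freedom.  Degenerate
    zero-variance differences give t = 0, p = 1 when the mean is also
    zero, and (by convention) p = 0 with an infinite t otherwise.
    """
    e = np.asarray(expert_scores, float)
    m = np.asarray(model_scores, float)
    if e.shape != m.shape or e.ndim != 1:
        raise JudgmentError(
            f"score lists must be 1-d and equally long, got shapes "
            f"{e.shape} and {m.shape}"
        )
    n = len(e)
    if n < 2:
        raise JudgmentError("need at least two paired scores")
    d = e - m
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, mean), 0.0
    else:
        t = mean / (sd / math.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return ValidationReport(
        n_cases=n,
        mean_difference=mean,
        t_statistic=t,
        degrees_of_freedom=n - 1,
        p_value=p,
        concordant=p >= alpha,
    )


def _modal_label(
    judgments: list[ExpertCaseJudgment], scale: LinguisticScale
) -> str:
    """Most frequent overall label; ties go to the higher-risk term."""
    counts = Counter(
        j.judgments[OVERALL_FACTOR] for j in judgments
    )
    return max(
        counts,
        key=lambda lab: (counts[lab], scale.term_index(lab)),
    )


def validate_cases(
    hierarchy: RiskHierarchy,
    judgments: list[ExpertCaseJudgment],
    scale: LinguisticScale,
    defuzz: str = "modal",
    alpha: float = ALPHA,
) -> ValidationReport:
    """Run the full validation protocol on a judged case series.

    ``judgments`` must carry, per case and expert, labels for every
    hierarchy factor plus the reserved ``"overall"`` diagnosis column.
    """
    by_case: dict[str, list[ExpertCaseJudgment]] = {}
    for j in judgments:
        by_case.setdefault(j.case_id, []).append(j)
    if len(by_case) < 2:
        raise JudgmentError("validation needs at least two cases")
    expert_scores, model_scores, per_case = [], [], []
    for case_id, group in by_case.items():
        assessment: CaseAssessment = assess_case(
            hierarchy, group, scale, defuzz=defuzz
        )
        e_score = expert_reference_score(group, scale)
        expert_scores.append(e_score)
        model_scores.append(assessment.mbd)
        e_label = _modal_label(group, scale)
        per_case.append(
            CaseComparison(
                case_id=case_id,
                expert_score=e_score,
                model_score=assessment.mbd,
                expert_label=e_label,
                model_label=assessment.diagnosis,
                labels_agree=(
                    scale.term_index(e_label)
                    == scale.term_index(assessment.diagnosis)
                ),
            )
        )
    report = paired_t_test(expert_scores, model_scores, alpha=alpha)
    report.per_case = per_case
    return report
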