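"""Synthetic expert panels and case populations with known ground truth.

The study data behind the preterm-birth model -- the 35-expert pairwise
matrices and the 153 validation cases -- were never deposited, so this
module generates stand-ins with controllable ground truth:

* :func:`simulate_panel` draws each expert's pairwise matrix as a noisy
  multiplicative perturbation of a planted weight vector, discretized to
  the fuzzy Saaty 1-9 scale the questionnaire would impose.
* :func:`simulate_cases` draws per-case latent severity labels per risk
  factor and lets each simulated expert echo them with a configurable
  concordance, erring by at most one severity step otherwise.  Each
  expert also reports an ``"overall"`` diagnosis, sampled from the fuzzy
  memberships of the case's latent MBD, so the expert reference score is
  an unbiased (quantized) reading of the latent model score.

All randomness flows from one root seed through ``numpy`` seed-sequence
spawning, one independent substream per expert or case, so identical
specs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fahp import FuzzyPairwiseMatrix
from .fuzzy import LinguisticScale, TFN, saaty_intensity_tfn
from .model import (
    ExpertCaseJudgment,
    OVERALL_FACTOR,
    RiskHierarchy,
    mbd,
)

__all__ = [
    "PanelSpec",
    "CasePopulationSpec",
    "DEFAULT_RISK_MIX",
    "simulate_panel",
    "simulate_cases",
]

#: Default latent severity mix of the simulated validation population.
#: Emulates a referred, at-risk case series: every factor carries at
#: least moderate expression, so the degenerate bottom term ("none",
#: crisp value 0) arises only through rater error.
DEFAULT_RISK_MIX = {
    "medium": 0.40,
    "high": 0.30,
    "very_high": 0.20,
    "extreme": 0.10,
}


@dataclass(frozen=True)
class PanelSpec:
    """An expert panel whose judgments perturb known true weights.

    ``noise_sigma`` is the standard deviation of the lognormal
    multiplicative noise applied to each true ratio ``w_i / w_j`` before
    the ratio is snapped to the questionnaire's 1-9 intensity grid.
    """

    true_weights: tuple[float, ...]
    n_experts: int = 35
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, float)
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if w.ndim != 1 or len(w) < 2 or np.any(w <= 0):
            raise ValueError("true_weights must be >= 2 positive values")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"true_weights must sum to 1, got {w.sum():.9f}")


@dataclass(frozen=True)
class CasePopulationSpec:
    """A synthetic case series judged by a synthetic expert panel.

    ``concordance`` is the probability that an expert reports a case's
    latent label exactly; otherwise the expert reports an adjacent term
    of the scale (uniform over the one or two neighbors).
    """

    n_cases: int = 153
    n_experts: int = 35
    risk_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_MIX)
    )
    concordance: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_experts < 1:
            raise ValueError("n_cases and n_experts must be >= 1")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must lie in [0, 1]")
        total = sum(self.risk_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"risk_mix proportions must sum to 1, got {total:.9f}"
            )
        if any(p < 0 for p in self.risk_mix.values()):
            raise ValueError("risk_mix proportions must be nonnegative")


# ---------------------------------------------------------------------
# Expert panels (pairwise matrices)
# ---------------------------------------------------------------------

def _snap_intensity(r: float) -> int:
    """Nearest 1-9 intensity for a crisp ratio >= 1 (half rounds up)."""
    return int(min(9, max(1, np.floor(r + 0.5))))


def simulate_panel(spec: PanelSpec, labels) -> list[FuzzyPairwiseMatrix]:
    """One noisy, scale-discretized pairwise matrix per expert.

    For each expert and each criterion pair ``i < j`` the perceived
    ratio is ``(w_i / w_j) * exp(sigma * z)`` with ``z`` standard
    normal; the ratio (or its reciprocal, if below one) is snapped to
    the nearest 1-9 intensity and replaced by that intensity's fuzzy
    Saaty TFN, the mirror cell by its fuzzy reciprocal.
    """
    labels = [str(x) for x in labels]
    w = np.asarray(spec.true_weights, float)
    if len(labels) != len(w):
        raise ValueError(
            f"{len(labels)} labels given for {len(w)} true weights"
        )
    n = len(labels)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_experts)
    matrices = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        one = TFN(1.0, 1.0, 1.0)
        grid = [[one for _ in range(n)] for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                z = rng.standard_normal()
                r = (w[i] / w[j]) * np.exp(spec.noise_sigma * z)
                if r == 1.0:
                    continue  # genuinely equal criteria: crisp (1, 1, 1)
                if r > 1.0:
                    t = saaty_intensity_tfn(_snap_intensity(r))
                    grid[i][j], grid[j][i] = t, t.inverse()
                else:
                    t = saaty_intensity_tfn(_snap_intensity(1.0 / r))
                    grid[j][i], grid[i][j] = t, t.inverse()
        matrices.append(FuzzyPairwiseMatrix(labels, grid))
    return matrices


# ---------------------------------------------------------------------
# Case populations (linguistic judgments)
# ---------------------------------------------------------------------

def _neighbor_indices(idx: int, n_terms: int) -> list[int]:
    return [k for k in (idx - 1, idx + 1) if 0 <= k < n_terms]


def simulate_cases(
    spec: CasePopulationSpec,
    hierarchy: RiskHierarchy,
    scale: LinguisticScale,
    include_overall: bool = True,
    return_truth: bool = False,
):
    """Per-expert linguistic judgment records for a synthetic case series.

    Each case draws one latent severity term per risk factor from
    ``spec.risk_mix``; experts echo the latent term with probability
    ``spec.concordance`` and report an adjacent term otherwise.  When
    ``include_overall`` is set, the case's latent overall diagnosis is
    sampled from the fuzzified latent MBD (for a Ruspini scale this
    makes the latent overall value an unbiased quantization of the
    latent score), and the experts report it under the reserved
    ``"overall"`` key with the same concordance error model.

    With ``return_truth`` the per-case ground truth is returned as a
    second value: a list of ``{"case_id", "labels", "mbd", "overall"}``
    dicts holding the latent factor labels and the latent model score.
    """
    term_labels = list(scale.labels)
    n_terms = len(term_labels)
    mix_probs = np.zeros(n_terms)
    for lab, p in spec.risk_mix.items():
        mix_probs[scale.term_index(lab)] = p
    factors = hierarchy.factor_names

    def noisy_report(rng: np.random.Generator, latent_idx: int) -> int:
        if rng.random() < spec.concordance:
            return latent_idx
        nbrs = _neighbor_indices(latent_idx, n_terms)
        return nbrs[rng.integers(len(nbrs))]

    case_streams = np.random.SeedSequence(spec.seed).spawn(spec.n_cases)
    width = len(str(spec.n_cases))
    ewidth = len(str(spec.n_experts))
    records: list[ExpertCaseJudgment] = []
    truth: list[dict] = []
    for c, ss in enumerate(case_streams):
        rng = np.random.default_rng(ss)
        case_id = f"case_{c + 1:0{width}d}"
        latent = {
            f: int(rng.choice(n_terms, p=mix_probs)) for f in factors
        }
        degrees = {f: scale.value_of(term_labels[i])
                   for f, i in latent.items()}
        score = mbd(hierarchy, degrees)
        latent_overall: int | None = None
        if include_overall:
            memb = np.array(
                [v for v in scale.fuzzify(score).values()], float
            )
            memb /= memb.sum()
            latent_overall = int(rng.choice(n_terms, p=memb))
        truth.append(
            {
                "case_id": case_id,
                "labels": {f: term_labels[i] for f, i in latent.items()},
                "mbd": score,
                "overall": (
                    None if latent_overall is None
                    else term_labels[latent_overall]
                ),
            }
        )
        for e in range(spec.n_experts):
            judged = {
                f: term_labels[noisy_report(rng, latent[f])]
                for f in factors
            }
            if latent_overall is not None:
                judged[OVERALL_FACTOR] = term_labels[
                    noisy_report(rng, latent_overall)
                ]
            records.append(
                ExpertCaseJudgment(
                    case_id=case_id,
                    expert_id=f"expert_{e + 1:0{ewidth}d}",
                    judgments=judged,
                )
            )
    if return_truth:
        return records, truth
    return records
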