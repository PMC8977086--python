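# Methods

This note documents the model implemented by `preterm_fahp`, the
choices made where the published record leaves the design open, and
what the synthetic-data experiments do and do not show.

## Triangular fuzzy numbers and linguistic scales

All fuzzy quantities are triangular fuzzy numbers (TFNs) `(a, m, b)`
with `a ≤ m ≤ b`: membership rises linearly from 0 at `a` to 1 at the
modal value `m` and falls to 0 at `b`. Shoulder TFNs (`a = m` or
`m = b`) are permitted so edge terms saturate at domain boundaries.
Addition and nonnegative scaling are componentwise; the fuzzy
reciprocal is `(1/b, 1/m, 1/a)` and requires strictly positive support.

**Case-judgment scale** (domain [0, 1], six terms):

| term      | TFN            |
|-----------|----------------|
| none      | (0, 0, 0.2)    |
| low       | (0, 0.2, 0.4)  |
| medium    | (0.2, 0.4, 0.6)|
| high      | (0.4, 0.6, 0.8)|
| very_high | (0.6, 0.8, 1)  |
| extreme   | (0.8, 1, 1)    |

This is the unique evenly spaced triangular Ruspini partition (adjacent
memberships sum to one everywhere) that reproduces the published
worked-example memberships f(low) = 0.19 and f(medium) = 0.81 at
MBD = 0.36120376. The exact term set of the original study instrument
was published only as an image, so this scale is a *reconstruction*;
the number and labels of terms beyond "low" and "medium" are inferred.
Scales are fully replaceable through the hierarchy configuration file.

**Pairwise-comparison scale** (domain [1, 9]): fuzzy Saaty intensities
`ĩ = (max(1, i−1), i, min(9, i+1))` for `i = 1..9`. The alias `"equal"`
resolves to the crisp `(1, 1, 1)` used on matrix diagonals and for
exact indifference; graded intensity 1, `(1, 1, 2)`, expresses a weak,
direction-carrying near-tie. Reciprocal comparisons are entered by
orientation (which cell of the matrix holds the intensity), not by
dedicated reciprocal terms.

Label matching is case-insensitive and whitespace-normalized because
judgment CSVs are typically hand-entered. Reports display two decimals
with half-up rounding; all internal computation is full precision.

## Extent-analysis weights

For an `n × n` reciprocal fuzzy matrix the synthetic extent of
criterion *i* is the fuzzy row sum multiplied by the fuzzy reciprocal
of the grand total, i.e. componentwise
`(row_a / total_b, row_m / total_m, row_b / total_a)`. The degree of
possibility is

    V(S2 ≥ S1) = 1                        if m2 ≥ m1
               = 0                        if a1 ≥ b2
               = (a1 − b2) / ((m2 − b2) − (m1 − a1))   otherwise,

the height of the intersection of the falling edge of S2 with the
rising edge of S1. Weights normalize `d′(A_i) = min_{k≠i} V(S_i ≥ S_k)`.

Extent analysis is known to assign *exactly zero* weight to criteria
whose synthetic extents do not overlap the strongest one. The package
permits this but always emits `ZeroWeightWarning`; an optional
`zero_floor` substitutes a small positive floor before normalization
(off by default). A corollary worth knowing: on a perfectly consistent
*crisp* matrix the extents are crisp, so every dominated criterion
collapses to possibility zero and only the top criterion keeps weight —
extent analysis needs fuzzy spread to resolve a full ranking.

## Consistency

The consistency ratio is computed on the crisp projection of a fuzzy
matrix to its modal values: `λ_max` from power iteration (tolerance
1e-10; a dense eigensolver serves as an independent oracle in the test
suite), `CI = (λ_max − n)/(n − 1)`, `CR = CI / RI(n)` with Saaty's
random-index table for `n ≤ 15`. `CR < 0.1` accepts a matrix; orders 1
and 2 are consistent by construction. `build_hierarchy` computes and
stores a report per expert-facing matrix and refuses inconsistent input
unless forced.

## Panel aggregation

Pairwise matrices from several experts are merged by the componentwise
geometric mean, which commutes with the fuzzy reciprocal and therefore
preserves matrix reciprocity exactly. (The alternative
`(min, geomean, max)` envelope aggregation breaks reciprocity and is
not offered for matrices.)

Per-case factor judgments aggregate as `e_agg = (min, geometric mean,
max)` of the experts' crisp judgment values, one value per linguistic
label — the term's modal value, consistent with the modal-value
convention used for the consistency ratio. Zeros (the "none" term) are
floored at 1e-6 with `ZeroJudgmentWarning` when the panel is mixed,
because a single bottom-of-scale judgment would otherwise annihilate
the geometric mean; a unanimous zero panel keeps its honest zero. The
geometric mean is therefore ill-conditioned near the bottom of the
scale — a documented limitation of this consensus operator.

## Model-based diagnosis

`MBD_k = Σ_j W_j Σ_i w_ij · degree_{k,i,j}`, a double weighted sum over
dimensions and factors. The degree entering the sum is the modal
component `e_agg.m` (maximum-membership defuzzification; the only
component the consensus step computes by geometric mean). Centroid
defuzzification `(a + m + b)/3` is available behind `defuzz="centroid"`
for sensitivity analysis; which of the two the original study used is
not recoverable, so modal is the default. With normalized weights the
score is a convex combination of degrees: it lies in [0, 1], is
monotone in every degree, and is invariant to factor ordering (all
property-tested).

Classification fuzzifies the score on the case scale and takes the
maximal-membership term, breaking exact ties toward the later
(higher-risk) term — the clinically conservative default.

## Packaged hierarchy

The default hierarchy ships the published panel-elicited dimension
weights (0.339, 0.306, 0.166, 0.1342, 0.042, 0.0115; they sum to
0.9987 because the published values are rounded — weight-sum checks
tolerate 0.01). Factor-level weights were never published in
machine-readable form: the package ships the factor names attested in
the published narrative (late booking, maternal age, education level,
marital status; substance use, alcohol, smoking; type 1/2 diabetes,
chronic blood pressure, cardiovascular disease; previous early
gestational age, previous stillbirth; early rupture of the amniotic
sac, fetal fibronectin; three unnamed gynecological/obstetric
placeholders) with *uniform* local weights, clearly labelled
reconstructed. Users with the true values supply them via the
configuration file.

## Synthetic data

`simulate_panel` draws each expert's matrix from a planted weight
vector `w`: the perceived ratio for pair `(i, j)` is
`(w_i/w_j)·exp(σz)` with `z` standard normal (lognormal multiplicative
noise, the standard AHP simulation model), snapped to the nearest 1–9
intensity to mimic questionnaire discretization; an exact ratio of 1
yields the crisp "equal". Default panel: 35 experts, σ = 0.05.

For parameter-recovery experiments the planted dimension weights are
`(0.30, 0.24, 0.17, 0.13, 0.09, 0.07)` — ordered like the published
dimension ranking but with milder dispersion. This is deliberate:
with the published spread (ratio ≈ 29 between extreme dimensions) the
snapped extents of the weakest dimensions separate from the strongest
and extent analysis zeroes them out, making full-ranking recovery
impossible *for any estimator of this family*; the milder vector keeps
every synthetic extent overlapping the strongest one so the recovery
question is well-posed.

`simulate_cases` draws one latent severity term per factor per case
from a configurable `risk_mix`, and each simulated expert echoes the
latent term with probability `concordance` (default 0.9), otherwise
reporting an adjacent term (uniform over neighbors) — experts rarely
mislabel by more than one severity step. The default mix
`{medium 0.40, high 0.30, very_high 0.20, extreme 0.10}` emulates a
referred, at-risk case series (the study population of 153 "carefully
selected" cases): every factor carries at least moderate expression,
so the degenerate "none" term (crisp value 0, where the geometric-mean
consensus is ill-conditioned, see above) arises only through rater
error. Each expert also reports an overall diagnosis under the reserved
`"overall"` key: the case's latent overall term is sampled from the
fuzzified latent MBD, using the Ruspini memberships as probabilities —
for this partition `Σ_t f_t(x)·m_t = x`, so the latent overall judgment
is an *unbiased* quantization of the latent score rather than a
deterministic rounding (which would inject a grid-alignment bias of up
to ±0.02 into expert-versus-model differences and confound the
validation protocol with an artifact of the generator).

Randomness flows from a single root seed through numpy seed-sequence
spawning with one substream per expert/case; identical specs give
byte-identical output.

What the generator does *not* emulate: real clinical covariates
(gestational age, laboratory values), correlated factor severities
within a case, systematic expert biases (leniency/severity), or
missing judgments. Passing synthetic-data tests therefore demonstrates
the pipeline's internal correctness and statistical behaviour under
the stated error model, not clinical validity on real populations.

## Validation protocol

Per case, the expert reference score is the geometric-mean consensus
of the panel's overall diagnoses; the model score is the MBD. A
two-sided paired Student t-test (sample sd, `n − 1` denominator,
`n − 1` df) tests the mean difference; concordance is declared at
p ≥ 0.05. (The published account phrases the concordance criterion as
"no statistical difference (p < 0.05)", which is internally
contradictory; p ≥ 0.05 is the conventional reading and the one
implemented.) Zero-variance differences short-circuit: t = 0, p = 1
if the mean is also zero, else p = 0. One pooled test is run over all
cases; per-case score and label comparisons are reported alongside,
since a score-level t-test can mask categorical disagreement.

Simulation results computed by the test suite under the default
conditions: with 153 cases, 35 experts and concordance 0.9, the
protocol declares concordance in ≥ 90% of 100 replicates; under the
null (both score lists drawn from the same distribution) the empirical
type-I error over 1000 replicates lies in (0.03, 0.07) at α = 0.05.

## Numerical conventions

- Reciprocity tolerance 1e-9 (relative) for in-memory matrices, 1e-6
  for hand-entered CSVs.
- Geometric means are computed in log space; the modal component of
  `e_agg` is clamped into `[min, max]` to absorb log/exp round-off.
- Power iteration: tolerance 1e-10 on both eigenvalue and eigenvector;
  tiny negative CI from round-off (below 1e-9) is clamped to zero.
- Ties: `classify` breaks toward the higher-risk term; `rank_cases` is
  stable (input order) on equal scores; the minimum in `d′` is exact,
  with no jitter.
- Problem sizes in the test suite (100 random matrices for the oracle
  equivalence check, 20 recovery replicates, 100 + 1000 validation
  replicates) were chosen to make the statistical assertions stable
  under their fixed seeds.

## Known limitations

- Extent analysis' zero-weight pathology (above); consider the
  `zero_floor` option or a different weighting scheme when criteria
  differ by more than about one order of magnitude.
- The geometric-mean consensus collapses toward zero whenever any
  expert uses the bottom term; the 1e-6 floor is a pragmatic, not a
  principled, remedy.
- The packaged factor-level weights are uniform placeholders, not
  elicited values; dimension-level conclusions are faithful to the
  published elicitation, factor-level ones are not.
- No calibration against real birth outcomes is included or implied.
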