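# preterm-fahp

Fuzzy analytic hierarchy process (FAHP) risk assessment for preterm
birth (delivery before 37 completed weeks of gestation).

Preterm birth is multifactorial, and much of what an experienced
obstetrician knows about a case resists crisp measurement. This package
implements a fuzzy multi-criteria pipeline that turns expert *linguistic*
judgments into a reproducible risk score: criterion weights are elicited
from fuzzy pairwise comparisons by an expert panel, each pregnant-woman
case is judged factor-by-factor on a linguistic scale, and the judgments
are aggregated into a model-based diagnosis (MBD) score and a linguistic
risk label. It is aimed at biostatisticians and clinical researchers who
want to build, audit, or stress-test this class of scoring model —
including fully synthetic ground-truth experiments when no study data
are available.

## The model

**Weights.** Each expert compares sibling criteria pairwise on a fuzzy
Saaty 1–9 scale of triangular fuzzy numbers (TFNs). Panel matrices are
merged by the componentwise geometric mean, and weights come from
extent analysis: the fuzzy synthetic extent of criterion *i* is

    S_i = ( Σ_j a_ij , Σ_j m_ij , Σ_j b_ij ) ⊗ ( Σ_ij entries )⁻¹ ,

criteria are compared by degrees of possibility V(S_i ≥ S_k), and the
weight vector normalizes d′(A_i) = min_{k≠i} V(S_i ≥ S_k). Judgment
consistency is screened with Saaty's consistency ratio on the matrix of
modal values; CR < 0.1 accepts a matrix.

**Scoring.** For case *k*, the panel's judgments of factor *i* in
dimension *j* aggregate to e_agg = (min, geometric mean, max) of the
crisp judgment values; the modal component is the degree entering

    MBD_k = Σ_j FAHP_j · Σ_i FAHP_ij · degree_{k,i,j} ∈ [0, 1],

which is fuzzified back onto the six-term case scale (none, low,
medium, high, very_high, extreme — an evenly spaced Ruspini partition
of [0, 1]) and labelled by maximal membership.

**Validation.** Expert holistic diagnoses and model scores for the same
cases are compared with a two-sided paired t-test; the model is
concordant with the panel when p ≥ 0.05. Label-level agreement is
reported alongside.

The packaged default hierarchy carries the published dimension weights
elicited from a panel of 35 obstetricians (information during pregnancy
0.339, medical history of previous pregnancies 0.306, clinical medical
history 0.166, gynecological/obstetric history 0.1342, behavioral/
lifestyle 0.042, socio-personal-economic 0.0115); factor-level weights
are reconstructed as uniform and are meant to be replaced via the
configuration file (see `docs/methods.md`).

## Worked example

```python
from preterm_fahp import classify, default_case_scale

scale = default_case_scale()
cls = classify(0.36120376, scale)   # an MBD score for one case
print({k: round(v, 2) for k, v in cls.fuzzified.items() if v > 0})
print(cls.diagnosis)
```

prints

```
{'low': 0.19, 'medium': 0.81}
medium
```

i.e. a case scoring MBD = 0.36120376 belongs to the "low" risk set with
degree 0.19 and to the "medium" risk set with degree 0.81, so the model
diagnoses medium risk.

End-to-end from the shell, with synthetic data:

```sh
preterm-fahp init-config hierarchy.json
preterm-fahp simulate-cases hierarchy.json --cases 153 --experts 35 \
    --seed 7 --out cases.csv
preterm-fahp assess hierarchy.json cases.csv --out report.csv
preterm-fahp validate hierarchy.json cases.csv --out validation.json
```

`assess` prints one line per case in descending score order, e.g.
`case_016: MBD 0.781712 -> very_high`; `validate` prints the paired-t
summary — for this seed, `t = -0.0837182 (df = 152), p = 0.933391`,
label agreement 0.76, so the model and the simulated panel are
concordant (p ≥ 0.05).

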