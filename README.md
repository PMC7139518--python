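# csfmarkov

Steady-state Markov modelling of lymphocyte differentiation and
trafficking between peripheral blood (PB) and cerebrospinal fluid (CSF).

## The problem

The central nervous system is immunologically privileged: only selected
lymphocyte subsets cross the blood–CSF barrier, and their
naive/differentiated balance inside the CSF differs markedly from the
blood. Clinically, the CSF profile is informative (multiple sclerosis,
Susac syndrome, treatment monitoring) but lumbar puncture is invasive
and rarely repeatable, whereas blood is easy to sample. `csfmarkov`
implements a minimal compartmental model that (i) summarises paired
PB/CSF flow-cytometry cohorts as four interpretable transition rates,
(ii) makes the structural identifiability of those rates explicit, and
(iii) predicts a patient's CSF profile from blood measurements alone.

## The model

One lymphocyte lineage occupies four stages — PB/naive (x₁), CSF/naive
(x₂), PB/differentiated (x₃), CSF/differentiated (x₄) — connected by
four per-step transition probabilities: α₁ (naive PB→CSF migration),
β₁ (differentiation within PB), α₂ (differentiated PB→CSF migration)
and β₂ (differentiation within CSF). With the total pool normalised to
1, the stationary distribution is the solution of a linear system
A(α, β) X = b(α, β):

    x₁ = 1 − α₁ − β₁
    (1 + β₂) x₂ = α₁
    (1 + α₂) x₃ = β₁
    x₄ = β₂ x₂ + α₂ x₃

which conserves mass (Σxᵢ = 1) and is nonnegative whenever
α₁ + β₁ ≤ 1. Rates are calibrated to a cohort of per-patient stage
vectors X_k by constrained least squares,

    (1/K) Σ_k ‖X(α, β) − X_k‖² → min  subject to 0 ≤ α, β ≤ 1,

and the package reports that the steady state pins down only the three
combinations s₁ = α₁+β₁, s₂ = α₁/(1+β₂), s₃ = β₁/(1+α₂) — including an
explicit constructor for the one-parameter family of rate vectors with
an identical steady state. A continuous-time birth–death simulation
(immigration with stage assignment at birth, unit clearance,
exponential differentiation/migration clocks) serves as an independent
stochastic oracle for the stationary distribution, and a synthetic
cohort generator emulates flow-cytometry records (binomial event noise,
paucicellular CSF, optional logit-scale patient heterogeneity) so the
whole pipeline is testable without patient data.

A table of published cohort-calibrated rates for CD4/CD8 T cells, B
cells and NK cells in five clinical groups (non-inflammatory controls,
treatment-naive RRMS, RRMS under natalizumab or alemtuzumab, Susac
syndrome) ships with the package (`reference_rates`).

## Worked example

```python
from csfmarkov import (MarkovStageModel, GeneratorConfig, generate_cohort,
                       reference_rates)

rates = reference_rates("CD8", "controls")            # published control CD8 rates
cohort = generate_cohort(rates, GeneratorConfig(n_patients=75, seed=1))
res = MarkovStageModel.from_cohort(cohort).fit()
print(res.summary())
```

```
Four-stage blood/CSF trafficking model — least-squares calibration
====================================================================
cell type: CD8             patients (K): 75
assembly:  count_weighted  starts: 82   converged: True
objective (mean squared deviation): 1.703284e-05
--------------------------------------------------------------------
rate        estimate (%)   identifiable combination
alpha1          0.100692   s1 = alpha1+beta1      = 0.107286
alpha2           0.47086   s2 = alpha1/(1+beta2)  = 0.00100684
beta1            10.6279   s3 = beta1/(1+alpha2)  = 0.105781
beta2         0.00764324
--------------------------------------------------------------------
stationary stages (x1..x4): 0.89271 0.00101 0.10578 0.00050
PB naive/diff: 89.41/10.59 %   CSF naive/diff: 66.90/33.10 %
equal-objective family width (delta interval): 0.000498
====================================================================
```

The synthetic cohort was generated from rates with α₁+β₁ = 0.107146,
x₂ = 0.0010090, x₃ = 0.1056418: the fitted *combinations* recover those
values to within the cohort's sampling noise, while the raw α₂ and β₂
land elsewhere on the equal-objective family — exactly the
degeneracy the family-width line flags. Prediction from blood alone,
with bootstrap ranges from resampling the training cohort:

```python
pred = res.predict_csf((0.80, 0.20), bootstrap=200, seed=1)
```

```
predicted CSF naive: 51.72% [51.02, 52.56]
predicted CSF diff:  48.28% [47.44, 48.98]
```

i.e. a patient with 20% differentiated CD8 T cells in blood is
predicted to carry ~48% differentiated CD8 T cells in the CSF under the
control-cohort dynamics (CSF differentiation runs ~1.9× faster than in
blood for this lineage).

The same operations are available from the shell:

```sh
csfmarkov simulate --cell-type CD8 --group controls --n-patients 75 \
    --seed 1 --out cohort.csv
csfmarkov fit --input cohort.csv --out fit.json
csfmarkov predict --cell-type CD8 --pb-input pb.csv --train cohort.csv \
    --bootstrap 200 --seed 1 --out pred.json
csfmarkov oracle --cell-type CD8 --group controls --birth-rate 10000 \
    --horizon 200 --burn-in 20 --seed 0
```

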