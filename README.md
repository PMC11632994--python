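# dnmbc

Survival analysis and individualized treatment recommendation for *de novo*
metastatic breast cancer (dnMBC), exercised end-to-end on simulated
registry-style cohorts.

Whether dnMBC patients benefit from surgery of the primary tumour — and if
so, whether systemic therapy should come before the operation — is
contested, and the answer differs across patient subgroups. This package
implements the full analysis a registry study of that question would run,
for three treatment strategies:

* **CW** — chemotherapy without surgery,
* **NS** — neoadjuvant systemic therapy followed by surgery,
* **SC** — surgery followed by chemotherapy,

together with a seeded synthetic-cohort generator whose every patient
carries a known ground-truth log-risk under each arm, so that every
estimator in the pipeline can be validated against the truth rather than
against an external registry.

## What is inside

| Layer | Module | Contents |
| --- | --- | --- |
| Simulation | `dnmbc.cohort` | covariate schemes, proportional-hazards event model with treatment-by-covariate interactions, confounded multinomial-logit arm assignment, administrative censoring; named scenarios (`default`, `null`, `recovery`) |
| Classical statistics | `dnmbc.survival` | Kaplan–Meier, *k*-sample log-rank, Benjamini–Hochberg, Cox partial-likelihood fit (Newton–Raphson; Efron/Breslow ties), Harrell's C, percentile bootstrap |
| Matching | `dnmbc.matching` | logistic propensity scores, 1:1:2 (NS:SC:CW) greedy nearest-neighbour matching on the propensity logit with an SD-scaled caliper, balance diagnostics |
| Risk model | `dnmbc.network` | feed-forward Cox log-risk network in pure NumPy (ReLU, batch norm, dropout, Adam with weight decay, gradient clipping, LR schedules, early stopping, random hyperparameter search) |
| Recommendation | `dnmbc.recommend` | counterfactual rec function, concordant/anti-recommended grouping, K-M/log-rank/Cox validation |
| Orchestration | `dnmbc.pipeline`, `dnmbc.cli` | 7:3 split, descriptive and Cox tables, stratified K-M panels with BH correction, C-statistic comparison with bootstrap CIs, the full study runner |

## The model

Survival follows a proportional-hazards model
`λ(t; x, τ) = λ0(t) · exp(h_τ(x))` with a Weibull baseline `λ0` and an
arm-specific log-risk `h_τ(x)`. The neural risk model replaces the linear
predictor of a Cox model with a multilayer perceptron ending in a single
output node and is trained on the Breslow-form negative log partial
likelihood, which is free of `λ0`. Treatment recommendation uses

```
rec_ij(x) = log( λ(t; x, τ=i) / λ(t; x, τ=j) ) = h_i(x) − h_j(x)
```

so `rec_ij(x) > 0` means strategy *i* carries the higher death risk and *j*
should be preferred; the baseline hazard cancels by construction. Model 1
decides surgery versus no surgery on the whole cohort; model 2 decides
neoadjuvant-first versus surgery-first among surgical patients.

## Worked example

`python examples/06_full_study.py` runs the whole study on a simulated
cohort of 4 000 patients (seed 0) and prints, among other tables:

```
matched triplets: 379 (minimum balance p = 0.628)

C statistics (train/test, with 95% bootstrap CIs):
                     model split     c  ci_low  ci_high    n
    deep model 1 (surgery) train 0.702   0.685    0.713 2800
    deep model 1 (surgery)  test 0.684   0.666    0.706 1200
                linear Cox  test 0.695   0.678    0.717 1200
                   subtype  test 0.612   0.592    0.635 1200
                metastases  test 0.605   0.585    0.628 1200
deep model 2 (neoadjuvant)  test 0.642   0.595    0.686  319

recommendation validation (HR < 1 favours following the model):
                     model split    hr  hr_low  hr_high  cox_p
    deep model 1 (surgery) train 0.687   0.615    0.767  0.000
    deep model 1 (surgery)  test 0.759   0.641    0.900  0.001
```

Reading this: after 1:1:2 matching all covariates are balanced
(all p > 0.05); both risk networks and the linear Cox model discriminate
survival far better than single-factor scores; and patients whose received
therapy matches the model-1 recommendation have markedly better overall
survival on held-out data (test HR 0.76, CI excluding 1). Because the data
are simulated, the recommendation can also be scored against the
generator's truth: `examples/05_treatment_recommendation.py` reports ~86 %
agreement with the true optimal policy on an independent cohort.

The other examples (`examples/01`–`05`) each demonstrate one capability:
simulation, the survival core, matching, network training, and
recommendation.

A thin CLI mirrors the main entry points:

```
dnmbc simulate --n 4000 --seed 1 --out cohort.csv
dnmbc match --cohort cohort.csv --out matched.csv --caliper 0.05 --seed 1
dnmbc run --outdir study_out --seed 1
```

## Scope and limitations

The cohort generator emulates the *structure* of a registry cohort
(confounded assignment, covariate-dependent hazards, administrative
censoring), not any registry's actual frequencies; see `docs/methods.md`
for the modelling assumptions, parameter choices and known limitations,
including why a correctly specified additive Cox model is a near-ceiling
competitor on this generator family.
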