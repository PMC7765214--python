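# ssbn — Sons-and-Spouses Bayesian networks for discrete survey data

`ssbn` is a toolkit for probabilistic explanation of a rare binary
outcome in categorical survey data — the setting of epidemiological
risk-factor studies, where an analyst wants to know not just *whether*
a condition can be predicted, but *which configuration of factors best
explains it* and *what happens to the risk* under hypothetical profiles.

It implements, end to end:

* **Discrete Bayesian networks** with exact inference.  The joint
  distribution factorises by the chain rule,
  `P(x_1..x_n) = prod_i P(x_i | pa_i)`; posteriors come from Bayes'
  theorem via variable elimination.
* **Supervised structure learning**: Naive Bayes; Tree-Augmented Naive
  Bayes (TAN, a Chow-Liu tree over the features under conditional mutual
  information given the class); and **Sons and Spouses (SS)** — a TAN
  variant that learns the target's local neighbourhood (its children,
  the "sons", which may be interlinked, plus those children's other
  parents, the "spouses") and prunes everything else, acting as a
  feature selector.
* **Strength metrics** in bits: mutual information, KL-divergence arc
  force, relative binary mutual information, and single-state Bayes
  factors.
* **Most-relevant-explanation search**: the partial assignment x
  maximising the generalized Bayes factor
  `GBF(x; e) = P(e|x) / P(e|x-bar)` for a target hypothesis e, searched
  by a seeded genetic algorithm and validated against an exhaustive
  oracle.
* **What-if analysis**: the posterior of the target under a hypothetical
  evidence profile versus the unconditioned prior.
* **Evaluation**: stratified 10-fold cross-validation with pooled
  accuracy / precision / recall / F-measure and rank-based AUC.
* **A synthetic cohort generator** with a known ground-truth network
  (rare target, sons, spouses, distractors, missing entries), so every
  claim above is testable without any external data.

## Worked example

```python
from ssbn import CohortSpec, SonsAndSpouses, simulate_study_cohort

# a survey-shaped synthetic cohort with a known generating network
data, truth = simulate_study_cohort(CohortSpec(seed=0), 10_000)
data = data.subset_columns(
    [v.name for v in data.variables if v.name != "eq5d_level"]
)

result = SonsAndSpouses(data, "depression").fit()
print(result.summary())
```

```
SonsAndSpouses results
======================
Target:              depression
Observations used:   8509 (excluded 1491)
Variables in model:  14
Arcs:                13
Direct children:     7 (diabetes, gender, marital_status, subjective_health, arthritis, economic_status, income_quartile)
Spouses:             6 (age, glycated_hemoglobin, hemoglobin, hypertension, oral_examination, smoking)
BIC:                 -103551.20

Strength of direct and indirect factors
----------------------------------------
               node  relative_binary_mi_pct  posterior_mean_value
           diabetes                  8.6284                0.8943
             gender                  7.6769                0.1250
     marital_status                  7.0056                2.3713
  subjective_health                  6.9969                1.9348
...
```

1,491 of 10,000 records were dropped for heavy missingness; the learner
then recovered exactly the generating neighbourhood — 7 direct children
and 6 spouses, 13 variables in all — and ranked them by how much of the
target's entropy each explains (`relative_binary_mi_pct`).

```python
w = result.what_if(truth.high_risk_profile)
print(f"prior {100*w.prior:.2f}% -> posterior {100*w.posterior:.2f}%")
# prior 5.47% -> posterior 98.61%
```

A subject matching the designed high-risk profile moves from the 5.5%
baseline risk to near certainty under the fitted model.  The GA search
for such profiles is `result.most_probable_cause()`, which returns the
top explanations ranked by GBF.

## Command line

Every step is also a CLI subcommand (`ssbn simulate`, `learn`,
`metrics`, `mre`, `whatif`, `cv`), reading CSV cohorts with a JSON
codebook and writing networks as JSON or XMLBIF.  All commands are pure
functions of their inputs and explicit seeds.

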