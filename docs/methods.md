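# Methods

## Model

`ssbn` works with discrete Bayesian networks: a directed acyclic graph
over categorical variables whose joint distribution factorises as

    P(x_1, ..., x_n) = prod_i P(x_i | pa_i),

one conditional probability table (CPT) per variable.  CPT parent
configurations are enumerated in odometer order over the declared parent
order, last parent varying fastest, so serialised tables are bit-stable.
Posterior queries use exact variable elimination with a min-degree
ordering; a brute-force full-joint enumerator is kept as an independent
oracle (and as the fallback whose answers the test suite compares against
to 1e-10).  The networks targeted here have tens of nodes with
cardinalities 2-5, so exact inference is always affordable; approximate
inference is deliberately out of scope.

Impossible evidence (probability zero) raises a dedicated error rather
than returning a zero distribution: callers that probe arbitrary
configurations — the GA fitness function, the classifier — must decide
explicitly what to do (score zero, fall back to the prior).

## Structure learners

Three supervised learners around a single binary target:

* **Naive Bayes** — every feature a child of the target.
* **TAN** — features additionally joined by the maximum-weight spanning
  tree under conditional mutual information given the target (Chow-Liu on
  the class-conditional distribution), edges directed outward from the
  root.  The root is the feature with the highest mutual information with
  the target; spanning-tree and root ties break lexicographically so the
  result is order-independent.
* **Sons and Spouses (SS)** — learns the target's local neighbourhood:
  its children ("sons", which may be interlinked) and the other parents of
  those children ("spouses", with no arc to or from the target), pruning
  everything else.  This is simultaneously a classifier and a feature
  selector.

The SS search is a reconstruction (the original is a feature of a
commercial tool with no published algorithm): candidate sons must exceed a
relative-binary-MI threshold (default 0.1% of the target's entropy);
stage one adds `target -> candidate` arcs whose BIC delta is positive,
stage two greedily adds `feature -> son` arcs by largest positive BIC
delta subject to acyclicity and a `max_parents` cap (default 3); finally
unconnected variables are dropped.  Adding the class arc before augmenting
arcs prevents indirect correlations from exhausting a son's parent budget
before the target is considered.  With incomplete data, the two families
compared by a BIC delta are always scored on the same rows (complete for
child, current parents and the candidate parent); comparing
available-case log-likelihoods computed on different row subsets
systematically favours the smaller subset and admits noise parents.

Parameters are MAP estimates with a Dirichlet pseudo-count (default 1,
Laplace).  Rows incomplete for a family are dropped from that family's
counts only; records missing more than 20% of their columns are excluded
up front, mirroring the survey-cleaning step the generator emulates.

## Strength metrics

All information quantities are base-2 (bits).  Per-variable strength
against the target is reported as relative binary mutual information,
`100 * MI(x; target) / H(target)`.  Arc force is the KL divergence
between the network's joint and the joint of the arc-deleted structure
refit on the data, by exact enumeration (for a two-node network this
equals the empirical mutual information, which the tests assert to 1e-9).
Single-state Bayes factors are likelihood ratios
`P(x=s | t) / P(x=s | t-bar)` — consistent with the generalized Bayes
factor below, not the lift `P(s|t)/P(s)`.  Because published tables of
this quantity are ambiguous about direction, reports always carry both
target directions explicitly.

The **generalized Bayes factor** of an explanation x for evidence e is

    GBF(x; e) = P(e | x) / P(e | x-bar),

with the complement handled by total probability,
`P(e | x-bar) = (P(e) - P(e, x)) / (1 - P(x))` — never by enumerating the
complement configurations.  The conditional form GBF(y; e | x) takes the
complement over y only, and the chain-rule product over an evidence split
telescopes back to the direct GBF; the suite checks this identity to
1e-9 over random networks and all orderings.  Ratios with a zero
denominator and non-zero numerator return `inf` (a sentinel, not an
exception); P(x) of 0 or 1 raises an ill-defined-complement error.

## Most-relevant-explanation search

The search for the partial assignment maximising GBF for a fixed target
hypothesis uses a generational GA: one gene per candidate variable (a
state index or "unset"), tournament selection (size 3), one-point
crossover (rate 0.8), per-gene mutation (rate 1/L), elitism (2), population
100, 50 generations.  The source being reconstructed names no GA
hyperparameters; these defaults are conventional desk-scale values, frozen
before any benchmark was run, and all randomness flows through one integer
seed.  Fitness is total: an empty explanation scores 1, an ill-defined
GBF scores 0.  Every distinct chromosome ever evaluated is cached, which
both speeds the run and provides the candidate pool for the final ranking
(ties: fewer bound variables, then lexicographic).  An exhaustive
enumerator over the same space (capped at 1e6 configurations) is the
oracle: on 8-10 binary candidates the GA finds its optimum in >= 18/20
seeded runs and can never exceed it.  For small state spaces the full
joint table is cached once per search, making a fitness evaluation three
array slices.

## Evaluation

Stratified k-fold cross-validation (scikit-learn's `StratifiedKFold`,
shuffled with the caller's seed).  The confusion matrix is pooled across
held-out folds and accuracy / precision / recall / F are computed once
from the pooled counts (micro-average) — far more stable than per-fold
ratios when positives are ~5% of the data.  AUC is the Mann-Whitney rank
statistic of the positive-class scores (`roc_auc_score`).  A classifier
that never predicts the positive class has no defined F-measure; it is
flagged degenerate and F is reported as absent rather than zero, matching
how benchmark tables mark such classifiers "N/A".  Prediction is argmax
posterior with ties going to the negative class; records whose evidence
the network deems impossible fall back to the prior and are counted.

## Synthetic cohort generator

The generator emulates the shape of a national health-survey extract used
for depression modelling; its defaults are the study conditions of the
package's tests, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| target prevalence | 0.055 | rare binary outcome of the emulated survey |
| sons / spouses / noise | 7 / 6 / 6 | neighbourhood sizes of the emulated network (13 related variables) |
| cardinalities | 2-5 | survey item levels |
| son row contrast | >= 0.3 | minimum CPT difference between target states, every spouse configuration |
| per-cell missing rate | 0.01 | sporadic item non-response |
| poor-responder share / rate | 0.15 / 0.5 | a minority of records with heavy missingness, so the >20%-missing exclusion filter actually bites (~15% excluded) |

Spouse and noise marginals are drawn near-balanced (Dirichlet
concentration 8, floored at 0.1), as designed survey strata (age bands,
income quartiles) typically are.  Missingness is completely at random —
a two-component MCAR mixture over records; real non-response is usually
informative, so conclusions about missing-data robustness do not
transfer.  The binary target is the collapse of a three-level
none/some/extreme item; cohorts can carry the raw item so the merge step
is itself testable.  The raw item determines the target and must never be
fed to a learner as a feature.

Each ground truth stores a designed high-risk profile: the
single-state-per-son assignment maximising the target posterior, found
exactly by marginalising the joint onto (target, sons) and scanning the
grid.  What-if queries against it must beat the prior, which the tests
check by enumeration.

What passing tests show — and do not show.  Recovery results (TAN
skeleton 10/10 at n = 20000, SS sons-recall and noise-precision 1.0)
hold under the generator's conditions: faithful distributions, known
cardinalities, MCAR missingness, effect sizes at or above the configured
contrast.  They say nothing about misspecified cardinalities, selection
bias, or informative missingness.

## Numerical choices and limitations

* CPT rows must sum to 1 within 1e-9; posteriors by elimination agree
  with enumeration to 1e-10; serialization round-trips preserve a fixed
  posterior to 1e-12 (probabilities are written with full `repr`
  precision).
* BIC uses natural logs with the standard `0.5 ln(N) q (r-1)` penalty,
  N being the rows actually scored.
* Parameter recovery on n = 1e5 cohort samples reaches max absolute CPT
  error ~0.02-0.03, floored by binomial noise: rows conditioned on the
  rare target state (and a spouse state) see only a few hundred to a few
  thousand records, so per-cell standard errors of 0.01-0.03 are
  irreducible at this prevalence regardless of design.
* The GA is a heuristic; on large candidate spaces it may return a local
  optimum.  The exhaustive oracle is capped at 1e6 configurations.
* Only discrete variables are supported; continuous measurements must be
  discretised (the CSV reader applies declared cut-points, half-open
  bins, last bin closed).

## Problem sizes used by the acceptance script

`scripts/acceptance.py` draws a 10,120-record cohort (the scale of the
emulated survey extract), excludes heavy-missingness records (~15%),
learns all three structures, runs 10-fold CV on the retained ~8.6k
records, searches explanations over the 13 selected variables with the
default GA, evaluates the high-risk what-if profile, and refits the
generating network on 1e5 fresh samples.  It completes in well under a
minute on one CPU; every quantity is recomputed from the seed passed on
the command line.
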