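"""Most-relevant-explanation search: which partial assignment of risk
factors best explains a target hypothesis, scored by the generalized
Bayes factor.

The search space — one gene per candidate variable, each gene a state
index or "unset" — is explored with a plain generational genetic
algorithm: tournament selection, one-point crossover, small per-gene
mutation, and elitism.  An exhaustive enumerator over the same space
serves as the oracle for small problems.  All randomness flows through
the caller-supplied seed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigurationError,
    IllDefinedComplementError,
    ImpossibleEvidenceError,
    TooLargeError,
    ValidationError,
)
from .inference import JointLookup
from .metrics import gbf
from .network import Assignment, BayesianNetwork, posterior

logger = logging.getLogger(__name__)

UNSET = -1


@dataclass
class GAConfig:
    population_size: int = 100
    generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1/L, L = number of candidates
    elite_count: int = 2
    tournament_size: int = 3
    allow_unset: bool = True
    top_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.crossover_rate,):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("rates must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigurationError("rates must lie in [0, 1]")
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if not 0 <= self.elite_count < self.population_size:
            raise ConfigurationError("elite_count must be < population_size")


@dataclass
class ExplanationResult:
    explanation: dict[str, str]
    gbf: float
    posterior_of_target: float
    generation_found: int = 0


def decode(
    chromosome: tuple[int, ...], candidates: list[str], net: BayesianNetwork
) -> dict[str, str]:
    """Chromosome -> partial assignment; unset genes are omitted."""
    out = {}
    for gene, name in zip(chromosome, candidates):
        if gene != UNSET:
            out[name] = net.variable(name).states[gene]
    return out


def fitness(
    net: BayesianNetwork,
    chromosome: tuple[int, ...],
    hypothesis: Assignment,
    candidates: list[str],
    lookup: JointLookup | None = None,
) -> float:
    """GBF of the decoded explanation for the hypothesis; total by design.

    The all-unset chromosome scores 1.0 (an empty explanation changes no
    odds); an ill-defined GBF scores 0.0 with a logged note.
    """
    x = decode(chromosome, candidates, net)
    if not x:
        return 1.0
    try:
        return gbf(net, x, hypothesis, lookup=lookup)
    except (IllDefinedComplementError, ImpossibleEvidenceError) as err:
        logger.info("ill-defined GBF for %r: %s", x, err)
        return 0.0


def _tie_key(result: ExplanationResult) -> tuple:
    items = tuple(sorted(result.explanation.items()))
    return (-result.gbf, len(items), items)


def _check_hypothesis(net: BayesianNetwork, hypothesis: Assignment) -> None:
    target = net.target
    if target is None or set(hypothesis) != {target}:
        raise ConfigurationError(
            "the hypothesis must bind exactly the network's target variable"
        )


def _result(
    net: BayesianNetwork,
    x: dict[str, str],
    score: float,
    hypothesis: Assignment,
    generation: int = 0,
) -> ExplanationResult:
    (target, t_state), = hypothesis.items()
    try:
        post = posterior(net, target, x)[t_state]
    except ImpossibleEvidenceError:
        post = float("nan")
    return ExplanationResult(x, score, post, generation)


def run_ga(
    net: BayesianNetwork,
    hypothesis: Assignment,
    candidates: list[str],
    config: GAConfig | None = None,
) -> list[ExplanationResult]:
    """Seeded GA search; returns the top-k unique explanations by GBF.

    Ties are broken by fewer bound variables, then lexicographically.
    The best fitness per generation is non-decreasing (elitism).
    """
    config = config or GAConfig()
    _check_hypothesis(net, hypothesis)
    if not candidates:
        raise ConfigurationError("empty candidate list")
    target = net.target
    for c in candidates:
        if c == target:
            raise ConfigurationError("candidates must exclude the target")
        net.variable(c)
    L = len(candidates)
    cards = [net.variable(c).cardinality for c in candidates]
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / L
    rng = np.random.default_rng(config.seed)
    lookup = JointLookup(net)
    cache: dict[tuple[int, ...], float] = {}
    first_seen: dict[tuple[int, ...], int] = {}

    def gene_choices(i: int) -> list[int]:
        opts = list(range(cards[i]))
        return ([UNSET] + opts) if config.allow_unset else opts

    def evaluate(chrom: tuple[int, ...], gen: int) -> float:
        if chrom not in cache:
            cache[chrom] = fitness(net, chrom, hypothesis, candidates, lookup)
            first_seen[chrom] = gen
        return cache[chrom]

    def random_chrom() -> tuple[int, ...]:
        return tuple(
            int(rng.choice(gene_choices(i))) for i in range(L)
        )

    population = [random_chrom() for _ in range(config.population_size)]
    scores = [evaluate(c, 0) for c in population]
    best_so_far = -math.inf
    for gen in range(1, config.generations + 1):
        order = sorted(range(len(population)), key=lambda i: -scores[i])
        gen_best = scores[order[0]]
        assert gen_best >= best_so_far or math.isclose(gen_best, best_so_far), \
            "elitism must make the best fitness non-decreasing"
        best_so_far = max(best_so_far, gen_best)
        elites = [population[i] for i in order[: config.elite_count]]
        children: list[tuple[int, ...]] = list(elites)
        while len(children) < config.population_size:
            pa = _tournament(rng, population, scores, config.tournament_size)
            pb = _tournament(rng, population, scores, config.tournament_size)
            if rng.random() < config.crossover_rate and L > 1:
                point = int(rng.integers(1, L))
                ca = pa[:point] + pb[point:]
                cb = pb[:point] + pa[point:]
            else:
                ca, cb = pa, pb
            for child in (ca, cb):
                child = tuple(
                    int(rng.choice(gene_choices(i))) if rng.random() < mut else g
                    for i, g in enumerate(child)
                )
                children.append(child)
                if len(children) >= config.population_size:
                    break
        population = children
        scores = [evaluate(c, gen) for c in population]

    # rank every distinct chromosome ever evaluated; posteriors are only
    # computed for the explanations actually returned
    ranked: dict[tuple, tuple[float, int, dict]] = {}
    for chrom, score in cache.items():
        x = decode(chrom, candidates, net)
        key = tuple(sorted(x.items()))
        if key not in ranked:
            ranked[key] = (score, first_seen[chrom], x)
    order = sorted(ranked, key=lambda k: (-ranked[k][0], len(k), k))
    return [
        _result(net, ranked[k][2], ranked[k][0], hypothesis, ranked[k][1])
        for k in order[: config.top_k]
    ]


def _tournament(rng, population, scores, k: int) -> tuple[int, ...]:
    idx = rng.integers(0, len(population), size=k)
    best = max(idx, key=lambda i: scores[i])
    return population[best]


def exhaustive_mre(
    net: BayesianNetwork,
    hypothesis: Assignment,
    candidates: list[str],
    allow_unset: bool = True,
    cap: int = 10**6,
) -> ExplanationResult:
    """Brute-force optimum over every explanation; the GA's oracle."""
    _check_hypothesis(net, hypothesis)
    if not candidates:
        raise ConfigurationError("empty candidate list")
    cards = [net.variable(c).cardinality for c in candidates]
    space = 1
    for c in cards:
        space *= c + (1 if allow_unset else 0)
    if space > cap:
        raise TooLargeError(f"{space} explanations exceed the cap {cap}")
    lookup = JointLookup(net)
    ranges = [
        ([UNSET] + list(range(c))) if allow_unset else list(range(c)) for c in cards
    ]
    best_key, best_x, best_score = None, None, None
    for combo in itertools.product(*ranges):
        score = fitness(net, combo, hypothesis, candidates, lookup)
        x = decode(combo, candidates, net)
        key = (-score, len(x), tuple(sorted(x.items())))
        if best_key is None or key < best_key:
            best_key, best_x, best_score = key, x, score
    return _result(net, best_x, best_score, hypothesis)


@dataclass
class WhatIfResult:
    posterior: float  # P(target = positive state | evidence)
    prior: float
    delta: float
    target_state: str


def whatif(
    net: BayesianNetwork,
    evidence: Assignment,
    target: str | None = None,
    target_state: str | None = None,
) -> WhatIfResult:
    """Posterior of the target's positive state under a hypothetical
    evidence profile, and its change from the unconditioned prior."""
    target = target or net.target
    if target is None:
        raise ConfigurationError("no target variable")
    if target in evidence:
        raise ValidationError("evidence must exclude the target")
    state = target_state or net.variable(target).states[-1]
    prior = posterior(net, target, {})[state]
    post = posterior(net, target, evidence)[state]  # raises if impossible
    return WhatIfResult(post, prior, post - prior, state)
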