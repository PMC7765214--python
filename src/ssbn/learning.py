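"""Supervised structure learning: Naive Bayes, TAN, and Sons-and-Spouses.

Parameter estimation is maximum a posteriori with a Dirichlet pseudo-count
(Laplace smoothing by default).  Rows incomplete for a family are dropped
from that family's counts only (available-case counting); records missing
more than ``max_missing_fraction`` of their columns are excluded up front.

The Sons-and-Spouses (SS) learner builds the local neighbourhood of a
target variable: its children ("sons"), which may be interlinked, and the
other parents of those children ("spouses"), which have no arc to or from
the target.  The concrete search is a reconstruction — candidate sons are
admitted by relative binary mutual information with the target, arcs are
added greedily by BIC improvement over the SS-legal arc set
{target->son, feature->son}, and variables left unconnected are pruned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .datatable import DataTable, exclude_incomplete
from .exceptions import ConfigurationError, EstimationError, ValidationError
from .metrics import conditional_mutual_information, mutual_information, relative_binary_mi
from .network import (
    BayesianNetwork,
    ConditionalProbabilityTable,
    NetworkStructure,
)

logger = logging.getLogger(__name__)


@dataclass
class LearnerConfig:
    """Hyperparameters shared by the structure learners.

    smoothing
        Dirichlet pseudo-count added to every CPT cell (1 = Laplace).
    max_parents
        Cap on the number of parents per node, bounding CPT size.
    mi_threshold
        Minimum relative binary mutual information with the target
        (percent) for a feature to be a candidate son in SS learning.
    max_missing_fraction
        Records missing more than this fraction of columns are excluded
        before learning.
    """

    smoothing: float = 1.0
    max_parents: int = 3
    score: str = "BIC"
    mi_threshold: float = 0.1
    max_missing_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothing < 0:
            raise ConfigurationError("smoothing must be >= 0")
        if self.max_parents < 1:
            raise ConfigurationError("max_parents must be >= 1")
        if self.score != "BIC":
            raise ConfigurationError(f"unsupported score {self.score!r}")


# ---------------------------------------------------------------------------
# parameter estimation


def _family_counts(
    data: DataTable,
    child: str,
    parents: tuple[str, ...],
    extra_complete: tuple[str, ...] = (),
) -> np.ndarray:
    """(n_parent_configs, child_card) counts over family-complete rows."""
    names = list(parents) + [child]
    mask = data.complete_mask(names + [v for v in extra_complete if v not in names])
    cards = [data.variable(n).cardinality for n in names]
    codes = data.code_matrix(names)[mask]
    flat = np.ravel_multi_index(tuple(codes.T), cards) if len(codes) else np.array([], int)
    counts = np.bincount(flat, minlength=int(np.prod(cards))).astype(float)
    return counts.reshape(-1, cards[-1])


def fit_parameters(
    structure: NetworkStructure, data: DataTable, smoothing: float = 1.0
) -> BayesianNetwork:
    """MAP CPT estimation: (count + smoothing) / (total + smoothing * card)."""
    missing_cols = set(structure.variables) - {v.name for v in data.variables}
    if missing_cols:
        raise ConfigurationError(f"data lacks columns for {sorted(missing_cols)}")
    cpts = {}
    for name, var in structure.variables.items():
        parents = structure.parents(name)
        counts = _family_counts(data, name, parents)
        totals = counts.sum(axis=1, keepdims=True)
        if smoothing == 0.0 and (totals == 0).any():
            raise EstimationError(
                f"family of {name!r} has parent configurations with no complete "
                f"data and smoothing is 0"
            )
        table = (counts + smoothing) / (totals + smoothing * var.cardinality)
        cpts[name] = ConditionalProbabilityTable(
            name,
            parents,
            table,
            [structure.variables[p].cardinality for p in parents],
            var.cardinality,
        )
    return BayesianNetwork(structure, cpts)


def cpt_standard_errors(net: BayesianNetwork, data: DataTable) -> dict[str, np.ndarray]:
    """Binomial standard errors of the fitted CPT entries, per family row."""
    out = {}
    for name, cpt in net.cpts.items():
        counts = _family_counts(data, name, cpt.parents)
        totals = counts.sum(axis=1, keepdims=True)
        p = cpt.table
        out[name] = np.sqrt(p * (1 - p) / np.maximum(totals + 1, 1))
    return out


# ---------------------------------------------------------------------------
# BIC scoring (natural log, standard penalty)


def family_bic(
    data: DataTable,
    child: str,
    parents: tuple[str, ...],
    scoring_vars: tuple[str, ...] = (),
) -> float:
    """BIC of one family.  ``scoring_vars`` extends the completeness
    requirement so that two families can be compared on identical rows —
    with available-case data, comparing log-likelihoods computed on
    different row subsets would bias the score toward smaller subsets."""
    counts = _family_counts(data, child, parents, extra_complete=scoring_vars)
    totals = counts.sum(axis=1, keepdims=True)
    n = counts.sum()
    if n == 0:
        return -math.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / totals), 0.0).sum()
    r = counts.shape[1]
    q = counts.shape[0]
    penalty = 0.5 * math.log(n) * q * (r - 1)
    return float(ll - penalty)


# ---------------------------------------------------------------------------
# learners


def _prepare(data: DataTable, target: str, config: LearnerConfig) -> DataTable:
    if target not in {v.name for v in data.variables}:
        raise ConfigurationError(f"target column {target!r} not in data")
    cleaned, report = exclude_incomplete(data, config.max_missing_fraction)
    if report.excluded:
        logger.info(
            "excluded %d of %d records with > %.0f%% missing columns",
            report.excluded, data.n_rows, 100 * config.max_missing_fraction,
        )
    return cleaned


def _with_target_role(data: DataTable, target: str) -> list:
    """Variables re-declared so that exactly `target` has the target role."""
    out = []
    for v in data.variables:
        role = "target" if v.name == target else "feature"
        out.append(replace(v, role=role))
    return out


def learn_naive_bayes(
    data: DataTable, target: str, config: LearnerConfig | None = None
) -> BayesianNetwork:
    """Every feature is a child of the target and nothing else."""
    config = config or LearnerConfig()
    data = _prepare(data, target, config)
    variables = _with_target_role(data, target)
    arcs = [(target, v.name) for v in variables if v.name != target]
    structure = NetworkStructure(variables, arcs)
    return fit_parameters(structure, data, config.smoothing)


def _maximum_spanning_tree(
    nodes: list[str], weights: dict[tuple[str, str], float]
) -> list[tuple[str, str]]:
    """Kruskal with deterministic lexicographic tie-breaking."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = sorted(weights, key=lambda e: (-weights[e], e))
    tree = []
    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v))
    return tree


def learn_tan(
    data: DataTable, target: str, config: LearnerConfig | None = None
) -> BayesianNetwork:
    """Tree-augmented Naive Bayes.

    Features are joined by the maximum-weight spanning tree under
    conditional mutual information given the target; edges are directed
    outward from the root (the feature with the highest MI with the
    target), and the target is added as a parent of every feature.
    """
    config = config or LearnerConfig()
    data = _prepare(data, target, config)
    variables = _with_target_role(data, target)
    features = sorted(v.name for v in variables if v.name != target)
    if len(features) < 2:
        raise ConfigurationError("TAN requires at least two features")
    weights = {}
    for i, u in enumerate(features):
        for v in features[i + 1:]:
            weights[(u, v)] = conditional_mutual_information(data, u, v, target)
    if all(w == 0.0 for w in weights.values()):
        logger.warning("all conditional MI weights are zero; falling back to NB")
        return learn_naive_bayes(data, target, config)
    tree = _maximum_spanning_tree(features, weights)
    target_mi = {f: mutual_information(data, f, target) for f in features}
    root = max(features, key=lambda f: (target_mi[f], [-ord(c) for c in f]))
    # direct tree edges outward from the root (BFS, lexicographic neighbours)
    adj: dict[str, set[str]] = {f: set() for f in features}
    for u, v in tree:
        adj[u].add(v)
        adj[v].add(u)
    arcs = [(target, f) for f in features]
    visited = {root}
    frontier = [root]
    while frontier:
        node = frontier.pop(0)
        for nb in sorted(adj[node]):
            if nb not in visited:
                arcs.append((node, nb))
                visited.add(nb)
                frontier.append(nb)
    structure = NetworkStructure(variables, arcs)
    return fit_parameters(structure, data, config.smoothing)


def learn_sons_and_spouses(
    data: DataTable, target: str, config: LearnerConfig | None = None
) -> BayesianNetwork:
    """Greedy BIC search over the SS-legal arc set, then pruning.

    1. Features whose relative binary MI with the target exceeds
       ``config.mi_threshold`` percent become candidate sons.
    2. Stage one adds ``target -> candidate`` arcs (largest positive BIC
       improvement first), fixing the set of sons; stage two greedily adds
       ``feature -> son`` arcs (other sons or spouses), subject to
       acyclicity and the ``max_parents`` cap.  Adding the class arc first
       keeps indirect correlations from crowding the target out of a son's
       parent set; arcs touching the target as a child are never considered.
    3. The returned network keeps the target, its children (sons) and the
       other parents of those children (spouses); everything unconnected
       is pruned — this is the feature-selection step.
    """
    config = config or LearnerConfig()
    data = _prepare(data, target, config)
    variables = _with_target_role(data, target)
    features = sorted(v.name for v in variables if v.name != target)
    candidates = [
        f for f in features
        if relative_binary_mi(data, f, target) > config.mi_threshold
    ]
    parents: dict[str, list[str]] = {f: [] for f in features}
    arcs: list[tuple[str, str]] = []
    score_cache: dict[tuple, float] = {}

    def fam_score(child: str, ps: tuple[str, ...],
                  scoring: tuple[str, ...]) -> float:
        key = (child, ps, tuple(sorted(scoring)))
        if key not in score_cache:
            score_cache[key] = family_bic(data, child, ps, scoring_vars=scoring)
        return score_cache[key]

    def arc_delta(child: str, current: tuple[str, ...], p: str) -> float:
        # both families scored on rows complete for child+current+p
        scoring = current + (p,)
        return (fam_score(child, current + (p,), scoring)
                - fam_score(child, current, scoring))

    def creates_cycle(p: str, c: str) -> bool:
        # does a directed path c -> ... -> p already exist?
        stack, seen = [c], set()
        while stack:
            node = stack.pop()
            if node == p:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(ch for par, ch in arcs if par == node)
        return False

    # stage 1: class arcs — which candidates are sons at all
    son_deltas = sorted(
        ((arc_delta(c, (), target), c) for c in candidates),
        key=lambda t: (-t[0], t[1]),
    )
    for delta, child in son_deltas:
        if delta > 0.0:
            arcs.append((target, child))
            parents[child].append(target)
    sons = {c for p, c in arcs if p == target}

    # stage 2: greedy augmenting arcs into sons
    while True:
        best_delta, best_arc = 0.0, None
        for child in sorted(sons):
            if len(parents[child]) >= config.max_parents:
                continue
            current = tuple(parents[child])
            for p in features:
                if p == child or p in parents[child] or creates_cycle(p, child):
                    continue
                delta = arc_delta(child, current, p)
                if delta > best_delta or (
                    delta == best_delta and best_arc is not None
                    and (p, child) < best_arc
                ):
                    best_delta, best_arc = delta, (p, child)
        if best_arc is None or best_delta <= 0.0:
            break
        arcs.append(best_arc)
        parents[best_arc[1]].append(best_arc[0])
    spouses = {p for p, c in arcs if c in sons and p != target} - sons
    keep = sons | spouses
    kept_arcs = [
        (p, c) for p, c in arcs
        if (p == target or p in keep) and c in keep
    ]
    kept_vars = [v for v in variables if v.name == target or v.name in keep]
    structure = NetworkStructure(kept_vars, kept_arcs)
    return fit_parameters(structure, data, config.smoothing)


def select_features(net: BayesianNetwork, target: str | None = None) -> set[str]:
    """children(target) union parents(children) minus the target itself."""
    target = target or net.target
    if target is None or target not in net.variables:
        raise ConfigurationError("network has no such target variable")
    sons = set(net.structure.children(target))
    spouses = set()
    for s in sons:
        spouses |= set(net.structure.parents(s))
    return (sons | spouses) - {target}
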