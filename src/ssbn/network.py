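"""Discrete Bayesian networks: variables, structure, CPTs, and core queries.

A :class:`BayesianNetwork` is a directed acyclic graph over categorical
variables together with one conditional probability table (CPT) per
variable.  The joint distribution factorises as the product of the CPT
entries, ``P(x_1..x_n) = prod_i P(x_i | pa_i)``, which is what
:func:`joint_probability` evaluates.  Posterior queries use variable
elimination (see :mod:`ssbn.inference`); ancestral forward sampling
provides seeded synthetic records.

Parent configurations in a CPT are enumerated in *odometer order* over the
declared parent order with the **last parent varying fastest** — the same
convention as ``numpy.ravel_multi_index`` — so serialised tables are
bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .exceptions import (
    DomainError,
    ImpossibleEvidenceError,
    IncompleteAssignmentError,
    ValidationError,
)

#: A (partial) assignment of variables to state labels.
Assignment = Mapping[str, str]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class DiscreteVariable:
    """A categorical variable with an ordered, finite state space."""

    name: str
    states: tuple[str, ...]
    role: str = "feature"

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ValidationError(f"variable {self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValidationError(f"variable {self.name!r} has duplicate states")
        if self.role not in ("target", "feature"):
            raise ValidationError(f"variable {self.name!r}: bad role {self.role!r}")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def index_of(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise DomainError(
                f"{state!r} is not a state of variable {self.name!r} "
                f"(states: {list(self.states)})"
            ) from None


class NetworkStructure:
    """A DAG over a fixed set of :class:`DiscreteVariable`.

    Variables keep their declaration order; each node's parent list keeps
    arc insertion order (this order is the CPT parent order).
    """

    def __init__(
        self,
        variables: Iterable[DiscreteVariable],
        arcs: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.variables: dict[str, DiscreteVariable] = {}
        for v in variables:
            if v.name in self.variables:
                raise ValidationError(f"duplicate variable {v.name!r}")
            self.variables[v.name] = v
        targets = [v.name for v in self.variables.values() if v.role == "target"]
        if len(targets) > 1:
            raise ValidationError(f"more than one target variable: {targets}")
        self._parents: dict[str, list[str]] = {n: [] for n in self.variables}
        self.arcs: list[tuple[str, str]] = []
        for parent, child in arcs:
            self.add_arc(parent, child)

    def add_arc(self, parent: str, child: str) -> None:
        for end in (parent, child):
            if end not in self.variables:
                raise DomainError(f"arc endpoint {end!r} is not a declared variable")
        if parent == child:
            raise ValidationError(f"self-arc on {parent!r}")
        if (parent, child) in self.arcs:
            raise ValidationError(f"duplicate arc {parent!r} -> {child!r}")
        self.arcs.append((parent, child))
        self._parents[child].append(parent)
        if not nx.is_directed_acyclic_graph(self.to_digraph()):
            raise ValidationError(f"arc {parent!r} -> {child!r} creates a cycle")

    def parents(self, name: str) -> tuple[str, ...]:
        return tuple(self._parents[name])

    def children(self, name: str) -> tuple[str, ...]:
        return tuple(c for p, c in self.arcs if p == name)

    @property
    def target(self) -> str | None:
        for v in self.variables.values():
            if v.role == "target":
                return v.name
        return None

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.arcs)
        return g

    def topological_order(self) -> list[str]:
        # deterministic: lexicographic among ready nodes
        return list(nx.lexicographical_topological_sort(self.to_digraph()))

    def copy(self) -> "NetworkStructure":
        return NetworkStructure(self.variables.values(), list(self.arcs))


class ConditionalProbabilityTable:
    """P(child | parents) as a (n_parent_configs, child_cardinality) array."""

    def __init__(
        self,
        child: str,
        parents: Sequence[str],
        table: np.ndarray | Sequence[Sequence[float]],
        parent_cards: Sequence[int],
        child_card: int,
    ) -> None:
        self.child = child
        self.parents = tuple(parents)
        self.parent_cards = tuple(int(c) for c in parent_cards)
        self.child_card = int(child_card)
        arr = np.asarray(table, dtype=float)
        n_cfg = int(np.prod(self.parent_cards)) if self.parents else 1
        if arr.shape != (n_cfg, self.child_card):
            raise ValidationError(
                f"CPT for {child!r}: expected shape ({n_cfg}, {self.child_card}), "
                f"got {arr.shape}"
            )
        if (arr < 0).any():
            raise ValidationError(f"CPT for {child!r} has negative entries")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=_PROB_TOL, rtol=0):
            raise ValidationError(f"CPT rows for {child!r} do not sum to 1")
        self.table = arr

    def row_index(self, parent_state_indices: Sequence[int]) -> int:
        if not self.parents:
            return 0
        return int(
            np.ravel_multi_index(tuple(parent_state_indices), self.parent_cards)
        )


class BayesianNetwork:
    """A structure plus one CPT per variable."""

    def __init__(
        self,
        structure: NetworkStructure,
        cpts: Mapping[str, ConditionalProbabilityTable],
    ) -> None:
        self.structure = structure
        self.cpts = dict(cpts)
        missing = set(structure.variables) - set(self.cpts)
        extra = set(self.cpts) - set(structure.variables)
        if missing or extra:
            raise ValidationError(f"CPT mismatch: missing {missing}, extra {extra}")
        for name, cpt in self.cpts.items():
            if cpt.parents != structure.parents(name):
                raise ValidationError(
                    f"CPT parents for {name!r} ({cpt.parents}) disagree with the "
                    f"structure ({structure.parents(name)})"
                )

    @property
    def variables(self) -> dict[str, DiscreteVariable]:
        return self.structure.variables

    @property
    def target(self) -> str | None:
        return self.structure.target

    def variable(self, name: str) -> DiscreteVariable:
        try:
            return self.structure.variables[name]
        except KeyError:
            raise DomainError(f"unknown variable {name!r}") from None


@dataclass
class Distribution:
    """A probability distribution over one variable's states."""

    variable: str
    states: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if (p < -_PROB_TOL).any() or abs(p.sum() - 1.0) > _PROB_TOL:
            raise ValidationError(
                f"distribution over {self.variable!r} is not normalised"
            )
        self.probabilities = np.clip(p, 0.0, None)

    def __getitem__(self, state: str) -> float:
        try:
            return float(self.probabilities[self.states.index(state)])
        except ValueError:
            raise DomainError(
                f"{state!r} is not a state of {self.variable!r}"
            ) from None

    def argmax(self) -> str:
        return self.states[int(np.argmax(self.probabilities))]

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.probabilities)}


# ---------------------------------------------------------------------------
# construction helpers


def tabular_cpt(
    structure: NetworkStructure, child: str, table
) -> ConditionalProbabilityTable:
    """Build a CPT for ``child`` consistent with ``structure``."""
    parents = structure.parents(child)
    cards = [structure.variables[p].cardinality for p in parents]
    return ConditionalProbabilityTable(
        child, parents, table, cards, structure.variables[child].cardinality
    )


def _check_assignment(net: BayesianNetwork, a: Assignment) -> dict[str, int]:
    """Validate names/states; return state indices."""
    out = {}
    for name, state in a.items():
        out[name] = net.variable(name).index_of(state)
    return out


# ---------------------------------------------------------------------------
# core queries


def joint_probability(net: BayesianNetwork, a: Assignment) -> float:
    """Probability of a *full* assignment: the product of CPT entries."""
    idx = _check_assignment(net, a)
    unbound = set(net.variables) - set(idx)
    if unbound:
        raise IncompleteAssignmentError(
            f"assignment leaves variables unbound: {sorted(unbound)}"
        )
    p = 1.0
    for name, cpt in net.cpts.items():
        row = cpt.row_index([idx[par] for par in cpt.parents])
        p *= cpt.table[row, idx[name]]
    return float(p)


def marginal_likelihood(net: BayesianNetwork, e: Assignment) -> float:
    """P(e): the joint probability summed over all completions of ``e``."""
    _check_assignment(net, e)
    from .inference import eliminate_all

    return eliminate_all(net, e)


def posterior(net: BayesianNetwork, query: str, e: Assignment) -> Distribution:
    """P(query | e) by variable elimination.

    Raises :class:`ImpossibleEvidenceError` when P(e) = 0 — callers such as
    the GA fitness function must handle impossible evidence explicitly.
    """
    var = net.variable(query)
    if query in e:
        raise ValidationError(f"query variable {query!r} is bound in the evidence")
    _check_assignment(net, e)
    from .inference import variable_elimination

    unnorm = variable_elimination(net, query, e)
    total = unnorm.sum()
    if total <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {dict(e)!r} has probability zero under the network"
        )
    return Distribution(query, var.states, unnorm / total)


def forward_sample(net: BayesianNetwork, n: int, seed: int):
    """Draw ``n`` complete records ancestrally; identical seed, identical table."""
    from .datatable import DataTable

    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = net.structure.topological_order()
    codes: dict[str, np.ndarray] = {}
    for name in order:
        cpt = net.cpts[name]
        if cpt.parents:
            rows_idx = np.ravel_multi_index(
                tuple(codes[p] for p in cpt.parents), cpt.parent_cards
            )
            rows = cpt.table[rows_idx]
        else:
            rows = np.broadcast_to(cpt.table[0], (n, cpt.child_card))
        u = rng.random(n)
        cum = np.cumsum(rows, axis=1)
        drawn = (u[:, None] > cum).sum(axis=1)
        codes[name] = np.minimum(drawn, cpt.child_card - 1).astype(np.int64)
    # emit columns in declared variable order
    cols = {name: codes[name] for name in net.variables}
    return DataTable.from_codes(list(net.variables.values()), cols)
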