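"""Exact inference by variable elimination, plus a brute-force enumerator.

Variable elimination with a min-degree ordering is the production path; the
networks targeted here are small (tens of nodes), so exactness is cheap.
:func:`enumerate_joint` builds the full joint table by explicit iteration
over all configurations and is deliberately kept independent of the factor
machinery so it can serve as an oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .exceptions import TooLargeError
from .network import Assignment, BayesianNetwork


@dataclass
class Factor:
    """A non-negative table over a tuple of variables (one axis each)."""

    vars: tuple[str, ...]
    values: np.ndarray

    def marginalize(self, var: str) -> "Factor":
        axis = self.vars.index(var)
        return Factor(
            self.vars[:axis] + self.vars[axis + 1 :], self.values.sum(axis=axis)
        )

    def reduce(self, evidence_idx: Mapping[str, int]) -> "Factor":
        keep_vars = []
        index: list = []
        for v in self.vars:
            if v in evidence_idx:
                index.append(evidence_idx[v])
            else:
                index.append(slice(None))
                keep_vars.append(v)
        return Factor(tuple(keep_vars), self.values[tuple(index)])


def factor_product(a: Factor, b: Factor) -> Factor:
    out_vars = a.vars + tuple(v for v in b.vars if v not in a.vars)
    av = a.values.reshape(a.values.shape + (1,) * (len(out_vars) - len(a.vars)))
    # move b's axes into position
    perm = [b.vars.index(v) for v in out_vars if v in b.vars]
    bt = np.transpose(b.values, perm)
    shape = tuple(
        bt.shape[[v for v in out_vars if v in b.vars].index(v)] if v in b.vars else 1
        for v in out_vars
    )
    return Factor(out_vars, av * bt.reshape(shape))


def _cpt_factor(net: BayesianNetwork, name: str) -> Factor:
    cpt = net.cpts[name]
    shape = cpt.parent_cards + (cpt.child_card,)
    return Factor(cpt.parents + (name,), cpt.table.reshape(shape))


def _reduced_factors(net: BayesianNetwork, evidence: Assignment) -> list[Factor]:
    idx = {k: net.variable(k).index_of(v) for k, v in evidence.items()}
    return [_cpt_factor(net, name).reduce(idx) for name in net.variables]


def _min_degree_order(factors: list[Factor], eliminate: set[str]) -> list[str]:
    # interaction graph over variables still to eliminate
    neighbors: dict[str, set[str]] = {v: set() for v in eliminate}
    scopes = [set(f.vars) for f in factors]
    order = []
    remaining = set(eliminate)
    while remaining:
        for scope in scopes:
            for v in scope & remaining:
                neighbors[v] |= (scope - {v}) & remaining
        # smallest neighborhood first; ties lexicographic
        v = min(remaining, key=lambda x: (len(neighbors[x] & remaining), x))
        order.append(v)
        merged = set()
        new_scopes = []
        for scope in scopes:
            if v in scope:
                merged |= scope - {v}
            else:
                new_scopes.append(scope)
        new_scopes.append(merged)
        scopes = new_scopes
        remaining.discard(v)
        for n in neighbors:
            neighbors[n] = set()
    return order


def _eliminate(factors: list[Factor], order: list[str]) -> list[Factor]:
    factors = list(factors)
    for v in order:
        bucket = [f for f in factors if v in f.vars]
        factors = [f for f in factors if v not in f.vars]
        if not bucket:
            continue
        prod = bucket[0]
        for f in bucket[1:]:
            prod = factor_product(prod, f)
        factors.append(prod.marginalize(v))
    return factors


def variable_elimination(
    net: BayesianNetwork, query: str, evidence: Assignment
) -> np.ndarray:
    """Unnormalised P(query, evidence) over the query's states."""
    factors = _reduced_factors(net, evidence)
    hidden = set(net.variables) - set(evidence) - {query}
    factors = _eliminate(factors, _min_degree_order(factors, hidden))
    result = Factor((), np.array(1.0))
    for f in factors:
        result = factor_product(result, f)
    if result.vars != (query,):
        result = Factor(
            (query,), np.transpose(result.values, [result.vars.index(query)])
        )
    return np.asarray(result.values, dtype=float)


def eliminate_all(net: BayesianNetwork, evidence: Assignment) -> float:
    """P(evidence): eliminate every unobserved variable."""
    factors = _reduced_factors(net, evidence)
    hidden = set(net.variables) - set(evidence)
    factors = _eliminate(factors, _min_degree_order(factors, hidden))
    p = 1.0
    for f in factors:
        p *= float(np.asarray(f.values).sum()) if f.vars else float(f.values)
    return p


# ---------------------------------------------------------------------------
# enumeration fallback (oracle path)


def enumerate_joint(
    net: BayesianNetwork, cap: int = 10**6
) -> tuple[list[str], np.ndarray]:
    """Full joint table by explicit enumeration of every configuration.

    Returns the variable order (declaration order) and an array with one
    axis per variable.  Independent of the factor code above by design.
    """
    names = list(net.variables)
    cards = [net.variables[n].cardinality for n in names]
    size = int(np.prod(cards))
    if size > cap:
        raise TooLargeError(f"joint table has {size} cells (cap {cap})")
    table = np.empty(cards, dtype=float)
    for combo in itertools.product(*(range(c) for c in cards)):
        idx = dict(zip(names, combo))
        p = 1.0
        for name in names:
            cpt = net.cpts[name]
            row = cpt.row_index([idx[par] for par in cpt.parents])
            p *= cpt.table[row, idx[name]]
        table[combo] = p
    return names, table


def posterior_by_enumeration(
    net: BayesianNetwork, query: str, evidence: Assignment
) -> np.ndarray:
    """Normalised P(query | evidence) from the full joint table."""
    names, table = enumerate_joint(net)
    idx: list = [slice(None)] * len(names)
    for k, v in evidence.items():
        idx[names.index(k)] = net.variable(k).index_of(v)
    sub = table[tuple(idx)]
    keep = [n for n in names if n not in evidence]
    axes = tuple(i for i, n in enumerate(keep) if n != query)
    unnorm = sub.sum(axis=axes) if axes else sub
    return unnorm / unnorm.sum()


class JointLookup:
    """Cached full-joint table supporting fast marginal queries.

    Used by the explanation search, where the same network is queried tens
    of thousands of times.  Falls back to variable elimination when the
    state space exceeds ``cap``.
    """

    def __init__(self, net: BayesianNetwork, cap: int = 2**22) -> None:
        self.net = net
        self._names: list[str] | None = None
        self._table: np.ndarray | None = None
        size = int(np.prod([v.cardinality for v in net.variables.values()]))
        if size <= cap:
            names = list(net.variables)
            factors = [_cpt_factor(net, n) for n in net.variables]
            prod = factors[0]
            for f in factors[1:]:
                prod = factor_product(prod, f)
            perm = [prod.vars.index(n) for n in names]
            self._names = names
            self._table = np.transpose(prod.values, perm)
            self._axis = {n: i for i, n in enumerate(names)}
            self._state_idx = {
                n: {s: i for i, s in enumerate(net.variables[n].states)}
                for n in names
            }

    def prob(self, assignment: Assignment) -> float:
        if self._table is None:
            return eliminate_all(self.net, assignment)
        idx: list = [slice(None)] * len(self._names)
        for k, v in assignment.items():
            idx[self._axis[k]] = self._state_idx[k][v]
        return float(self._table[tuple(idx)].sum())
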