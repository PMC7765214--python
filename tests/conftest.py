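"""Shared fixtures: hand-built toy networks and an independent enumerator.

``brute_joint`` deliberately re-derives the joint distribution with plain
Python loops and direct CPT-cell lookups so it can serve as an oracle for
the factor-based inference code.
"""

import itertools

import numpy as np
import pytest

from ssbn.network import (
    BayesianNetwork,
    DiscreteVariable,
    NetworkStructure,
    tabular_cpt,
)


@pytest.fixture
def toy_net():
    """T -> E with P(T=1)=0.1, P(E=1|T=1)=0.8, P(E=1|T=0)=0.2."""
    t = DiscreteVariable("T", ("0", "1"), role="target")
    e = DiscreteVariable("E", ("0", "1"))
    s = NetworkStructure([t, e], [("T", "E")])
    return BayesianNetwork(
        s,
        {
            "T": tabular_cpt(s, "T", [[0.9, 0.1]]),
            "E": tabular_cpt(s, "E", [[0.8, 0.2], [0.2, 0.8]]),
        },
    )


def brute_joint(net):
    """{full assignment (tuple of states): probability} by explicit loops."""
    names = list(net.variables)
    state_lists = [net.variables[n].states for n in names]
    out = {}
    for combo in itertools.product(*state_lists):
        assignment = dict(zip(names, combo))
        p = 1.0
        for name in names:
            cpt = net.cpts[name]
            var = net.variables[name]
            row = 0
            if cpt.parents:
                idx = [
                    net.variables[par].states.index(assignment[par])
                    for par in cpt.parents
                ]
                stride = 1
                row = 0
                for parent, i in zip(reversed(cpt.parents), reversed(idx)):
                    row += i * stride
                    stride *= net.variables[parent].cardinality
            p *= cpt.table[row, var.states.index(assignment[name])]
        out[combo] = p
    return names, out


def brute_marginal(net, evidence):
    """P(evidence) summed from the brute-force joint."""
    names, joint = brute_joint(net)
    total = 0.0
    for combo, p in joint.items():
        if all(combo[names.index(k)] == v for k, v in evidence.items()):
            total += p
    return total
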