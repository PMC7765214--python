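"""Information-theoretic strength measures and generalized Bayes factors.

All information quantities use base-2 logarithms and are reported in bits.

The generalized Bayes factor (GBF) of an explanation ``x`` for evidence
``e`` is ``P(e | x) / P(e | x-bar)``, where the complement ``x-bar`` is
"anything but x" and its likelihood is obtained by total probability,

    P(e | x-bar) = (P(e) - P(e, x)) / (1 - P(x)),

never by enumerating the complement configurations.  GBF > 1 means the
explanation makes the evidence more likely; an infinite ratio is reported
as ``math.inf`` (a documented sentinel, not an exception).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatable import DataTable
from .exceptions import (
    DomainError,
    IllDefinedComplementError,
    TooLargeError,
    UndefinedMeasureError,
    ValidationError,
)
from .inference import JointLookup, enumerate_joint
from .network import (
    Assignment,
    BayesianNetwork,
    Distribution,
    marginal_likelihood,
    posterior,
)

logger = logging.getLogger(__name__)

_EPS_P = 1e-15  # tolerance when deciding whether a probability is 0 or 1


@dataclass
class ArcForceReport:
    arc: tuple[str, str]
    force: float  # bits; KL(net joint || arc-deleted refit joint)


# ---------------------------------------------------------------------------
# divergences and mutual information


def kl_divergence(p: Distribution, q: Distribution) -> float:
    """KL(p || q) in bits; returns ``inf`` when p has mass where q has none."""
    if p.variable != q.variable or p.states != q.states:
        raise ValidationError("distributions are over different variables/states")
    return _kl_arrays(p.probabilities, q.probabilities)


def _kl_arrays(p: np.ndarray, q: np.ndarray) -> float:
    p = np.asarray(p, float).ravel()
    q = np.asarray(q, float).ravel()
    mask = p > 0
    if np.any(q[mask] == 0):
        return math.inf
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def _empirical_joint(data: DataTable, names: Sequence[str]) -> np.ndarray:
    mask = data.complete_mask(names)
    cards = [data.variable(n).cardinality for n in names]
    codes = data.code_matrix(names)[mask]
    if codes.shape[0] == 0:
        raise UndefinedMeasureError(f"no complete rows for {list(names)}")
    flat = np.ravel_multi_index(tuple(codes.T), cards)
    counts = np.bincount(flat, minlength=int(np.prod(cards))).astype(float)
    return (counts / counts.sum()).reshape(cards)


def _mi_from_joint(joint: np.ndarray) -> float:
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    return _kl_arrays(joint, px * py)


def mutual_information(data: DataTable, x: str, y: str) -> float:
    """Empirical MI(x; y) in bits, on rows complete for both columns."""
    joint = _empirical_joint(data, [x, y])
    if (joint.sum(axis=1) > 0).sum() < 2 or (joint.sum(axis=0) > 0).sum() < 2:
        logger.warning("mutual_information: constant column among (%s, %s)", x, y)
        return 0.0
    return _mi_from_joint(joint)


def conditional_mutual_information(data: DataTable, x: str, y: str, z: str) -> float:
    """MI(x; y | z) = sum_z P(z) MI(x; y | Z=z), on rows complete for all three."""
    joint = _empirical_joint(data, [x, y, z])
    cmi = 0.0
    for k in range(joint.shape[2]):
        pz = joint[:, :, k].sum()
        if pz == 0:
            continue
        cmi += pz * _mi_from_joint(joint[:, :, k] / pz)
    return cmi


def entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def relative_binary_mi(data: DataTable, x: str, target: str) -> float:
    """100 * MI(x; target) / H(target); the per-variable column of the
    strength report for a binary target."""
    tvar = data.variable(target)
    if tvar.cardinality != 2:
        raise ValidationError(f"target {target!r} must be binary")
    joint = _empirical_joint(data, [x, target])
    h = entropy_bits(joint.sum(axis=0))
    if h == 0.0:
        raise UndefinedMeasureError(f"target {target!r} has zero entropy")
    return 100.0 * _mi_from_joint(joint) / h


# ---------------------------------------------------------------------------
# arc force


def arc_force(
    net: BayesianNetwork,
    data: DataTable,
    arc: tuple[str, str],
    smoothing: float = 0.0,
    cap: int = 10**6,
) -> ArcForceReport:
    """Strength of a direct relationship: KL divergence in bits between the
    network's joint and the joint of the arc-deleted structure refit on
    ``data``, computed by exact enumeration."""
    if tuple(arc) not in [tuple(a) for a in net.structure.arcs]:
        raise DomainError(f"arc {arc!r} is not in the network")
    from .learning import fit_parameters

    size = int(np.prod([v.cardinality for v in net.variables.values()]))
    if size > cap:
        raise TooLargeError(f"joint enumeration needs {size} cells (cap {cap})")
    reduced = net.structure.copy()
    reduced.arcs.remove(tuple(arc))
    reduced._parents[arc[1]].remove(arc[0])
    refit = fit_parameters(reduced, data, smoothing=smoothing)
    _, p = enumerate_joint(net, cap=cap)
    _, q = enumerate_joint(refit, cap=cap)
    return ArcForceReport(arc=tuple(arc), force=_kl_arrays(p, q))


def arc_force_report(
    net: BayesianNetwork, data: DataTable, smoothing: float = 0.0
) -> pd.DataFrame:
    rows = [
        {"parent": a[0], "child": a[1],
         "force_bits": arc_force(net, data, a, smoothing=smoothing).force}
        for a in net.structure.arcs
    ]
    return pd.DataFrame(rows, columns=["parent", "child", "force_bits"])


# ---------------------------------------------------------------------------
# Bayes factors


def state_bayes_factor(
    net: BayesianNetwork, x: str, s: str, t: str
) -> float:
    """P(x=s | target=t) / P(x=s | target=t-bar) for a binary target."""
    target = net.target
    if target is None:
        raise ValidationError("network has no target variable")
    tvar = net.variable(target)
    if tvar.cardinality != 2:
        raise ValidationError("state Bayes factors require a binary target")
    t_idx = tvar.index_of(t)
    t_bar = tvar.states[1 - t_idx]
    num = posterior(net, x, {target: t})[s]
    den = posterior(net, x, {target: t_bar})[s]
    if den == 0.0:
        return math.inf if num > 0 else 1.0
    return num / den


def _prob_fn(net: BayesianNetwork, lookup: JointLookup | None):
    if lookup is not None:
        return lookup.prob
    return lambda a: marginal_likelihood(net, a)


def gbf(
    net: BayesianNetwork,
    x: Assignment,
    e: Assignment,
    lookup: JointLookup | None = None,
) -> float:
    """Generalized Bayes factor GBF(x; e) = P(e|x) / P(e|x-bar)."""
    if set(x) & set(e):
        raise ValidationError("explanation and evidence must bind disjoint variables")
    prob = _prob_fn(net, lookup)
    px = prob(x)
    if px <= _EPS_P or px >= 1.0 - _EPS_P:
        raise IllDefinedComplementError(
            f"P(x) = {px:.3g}; the complement of the explanation is ill-defined"
        )
    pe = prob(e)
    if pe <= 0.0:
        from .exceptions import ImpossibleEvidenceError

        raise ImpossibleEvidenceError("evidence has probability zero")
    pex = prob({**x, **e})
    e_given_x = pex / px
    e_given_not_x = max(pe - pex, 0.0) / (1.0 - px)
    if e_given_not_x == 0.0:
        return math.inf if e_given_x > 0 else 1.0
    return e_given_x / e_given_not_x


def gbf_conditional(
    net: BayesianNetwork,
    y: Assignment,
    e: Assignment,
    x: Assignment,
    lookup: JointLookup | None = None,
) -> float:
    """GBF(y; e | x) = P(e | y, x) / P(e | y-bar, x); complement over y only."""
    sets = [set(y), set(e), set(x)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ValidationError("y, e, x must bind pairwise disjoint variables")
    if not x:
        return gbf(net, y, e, lookup=lookup)
    prob = _prob_fn(net, lookup)
    pyx = prob({**y, **x})
    px = prob(x)
    if pyx <= _EPS_P or px - pyx <= _EPS_P:
        raise IllDefinedComplementError(
            "P(y | x) is 0 or 1; the conditional complement is ill-defined"
        )
    peyx = prob({**y, **x, **e})
    pex = prob({**x, **e})
    num = peyx / pyx
    den = max(pex - peyx, 0.0) / (px - pyx)
    if den == 0.0:
        return math.inf if num > 0 else 1.0
    return num / den


def gbf_chain(
    net: BayesianNetwork,
    x: Assignment,
    evidence_sequence: Sequence[Assignment],
    lookup: JointLookup | None = None,
) -> float:
    """Chain-rule decomposition: GBF(x; e1) * prod_i GBF(x; e_i | e_<i).

    Algebraically identical to ``gbf(net, x, union of evidence)`` for every
    ordering of the pieces.
    """
    seen: set[str] = set(x)
    for piece in evidence_sequence:
        if set(piece) & seen:
            raise ValidationError("evidence pieces must be pairwise disjoint and "
                                  "disjoint from the explanation")
        seen |= set(piece)
    prob = _prob_fn(net, lookup)
    px = prob(x)
    if px <= _EPS_P or px >= 1.0 - _EPS_P:
        raise IllDefinedComplementError(f"P(x) = {px:.3g}")
    result = 1.0
    prev: dict[str, str] = {}
    for piece in evidence_sequence:
        cur = {**prev, **piece}
        p_cur_x = prob({**x, **cur})
        p_prev_x = prob({**x, **prev}) if prev else px
        p_cur = prob(cur)
        p_prev = prob(prev) if prev else 1.0
        num = p_cur_x / p_prev_x
        den_num = max(p_cur - p_cur_x, 0.0)
        den_den = max(p_prev - p_prev_x, 0.0)
        if den_den == 0.0:
            raise IllDefinedComplementError("conditioning evidence impossible under x-bar")
        den = den_num / den_den
        if den == 0.0:
            return math.inf if num > 0 else 1.0
        result *= num / den
        prev = cur
    return result


# ---------------------------------------------------------------------------
# target strength report


def target_report(
    net: BayesianNetwork, data: DataTable, target: str | None = None
) -> pd.DataFrame:
    """Per-variable strength summary against a binary target.

    Columns: relative binary mutual information (percent), posterior mean
    of zero-based numeric state codes under the node's marginal, and the
    max/min single-state Bayes factors for each target state with the
    states attaining them.  Both target directions are reported explicitly.
    """
    target = target or net.target
    if target is None:
        raise ValidationError("no target variable")
    tvar = net.variable(target)
    rows = []
    for name, var in net.variables.items():
        if name == target:
            continue
        marg = posterior(net, name, {})
        post_mean = float(np.dot(np.arange(var.cardinality), marg.probabilities))
        row = {
            "node": name,
            "relative_binary_mi_pct": relative_binary_mi(data, name, target),
            "posterior_mean_value": post_mean,
        }
        for t in tvar.states:
            bfs = {s: state_bayes_factor(net, name, s, t) for s in var.states}
            hi = max(bfs, key=bfs.get)
            lo = min(bfs, key=bfs.get)
            row[f"max_bf_{t}"] = bfs[hi]
            row[f"max_bf_{t}_state"] = hi
            row[f"min_bf_{t}"] = bfs[lo]
            row[f"min_bf_{t}_state"] = lo
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        "relative_binary_mi_pct", ascending=False, ignore_index=True
    )
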