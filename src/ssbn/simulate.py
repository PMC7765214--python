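"""Synthetic survey cohorts with a known generating network.

The generator emulates the shape of a national health-survey extract used
for depression modelling: one rare binary target (prevalence 5.5%), a ring
of categorical risk factors that are direct children of the target
("sons", cardinalities 2-5, conditional row contrast >= 0.3), confounders
that parent those children but carry no arc to the target ("spouses"),
isolated distractor variables, and missing entries that exercise the
record-exclusion filter.  Because the generating network is known exactly,
every learner and search routine in the package can be tested against
ground truth without any external download.

The binary target is itself the collapse of a three-level
none/some/extreme item (the anxiety/depression dimension of a
quality-of-life instrument): cohorts carry the raw three-level column so
the merge step is testable too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatable import DataTable, ExclusionReport, exclude_incomplete  # noqa: F401
from .exceptions import SpecificationError, ValidationError
from .inference import JointLookup
from .network import (
    BayesianNetwork,
    ConditionalProbabilityTable,
    DiscreteVariable,
    NetworkStructure,
    forward_sample,
)

TARGET_NAME = "depression"
EQ5D_NAME = "eq5d_level"
EQ5D_STATES = ("none", "some", "extreme")

# Legible variable vocabulary for the default cohort (semantics synthetic).
_SON_NAMES = [
    ("subjective_health", ("very_good", "good", "not_bad", "bad", "very_bad")),
    ("income_quartile", ("low", "mid_low", "mid_high", "high")),
    ("marital_status", ("married_together", "married_separated", "divorced",
                        "widowed", "unmarried")),
    ("economic_status", ("yes", "no")),
    ("arthritis", ("no", "yes")),
    ("gender", ("male", "female")),
    ("diabetes", ("no", "yes")),
]
_SPOUSE_NAMES = [
    ("age", ("30s", "40s", "50s")),
    ("hypertension", ("no", "yes")),
    ("glycated_hemoglobin", ("le6", "le7", "le8", "gt8")),
    ("hemoglobin", ("le10", "le12", "le14", "le16", "gt16")),
    ("oral_examination", ("no", "yes")),
    ("smoking", ("non_smoker", "under_5_packs", "over_5_packs")),
]


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort."""

    prevalence: float = 0.055
    n_sons: int = 7
    n_spouses: int = 6
    n_noise: int = 6
    min_card: int = 2
    max_card: int = 5
    effect_size: float = 0.3  # minimum per-row CPT contrast for sons
    missing_rate: float = 0.01
    high_missing_fraction: float = 0.15  # share of poor-responder records
    high_missing_rate: float = 0.5
    extreme_fraction: float = 0.2  # share of the depressed drawn 'extreme'
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise SpecificationError("prevalence must lie in (0, 1)")
        if self.effect_size < 0:
            raise SpecificationError("effect_size must be >= 0")
        if min(self.n_sons, self.n_spouses, self.n_noise) < 0:
            raise SpecificationError("variable counts must be >= 0")
        if not 2 <= self.min_card <= self.max_card:
            raise SpecificationError("need 2 <= min_card <= max_card")
        if self.effect_size > 0.6:
            raise SpecificationError(
                "effect_size > 0.6 leaves no room for a valid baseline row"
            )


@dataclass
class GroundTruth:
    """A generating network with its role bookkeeping."""

    network: BayesianNetwork
    sons: list[str]
    spouses: list[str]
    noise: list[str]
    high_risk_profile: dict[str, str]
    spec: CohortSpec


def _dirichlet_row(rng: np.random.Generator, card: int, floor: float = 0.05,
                   concentration: float = 1.0) -> np.ndarray:
    row = rng.dirichlet(np.full(card, concentration))
    row = np.clip(row, floor, None)
    return row / row.sum()


def build_ground_truth(spec: CohortSpec) -> GroundTruth:
    """Construct the generating network for a cohort specification.

    Sons receive a designated risk state whose conditional probability is
    exactly ``effect_size`` higher when the target is positive, for every
    spouse configuration.  The stored high-risk profile is the
    single-state-per-son assignment with the maximal target posterior,
    found by exact enumeration over the (target, sons) marginal.
    """
    rng = np.random.default_rng(spec.seed)

    def pick_named(pool, k, prefix):
        out = []
        for i in range(k):
            if i < len(pool):
                name, states = pool[i]
                states = states[: spec.max_card]
                if len(states) < spec.min_card:
                    states = tuple(f"{name}_{j}" for j in range(spec.min_card))
            else:
                card = int(rng.integers(spec.min_card, spec.max_card + 1))
                name = f"{prefix}_{i + 1:02d}"
                states = tuple(f"cat{j + 1}" for j in range(card))
            out.append(DiscreteVariable(name, tuple(states)))
        return out

    sons = pick_named(_SON_NAMES, spec.n_sons, "son")
    spouses = pick_named(_SPOUSE_NAMES, spec.n_spouses, "spouse")
    noise = pick_named([], spec.n_noise, "noise")
    target = DiscreteVariable(TARGET_NAME, ("no", "yes"), role="target")

    variables = [target] + sons + spouses + noise
    arcs = [(TARGET_NAME, s.name) for s in sons]
    spouse_of: dict[str, list[str]] = {s.name: [] for s in sons}
    for i, sp in enumerate(spouses):
        son = sons[i % len(sons)].name if sons else None
        if son is not None:
            arcs.append((sp.name, son))
            spouse_of[son].append(sp.name)
    structure = NetworkStructure(variables, arcs)

    cpts: dict[str, ConditionalProbabilityTable] = {}
    cpts[TARGET_NAME] = ConditionalProbabilityTable(
        TARGET_NAME, (), [[1.0 - spec.prevalence, spec.prevalence]], (), 2
    )
    # survey strata (age bands, quartiles, ...) are roughly balanced
    for sp in spouses:
        cpts[sp.name] = ConditionalProbabilityTable(
            sp.name, (),
            [_dirichlet_row(rng, sp.cardinality, floor=0.1, concentration=8.0)],
            (), sp.cardinality,
        )
    for nv in noise:
        cpts[nv.name] = ConditionalProbabilityTable(
            nv.name, (),
            [_dirichlet_row(rng, nv.cardinality, floor=0.1, concentration=8.0)],
            (), nv.cardinality,
        )
    for son in sons:
        parents = structure.parents(son.name)  # (target, spouses...)
        parent_cards = tuple(structure.variables[p].cardinality for p in parents)
        n_cfg = int(np.prod(parent_cards))
        card = son.cardinality
        risk_state = int(rng.integers(0, card))
        table = np.empty((n_cfg, card))
        baselines: dict[tuple, np.ndarray] = {}
        for cfg in range(n_cfg):
            cfg_idx = np.unravel_index(cfg, parent_cards)
            t_idx = cfg_idx[0]  # target is the first declared parent
            key = cfg_idx[1:]
            # one baseline row per spouse configuration, shared across t,
            # with headroom so the shifted positive-target row stays valid
            if key not in baselines:
                baselines[key] = _baseline_row(rng, card, risk_state,
                                               spec.effect_size)
            base = baselines[key]
            row = base.copy()
            if t_idx == 1:
                shift = spec.effect_size
                row[risk_state] += shift
                others = np.arange(card) != risk_state
                row[others] -= shift * base[others] / base[others].sum()
                row = np.clip(row, 1e-9, None)
                row /= row.sum()
            table[cfg] = row
        cpts[son.name] = ConditionalProbabilityTable(
            son.name, parents, table, parent_cards, card
        )

    net = BayesianNetwork(structure, cpts)
    profile = _high_risk_profile(net, [s.name for s in sons])
    return GroundTruth(
        network=net,
        sons=[s.name for s in sons],
        spouses=[sp.name for sp in spouses],
        noise=[nv.name for nv in noise],
        high_risk_profile=profile,
        spec=spec,
    )


def _baseline_row(rng, card, risk_state, effect) -> np.ndarray:
    row = _dirichlet_row(rng, card)
    max_base = 1.0 - effect - 0.05
    if row[risk_state] > max_base:
        excess = row[risk_state] - max_base
        row[risk_state] = max_base
        others = np.arange(card) != risk_state
        row[others] += excess / (card - 1)
    return row / row.sum()


def _high_risk_profile(net: BayesianNetwork, sons: list[str]) -> dict[str, str]:
    if not sons:
        return {}
    lookup = JointLookup(net)
    if lookup._table is None:  # state space too large for enumeration
        profile = {}
        for s in sons:
            from .metrics import state_bayes_factor

            var = net.variable(s)
            best = max(
                var.states, key=lambda st: state_bayes_factor(net, s, st, "yes")
            )
            profile[s] = best
        return profile
    names, table = lookup._names, lookup._table
    keep_axes = [names.index(n) for n in [TARGET_NAME] + sons]
    other_axes = tuple(i for i in range(len(names)) if i not in keep_axes)
    marg = table.sum(axis=other_axes) if other_axes else table
    # reorder to (target, sons...)
    order = np.argsort(np.argsort(keep_axes))
    marg = np.transpose(marg, order)
    t_axis_yes = marg[1]
    t_axis_no = marg[0]
    post = t_axis_yes / (t_axis_yes + t_axis_no)
    best = np.unravel_index(int(np.argmax(post)), post.shape)
    return {
        s: net.variable(s).states[i] for s, i in zip(sons, best)
    }


def generate_cohort(
    net: BayesianNetwork,
    n: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    high_missing_fraction: float = 0.0,
    high_missing_rate: float = 0.5,
) -> DataTable:
    """Forward-sample ``n`` records and mask cells completely at random.

    A ``high_missing_fraction`` share of records can be drawn as "poor
    responders" whose per-cell missing rate is ``high_missing_rate``; this
    is what makes the downstream exclusion filter bite.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValidationError("missing_rate must lie in [0, 1)")
    if not 0.0 <= high_missing_fraction <= 1.0:
        raise ValidationError("high_missing_fraction must lie in [0, 1]")
    data = forward_sample(net, n, seed)
    if missing_rate == 0.0 and high_missing_fraction == 0.0:
        return data
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B]))
    rate = np.full(n, missing_rate)
    if high_missing_fraction > 0.0:
        poor = rng.random(n) < high_missing_fraction
        rate[poor] = high_missing_rate
    mask = rng.random((n, len(data.variables))) < rate[:, None]
    codes = {
        v.name: np.where(mask[:, j], -1, data.codes(v.name))
        for j, v in enumerate(data.variables)
    }
    return DataTable.from_codes(data.variables, codes)


def attach_eq5d_levels(
    data: DataTable, extreme_fraction: float, seed: int
) -> DataTable:
    """Add the raw three-level item the binary target collapses from.

    Rows with a positive target are split into "some" and "extreme";
    negative rows are "none".  The level is missing wherever the target is.
    """
    if TARGET_NAME not in {v.name for v in data.variables}:
        raise ValidationError(f"data has no {TARGET_NAME!r} column")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE5]))
    t = data.codes(TARGET_NAME)
    level = np.where(t == 0, 0, np.where(rng.random(data.n_rows) < extreme_fraction, 2, 1))
    level = np.where(t < 0, -1, level)
    var = DiscreteVariable(EQ5D_NAME, EQ5D_STATES)
    codes = {v.name: data.codes(v.name) for v in data.variables}
    codes[EQ5D_NAME] = level
    return DataTable.from_codes(list(data.variables) + [var], codes)


def binarize_eq5d(levels: pd.Series | np.ndarray) -> np.ndarray:
    """Collapse none/some/extreme to binary codes (some+extreme -> 1).

    Returns integer codes (-1 missing) matching the target's (no, yes)
    state order.
    """
    if isinstance(levels, pd.Series):
        codes = levels.cat.codes.to_numpy() if hasattr(levels, "cat") else np.asarray(
            [EQ5D_STATES.index(x) if x in EQ5D_STATES else -1 for x in levels]
        )
    else:
        codes = np.asarray(levels)
    return np.where(codes < 0, -1, (codes > 0).astype(np.int64))


def simulate_study_cohort(
    spec: CohortSpec, n: int, seed: int | None = None
) -> tuple[DataTable, GroundTruth]:
    """The full study-shaped cohort: sampled records, three-level raw
    target item, and mixed-rate missingness."""
    gt = build_ground_truth(spec)
    seed = spec.seed if seed is None else seed
    data = generate_cohort(
        gt.network,
        n,
        missing_rate=spec.missing_rate,
        seed=seed,
        high_missing_fraction=spec.high_missing_fraction,
        high_missing_rate=spec.high_missing_rate,
    )
    return attach_eq5d_levels(data, spec.extreme_fraction, seed), gt


# ---------------------------------------------------------------------------
# random networks (test and validation utilities)


def random_network(
    n_nodes: int,
    seed: int,
    max_card: int = 3,
    edge_prob: float = 0.4,
    concentration: float = 1.0,
    binary: bool = False,
    with_target: bool = False,
) -> BayesianNetwork:
    """A random DAG with Dirichlet CPT rows (strictly positive)."""
    rng = np.random.default_rng(seed)
    variables = []
    for i in range(n_nodes):
        card = 2 if binary else int(rng.integers(2, max_card + 1))
        role = "target" if (with_target and i == 0) else "feature"
        variables.append(
            DiscreteVariable(f"v{i}", tuple(f"s{j}" for j in range(card)), role=role)
        )
    structure = NetworkStructure(variables)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                if len(structure.parents(variables[j].name)) < 3:
                    structure.add_arc(variables[i].name, variables[j].name)
    cpts = {}
    for v in variables:
        parents = structure.parents(v.name)
        cards = [structure.variables[p].cardinality for p in parents]
        n_cfg = int(np.prod(cards)) if parents else 1
        table = rng.dirichlet(np.full(v.cardinality, concentration), size=n_cfg)
        table = np.clip(table, 1e-3, None)
        table /= table.sum(axis=1, keepdims=True)
        cpts[v.name] = ConditionalProbabilityTable(
            v.name, parents, table, cards, v.cardinality
        )
    return BayesianNetwork(structure, cpts)


def build_tan_ground_truth(
    n_features: int = 8, seed: int = 0, effect_size: float = 0.3
) -> tuple[BayesianNetwork, list[tuple[str, str]]]:
    """A TAN-shaped generating network with strong tree dependencies.

    Returns the network and the undirected feature-tree skeleton.  Every
    feature is binary-to-4-state; each tree edge and each target arc has a
    conditional row contrast of at least ``effect_size``.
    """
    rng = np.random.default_rng(seed)
    target = DiscreteVariable("class", ("neg", "pos"), role="target")
    features = [
        DiscreteVariable(f"f{i:02d}", tuple(f"s{j}" for j in range(int(rng.integers(2, 5)))))
        for i in range(n_features)
    ]
    # random tree: attach node i to a uniformly chosen earlier node
    tree = []
    for i in range(1, n_features):
        j = int(rng.integers(0, i))
        tree.append((features[j].name, features[i].name))
    structure = NetworkStructure([target] + features)
    for f in features:
        structure.add_arc("class", f.name)
    for u, v in tree:
        structure.add_arc(u, v)
    cpts = {"class": ConditionalProbabilityTable("class", (), [[0.6, 0.4]], (), 2)}
    for f in features:
        parents = structure.parents(f.name)
        cards = tuple(structure.variables[p].cardinality for p in parents)
        n_cfg = int(np.prod(cards))
        card = f.cardinality
        table = np.empty((n_cfg, card))
        for cfg in range(n_cfg):
            # give every parent configuration its own sharply peaked row so
            # both the class arc and the tree edge carry signal
            idx = np.unravel_index(cfg, cards)
            peak = int(sum(idx)) % card
            row = np.full(card, (1.0 - (0.55 + effect_size / 2)) / (card - 1))
            row[peak] = 0.55 + effect_size / 2
            table[cfg] = row / row.sum()
        cpts[f.name] = ConditionalProbabilityTable(f.name, parents, table, cards, card)
    net = BayesianNetwork(structure, cpts)
    return net, tree
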