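"""Information measures, arc force, and generalized Bayes factors."""

import math

import numpy as np
import pytest

from conftest import brute_marginal

from ssbn import (
    DataTable,
    arc_force,
    conditional_mutual_information,
    fit_parameters,
    forward_sample,
    gbf,
    gbf_chain,
    gbf_conditional,
    kl_divergence,
    mutual_information,
    random_network,
    relative_binary_mi,
    state_bayes_factor,
    target_report,
)
from ssbn.exceptions import (
    IllDefinedComplementError,
    UndefinedMeasureError,
    ValidationError,
)
from ssbn.network import Distribution, DiscreteVariable, NetworkStructure


def dist(probs, var="x", states=None):
    states = states or tuple(f"s{i}" for i in range(len(probs)))
    return Distribution(var, states, np.array(probs, float))


def table_from_joint(joint, names=("x", "y")):
    """DataTable whose empirical joint equals ``joint`` exactly."""
    joint = np.asarray(joint)
    scale = 1000
    counts = np.round(joint * scale).astype(int)
    xs, ys = [], []
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            xs += [i] * counts[i, j]
            ys += [j] * counts[i, j]
    vx = DiscreteVariable(names[0], tuple(f"a{i}" for i in range(joint.shape[0])))
    vy = DiscreteVariable(names[1], tuple(f"b{j}" for j in range(joint.shape[1])))
    return DataTable.from_codes([vx, vy], {names[0]: np.array(xs), names[1]: np.array(ys)})


class TestKLDivergence:
    def test_identity_is_zero(self):
        p = dist([0.3, 0.7])
        assert kl_divergence(p, p) == 0.0

    def test_point_mass_vs_uniform_is_one_bit(self):
        assert kl_divergence(dist([1.0, 0.0]), dist([0.5, 0.5])) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        got = kl_divergence(dist([0.75, 0.25]), dist([0.5, 0.5]))
        assert got == pytest.approx(0.188722, abs=1e-5)

    def test_infinite_sentinel_not_exception(self):
        assert kl_divergence(dist([0.5, 0.5]), dist([1.0, 0.0])) == math.inf

    def test_mismatched_supports_rejected(self):
        with pytest.raises(ValidationError):
            kl_divergence(dist([0.5, 0.5], var="x"), dist([0.5, 0.5], var="y"))


class TestMutualInformation:
    def test_independent_uniform_is_zero(self):
        t = table_from_joint([[0.25, 0.25], [0.25, 0.25]])
        assert mutual_information(t, "x", "y") == pytest.approx(0.0, abs=1e-12)

    def test_perfect_dependence_is_one_bit(self):
        t = table_from_joint([[0.5, 0.0], [0.0, 0.5]])
        assert mutual_information(t, "x", "y") == pytest.approx(1.0)

    def test_direct_evaluation(self):
        t = table_from_joint([[0.4, 0.1], [0.1, 0.4]])
        assert mutual_information(t, "x", "y") == pytest.approx(0.278072, abs=1e-5)

    def test_constant_column_returns_zero(self, caplog):
        t = table_from_joint([[0.5, 0.5], [0.0, 0.0]])
        assert mutual_information(t, "x", "y") == 0.0


class TestConditionalMI:
    def test_degenerate_conditioning_equals_plain_mi(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 500)
        y = (x + (rng.random(500) < 0.2)) % 2
        z = np.zeros(500, dtype=int)
        vs = [DiscreteVariable(n, ("0", "1")) for n in "xyz"]
        t = DataTable.from_codes(vs, {"x": x, "y": y, "z": z})
        assert conditional_mutual_information(t, "x", "y", "z") == pytest.approx(
            mutual_information(t, "x", "y"), abs=1e-12
        )

    def test_conditional_independence_is_near_zero(self):
        # x and y both driven by z, independent given z
        rng = np.random.default_rng(1)
        n = 50_000
        z = rng.integers(0, 2, n)
        flip = lambda: rng.random(n) < 0.2
        x = (z + flip()) % 2
        y = (z + flip()) % 2
        vs = [DiscreteVariable(nm, ("0", "1")) for nm in "xyz"]
        t = DataTable.from_codes(vs, {"x": x, "y": y, "z": z})
        assert conditional_mutual_information(t, "x", "y", "z") < 0.001
        # while the unconditional MI is clearly positive
        assert mutual_information(t, "x", "y") > 0.05

    def test_matches_closed_form_of_generating_net(self):
        # z -> x, z -> y with known CPTs; closed-form CMI is 0 by construction
        net = random_network(3, seed=9, max_card=3)
        data = forward_sample(net, 100_000, seed=2)
        names = list(net.variables)
        cmi = conditional_mutual_information(data, names[0], names[1], names[2])
        assert cmi >= 0.0


class TestArcForce:
    def test_vacuous_arc_has_zero_force(self, toy_net):
        data = forward_sample(toy_net, 2000, seed=0)
        # rebuild E's CPT with identical rows -> arc carries nothing
        from ssbn.network import BayesianNetwork, tabular_cpt

        s = toy_net.structure
        net = BayesianNetwork(
            s,
            {"T": toy_net.cpts["T"],
             "E": tabular_cpt(s, "E", [[0.7, 0.3], [0.7, 0.3]])},
        )
        rep = arc_force(net, data, ("T", "E"), smoothing=1.0)
        # the refit joint differs only through sampling noise in the refit
        assert rep.force < 0.01

    def test_two_node_identity_with_empirical_mi(self, toy_net):
        data = forward_sample(toy_net, 5000, seed=3)
        rep = arc_force(toy_net_fit := fit_parameters(
            toy_net.structure, data, smoothing=0.0), data, ("T", "E"), smoothing=0.0)
        assert rep.force == pytest.approx(
            mutual_information(data, "T", "E"), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_force_nonnegative_on_random_nets(self, seed):
        net = random_network(5, seed=seed + 30, max_card=3, edge_prob=0.6)
        if not net.structure.arcs:
            pytest.skip("no arcs drawn")
        data = forward_sample(net, 3000, seed=seed)
        for arc in net.structure.arcs[:3]:
            assert arc_force(net, data, arc, smoothing=1.0).force >= 0.0


class TestRelativeBinaryMI:
    def test_independent_is_zero(self):
        t = table_from_joint([[0.25, 0.25], [0.25, 0.25]])
        assert relative_binary_mi(t, "x", "y") == pytest.approx(0.0, abs=1e-9)

    def test_identical_is_hundred(self):
        t = table_from_joint([[0.5, 0.0], [0.0, 0.5]])
        assert relative_binary_mi(t, "x", "y") == pytest.approx(100.0)

    def test_direct_evaluation(self):
        t = table_from_joint([[0.4, 0.1], [0.1, 0.4]])
        assert relative_binary_mi(t, "x", "y") == pytest.approx(27.8072, abs=1e-3)

    def test_zero_entropy_target_raises(self):
        t = table_from_joint([[0.5, 0.0], [0.5, 0.0]])
        with pytest.raises(UndefinedMeasureError):
            relative_binary_mi(t, "x", "y")


class TestStateBayesFactor:
    def test_hand_ratio(self, toy_net):
        assert state_bayes_factor(toy_net, "E", "1", "1") == pytest.approx(4.0)

    def test_reciprocity(self, toy_net):
        for s in ("0", "1"):
            prod = (state_bayes_factor(toy_net, "E", s, "1")
                    * state_bayes_factor(toy_net, "E", s, "0"))
            assert prod == pytest.approx(1.0, abs=1e-12)

    def test_independent_variable_is_unity(self):
        net = random_network(4, seed=5, edge_prob=0.0, with_target=True, binary=True)
        names = list(net.variables)
        assert state_bayes_factor(
            net, names[1], net.variables[names[1]].states[0], "s1"
        ) == pytest.approx(1.0, abs=1e-12)


class TestGBF:
    def test_hand_case(self, toy_net):
        assert gbf(toy_net, {"T": "1"}, {"E": "1"}) == pytest.approx(4.0)

    def test_independent_explanation_is_unity(self):
        net = random_network(5, seed=8, edge_prob=0.0)
        names = list(net.variables)
        x = {names[0]: net.variables[names[0]].states[0]}
        e = {names[1]: net.variables[names[1]].states[0]}
        assert gbf(net, x, e) == pytest.approx(1.0, abs=1e-10)

    def test_overlapping_sets_rejected(self, toy_net):
        with pytest.raises(ValidationError):
            gbf(toy_net, {"T": "1"}, {"T": "0"})

    def test_certain_explanation_is_ill_defined(self):
        from ssbn.network import BayesianNetwork, tabular_cpt

        t = DiscreteVariable("T", ("0", "1"))
        e = DiscreteVariable("E", ("0", "1"))
        s = NetworkStructure([t, e], [("T", "E")])
        net = BayesianNetwork(
            s,
            {"T": tabular_cpt(s, "T", [[0.0, 1.0]]),
             "E": tabular_cpt(s, "E", [[0.5, 0.5], [0.4, 0.6]])},
        )
        with pytest.raises(IllDefinedComplementError):
            gbf(net, {"T": "1"}, {"E": "1"})

    def test_symmetry_in_explanation(self):
        # GBF(x;e) > 1 iff swapping the binary explanation gives < 1
        for seed in range(10):
            net = random_network(5, seed=seed + 70, binary=True)
            names = list(net.variables)
            x = {names[0]: "s1"}
            x_bar = {names[0]: "s0"}
            e = {names[-1]: "s1"}
            g, g_swap = gbf(net, x, e), gbf(net, x_bar, e)
            if not math.isclose(g, 1.0, abs_tol=1e-9):
                assert (g > 1.0) == (g_swap < 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_joint(self, seed):
        net = random_network(5, seed=seed + 90, max_card=3)
        names = list(net.variables)
        x = {names[0]: net.variables[names[0]].states[0]}
        e = {names[-1]: net.variables[names[-1]].states[-1],
             names[-2]: net.variables[names[-2]].states[0]}
        px = brute_marginal(net, x)
        pe = brute_marginal(net, e)
        pex = brute_marginal(net, {**x, **e})
        want = (pex / px) / ((pe - pex) / (1 - px))
        assert gbf(net, x, e) == pytest.approx(want, rel=1e-9)


class TestGBFConditional:
    def test_empty_conditioning_reduces_to_gbf(self, toy_net):
        got = gbf_conditional(toy_net, {"T": "1"}, {"E": "1"}, {})
        assert got == pytest.approx(gbf(toy_net, {"T": "1"}, {"E": "1"}))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_full_joint_oracle(self, seed):
        net = random_network(6, seed=seed + 120, max_card=3)
        names = list(net.variables)
        y = {names[0]: net.variables[names[0]].states[0]}
        x = {names[1]: net.variables[names[1]].states[0]}
        e = {names[-1]: net.variables[names[-1]].states[-1]}
        pyx = brute_marginal(net, {**y, **x})
        px = brute_marginal(net, x)
        peyx = brute_marginal(net, {**y, **x, **e})
        pex = brute_marginal(net, {**x, **e})
        want = (peyx / pyx) / ((pex - peyx) / (px - pyx))
        assert gbf_conditional(net, y, e, x) == pytest.approx(want, rel=1e-9)


class TestGBFChain:
    def test_single_piece_equals_gbf(self, toy_net):
        assert gbf_chain(toy_net, {"T": "1"}, [{"E": "1"}]) == pytest.approx(
            gbf(toy_net, {"T": "1"}, {"E": "1"})
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_two_piece_split_equals_unsplit(self, seed):
        net = random_network(6, seed=seed + 150, max_card=3)
        names = list(net.variables)
        x = {names[0]: net.variables[names[0]].states[0]}
        e1 = {names[2]: net.variables[names[2]].states[0]}
        e2 = {names[4]: net.variables[names[4]].states[-1]}
        whole = gbf(net, x, {**e1, **e2})
        assert gbf_chain(net, x, [e1, e2]) == pytest.approx(whole, rel=1e-9)
        assert gbf_chain(net, x, [e2, e1]) == pytest.approx(whole, rel=1e-9)

    def test_three_piece_order_invariance(self):
        import itertools

        net = random_network(7, seed=321, max_card=3)
        names = list(net.variables)
        x = {names[0]: net.variables[names[0]].states[0]}
        pieces = [
            {names[i]: net.variables[names[i]].states[0]} for i in (2, 4, 6)
        ]
        values = {
            gbf_chain(net, x, list(perm))
            for perm in itertools.permutations(pieces)
        }
        ref = values.pop()
        assert all(math.isclose(v, ref, rel_tol=1e-9) for v in values)

    def test_nondisjoint_pieces_rejected(self, toy_net):
        with pytest.raises(ValidationError):
            gbf_chain(toy_net, {"T": "1"}, [{"E": "1"}, {"E": "0"}])


class TestTargetReport:
    def test_columns_and_ranges(self):
        from ssbn import CohortSpec, build_ground_truth, generate_cohort

        gt = build_ground_truth(CohortSpec(n_sons=3, n_spouses=2, n_noise=1))
        data = generate_cohort(gt.network, 3000, seed=0)
        rep = target_report(gt.network, data)
        assert len(rep) == len(gt.network.variables) - 1
        assert ((rep.relative_binary_mi_pct >= 0)
                & (rep.relative_binary_mi_pct <= 100)).all()
        for t in ("no", "yes"):
            assert (rep[f"max_bf_{t}"] >= rep[f"min_bf_{t}"] - 1e-12).all()
            assert (rep[f"min_bf_{t}"] >= 0).all()
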