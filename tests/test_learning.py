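"""Parameter estimation and the three structure learners."""

import numpy as np
import pytest

from ssbn import (
    CohortSpec,
    DataTable,
    LearnerConfig,
    build_ground_truth,
    build_tan_ground_truth,
    fit_parameters,
    forward_sample,
    generate_cohort,
    learn_naive_bayes,
    learn_sons_and_spouses,
    learn_tan,
    select_features,
)
from ssbn.exceptions import ConfigurationError, EstimationError
from ssbn.network import DiscreteVariable, NetworkStructure


def binary_table(name, codes):
    v = DiscreteVariable(name, ("0", "1"))
    return DataTable.from_codes([v], {name: np.asarray(codes)})


class TestFitParameters:
    def test_balanced_binary_no_smoothing(self):
        data = binary_table("x", [0] * 50 + [1] * 50)
        s = NetworkStructure([DiscreteVariable("x", ("0", "1"))])
        net = fit_parameters(s, data, smoothing=0.0)
        assert np.allclose(net.cpts["x"].table, [[0.5, 0.5]])

    def test_laplace_arithmetic_on_zero_cell(self):
        data = binary_table("x", [0] * 9)
        s = NetworkStructure([DiscreteVariable("x", ("0", "1"))])
        net = fit_parameters(s, data, smoothing=1.0)
        assert np.allclose(net.cpts["x"].table, [[10 / 11, 1 / 11]])

    def test_empty_family_without_smoothing_raises(self):
        data = binary_table("x", [0] * 5)  # state 1 never observed as parent
        y = DiscreteVariable("y", ("0", "1"))
        vs = [DiscreteVariable("x", ("0", "1")), y]
        full = DataTable.from_codes(vs, {"x": np.zeros(5, int), "y": np.zeros(5, int)})
        s = NetworkStructure(vs, [("x", "y")])
        with pytest.raises(EstimationError):
            fit_parameters(s, full, smoothing=0.0)

    def test_recovery_from_large_sample(self):
        # max error is bounded by the binomial noise of the thinnest CPT
        # stratum (target=yes ~ 5.5% of rows, split further by spouse state)
        gt = build_ground_truth(CohortSpec(seed=4))
        data = forward_sample(gt.network, 100_000, seed=11)
        refit = fit_parameters(gt.network.structure, data, smoothing=1.0)
        errors = np.concatenate([
            np.abs(refit.cpts[n].table - gt.network.cpts[n].table).ravel()
            for n in gt.network.variables
        ])
        assert errors.max() <= 0.08
        assert errors.mean() <= 0.01

    def test_incomplete_family_rows_are_dropped(self):
        vs = [DiscreteVariable("x", ("0", "1")), DiscreteVariable("y", ("0", "1"))]
        codes = {"x": np.array([0, 0, 1, -1]), "y": np.array([1, -1, 0, 1])}
        data = DataTable.from_codes(vs, codes)
        s = NetworkStructure(vs, [("x", "y")])
        net = fit_parameters(s, data, smoothing=0.0)
        # y's family uses only the two rows complete for both columns
        assert np.allclose(net.cpts["y"].table, [[0.0, 1.0], [1.0, 0.0]])


class TestNaiveBayes:
    def test_topology_contract(self):
        gt = build_ground_truth(CohortSpec(n_sons=3, n_spouses=0, n_noise=0))
        data = generate_cohort(gt.network, 500, seed=0)
        net = learn_naive_bayes(data, "depression")
        arcs = set(net.structure.arcs)
        assert arcs == {("depression", s) for s in gt.sons}

    def test_posterior_equals_closed_form_product_rule(self):
        gt = build_ground_truth(CohortSpec(n_sons=3, n_spouses=0, n_noise=0, seed=2))
        data = generate_cohort(gt.network, 2000, seed=1)
        net = learn_naive_bayes(data, "depression")
        record = data.record(0)
        evidence = {k: v for k, v in record.items() if k != "depression"}
        # closed form: prior * prod of likelihoods, renormalised
        prior = net.cpts["depression"].table[0]
        like = np.ones(2)
        for f, state in evidence.items():
            cpt = net.cpts[f]
            j = net.variables[f].index_of(state)
            like *= cpt.table[:, j]
        want = prior * like
        want /= want.sum()
        from ssbn import posterior

        got = posterior(net, "depression", evidence).probabilities
        assert np.allclose(got, want, atol=1e-12)

    def test_missing_target_column_rejected(self):
        gt = build_ground_truth(CohortSpec(n_sons=2, n_spouses=0, n_noise=0))
        data = generate_cohort(gt.network, 100, seed=0)
        with pytest.raises(ConfigurationError):
            learn_naive_bayes(data, "nonexistent")


class TestTAN:
    def test_topology_contract(self):
        net, _ = build_tan_ground_truth(6, seed=1)
        data = forward_sample(net, 5000, seed=1)
        learned = learn_tan(data, "class")
        for f in learned.variables:
            if f == "class":
                continue
            parents = learned.structure.parents(f)
            assert "class" in parents
            assert len(parents) <= 2  # class + at most one feature

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_skeleton_recovery(self, seed):
        net, tree = build_tan_ground_truth(8, seed=seed)
        data = forward_sample(net, 20_000, seed=seed + 100)
        learned = learn_tan(data, "class")
        got = {frozenset(a) for a in learned.structure.arcs if "class" not in a}
        assert got == {frozenset(e) for e in tree}

    def test_too_few_features_rejected(self):
        data = binary_table("t", [0, 1] * 10)
        with pytest.raises(ConfigurationError):
            learn_tan(data, "t")


class TestSonsAndSpouses:
    def test_recovery_of_sons_and_rejection_of_noise(self):
        spec = CohortSpec(seed=0)
        gt = build_ground_truth(spec)
        data = generate_cohort(gt.network, 20_000, seed=5)
        net = learn_sons_and_spouses(data, "depression")
        sons = set(net.structure.children("depression"))
        selected = select_features(net, "depression")
        assert sons >= set(gt.sons)
        assert not (selected & set(gt.noise))
        # spouses never connect to the target
        for sp in gt.spouses:
            assert ("depression", sp) not in net.structure.arcs
            assert (sp, "depression") not in net.structure.arcs

    def test_no_signal_yields_target_only_network(self):
        gt = build_ground_truth(CohortSpec(n_sons=0, n_spouses=0, n_noise=5))
        data = generate_cohort(gt.network, 3000, seed=1)
        net = learn_sons_and_spouses(data, "depression")
        assert set(net.variables) == {"depression"}
        assert not net.structure.arcs

    def test_monotone_in_sample_size(self):
        # a true son, once detected, is never lost as n grows
        gt = build_ground_truth(CohortSpec(seed=1))
        data = generate_cohort(gt.network, 20_000, seed=9)
        previous: set = set()
        for n in (2000, 10_000, 20_000):
            net = learn_sons_and_spouses(data.subset_rows(np.arange(n)), "depression")
            sons = set(net.structure.children("depression")) & set(gt.sons)
            assert sons >= previous
            previous = sons
        assert previous == set(gt.sons)

    def test_structure_acyclic_and_legal(self):
        gt = build_ground_truth(CohortSpec(seed=3))
        data = generate_cohort(gt.network, 8000, seed=2)
        net = learn_sons_and_spouses(data, "depression")
        import networkx as nx

        assert nx.is_directed_acyclic_graph(net.structure.to_digraph())
        assert not net.structure.parents("depression")
        # every retained non-son must parent at least one son
        sons = set(net.structure.children("depression"))
        for name in net.variables:
            if name == "depression" or name in sons:
                continue
            assert any(c in sons for c in net.structure.children(name))


class TestSelectFeatures:
    def test_figure_shaped_fixture_selects_thirteen(self):
        # 7 direct children; 6 extra parents of those children
        vs = [DiscreteVariable("t", ("0", "1"), role="target")]
        vs += [DiscreteVariable(f"son{i}", ("0", "1")) for i in range(7)]
        vs += [DiscreteVariable(f"sp{i}", ("0", "1")) for i in range(6)]
        arcs = [("t", f"son{i}") for i in range(7)]
        arcs += [(f"sp{i}", f"son{i}") for i in range(6)]
        s = NetworkStructure(vs, arcs)
        from ssbn.learning import fit_parameters as fp
        from ssbn.network import tabular_cpt, BayesianNetwork

        cpts = {}
        for v in vs:
            n_cfg = int(np.prod([2] * len(s.parents(v.name)))) if s.parents(v.name) else 1
            cpts[v.name] = tabular_cpt(s, v.name, [[0.5, 0.5]] * n_cfg)
        net = BayesianNetwork(s, cpts)
        assert len(select_features(net, "t")) == 13

    def test_naive_bayes_selects_all_features(self):
        gt = build_ground_truth(CohortSpec(n_sons=4, n_spouses=0, n_noise=0))
        data = generate_cohort(gt.network, 1000, seed=0)
        net = learn_naive_bayes(data, "depression")
        assert select_features(net, "depression") == set(gt.sons)

    def test_target_only_network_selects_nothing(self):
        v = DiscreteVariable("t", ("0", "1"), role="target")
        s = NetworkStructure([v])
        from ssbn.network import tabular_cpt, BayesianNetwork

        net = BayesianNetwork(s, {"t": tabular_cpt(s, "t", [[0.5, 0.5]])})
        assert select_features(net, "t") == set()

    def test_unknown_target_rejected(self, toy_net):
        with pytest.raises(ConfigurationError):
            select_features(toy_net, "ghost")
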