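"""Network learning, fitting and sampling against enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

from bayesboost.bayesnet import (
    BayesianNetwork,
    Cpt,
    Dag,
    NetworkError,
    bic_score,
    enumerate_dags,
    exact_marginal,
    fit_parameters,
    learn_structure,
    logic_sample,
    override_cpt,
    sample_with_evidence,
)


def three_se(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


def chain_data(n=5000, seed=0):
    """Strongly dependent chain A -> B -> C over binary variables."""
    rng = np.random.default_rng(seed)
    a = (rng.random(n) < 0.5).astype(int)
    b = np.where(rng.random(n) < 0.9, a, 1 - a)
    c = np.where(rng.random(n) < 0.9, b, 1 - b)
    return pd.DataFrame({"A": a.astype(str), "B": b.astype(str), "C": c.astype(str)})


class TestStructureLearning:
    def test_chain_skeleton_recovered_and_matches_exhaustive_optimum(self):
        data = chain_data()
        dag = learn_structure(data, max_parents=2, seed=0)
        skeleton = {frozenset(e) for e in dag.edges}
        assert skeleton == {frozenset({"A", "B"}), frozenset({"B", "C"})}
        best = max(enumerate_dags(["A", "B", "C"]), key=lambda d: bic_score(data, d))
        assert bic_score(data, dag) == pytest.approx(bic_score(data, best), rel=1e-12)

    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {k: rng.choice(["0", "1"], size=3000) for k in ("A", "B", "C")}
        )
        assert learn_structure(data).edges == ()

    def test_deterministic_under_seed(self):
        data = chain_data(seed=4)
        assert learn_structure(data, seed=3) == learn_structure(data, seed=3)

    def test_learned_bic_never_below_empty_graph(self, cvd_small):
        from bayesboost.core_data import discretize

        disc, _ = discretize(cvd_small)
        dag = learn_structure(disc)
        empty = Dag(dag.nodes, ())
        assert bic_score(disc, dag) >= bic_score(disc, empty)

    def test_roots_receive_no_parents(self):
        data = chain_data()
        dag = learn_structure(data, roots=("B",))
        assert dag.parents("B") == ()
        # B may still be a parent
        assert any(p == "B" for p, _ in dag.edges)


class TestParameterFitting:
    def test_laplace_formula_on_counts(self):
        # parentless binary node, counts (8, 2), alpha=1 -> (9/12, 3/12)
        data = pd.DataFrame({"X": ["0"] * 8 + ["1"] * 2})
        net = fit_parameters(data, Dag(("X",), ()), laplace_alpha=1.0)
        np.testing.assert_allclose(net.cpts["X"].table, [[9 / 12, 3 / 12]])
        net0 = fit_parameters(data, Dag(("X",), ()), laplace_alpha=0.0)
        np.testing.assert_allclose(net0.cpts["X"].table, [[0.8, 0.2]])

    def test_unseen_parent_configuration_is_uniform(self):
        from bayesboost.core_data import CATEGORICAL, Schema, TabularDataset, Variable

        schema = Schema(
            variables=(
                Variable("A", CATEGORICAL, ("0", "1")),
                Variable("B", CATEGORICAL, ("0", "1")),
            ),
            target_name="B",
            protected_name="A",
        )
        data = TabularDataset(schema, pd.DataFrame({"A": ["0", "0"], "B": ["0", "1"]}))
        net = fit_parameters(data, Dag(("A", "B"), (("A", "B"),)), laplace_alpha=1.0)
        # A=1 never observed; with alpha=1 on zero counts -> (0.5, 0.5)
        np.testing.assert_allclose(net.cpts["B"].table[1], [0.5, 0.5])


class TestSampling:
    def test_logic_sample_marginal_matches_enumeration(self, toy_net):
        n = 50_000
        frame = logic_sample(toy_net, n, seed=2)
        exact = exact_marginal(toy_net, "B")
        assert exact == pytest.approx([0.62, 0.38])
        emp = (frame["B"] == "1").mean()
        assert abs(emp - exact[1]) < three_se(exact[1], n)

    def test_single_row_and_degenerate_network(self, toy_net):
        row = logic_sample(toy_net, 1, seed=0)
        assert set(row.columns) == {"A", "B"}
        det = override_cpt(override_cpt(toy_net, "A", [0, 1]), "B", [1, 0])
        frame = logic_sample(det, 100, seed=0)
        assert (frame["A"] == "1").all() and (frame["B"] == "0").all()

    def test_evidence_sampling_matches_bayes_rule(self, toy_net):
        n = 50_000
        frame = sample_with_evidence(toy_net, {"B": "1"}, n, seed=5)
        assert (frame["B"] == "1").all()
        exact = exact_marginal(toy_net, "A", {"B": "1"})
        assert exact[1] == pytest.approx(0.3 * 0.8 / 0.38)
        assert abs((frame["A"] == "1").mean() - exact[1]) < three_se(exact[1], n)

    def test_full_evidence_returns_constant_rows(self, toy_net):
        frame = sample_with_evidence(toy_net, {"A": "0", "B": "1"}, 50, seed=1)
        assert (frame["A"] == "0").all() and (frame["B"] == "1").all()

    def test_root_evidence_equals_clamped_forward_sampling(self, toy_net):
        n = 50_000
        cond = sample_with_evidence(toy_net, {"A": "1"}, n, seed=3)
        clamped = override_cpt(toy_net, "A", [0, 1])
        fwd = logic_sample(clamped, n, seed=3)
        p_cond = (cond["B"] == "1").mean()
        p_fwd = (fwd["B"] == "1").mean()
        assert abs(p_cond - p_fwd) < 2 * three_se(0.8, n)

    def test_impossible_evidence_names_the_assignment(self, toy_net):
        det = override_cpt(toy_net, "B", [1.0, 0.0])
        with pytest.raises(NetworkError, match="B"):
            sample_with_evidence(det, {"B": "1"}, 10, seed=0)


class TestOverrideAndSerialization:
    def test_override_controls_sampled_marginal(self, toy_net):
        n = 50_000
        net = override_cpt(toy_net, "A", [0.7, 0.3])  # identity override
        emp = (logic_sample(net, n, seed=7)["A"] == "1").mean()
        assert abs(emp - 0.3) < three_se(0.3, n)
        skew = override_cpt(toy_net, "A", [0.1, 0.9])
        emp = (logic_sample(skew, n, seed=7)["A"] == "1").mean()
        assert abs(emp - 0.9) < three_se(0.9, n)

    def test_override_rejects_invalid_vector(self, toy_net):
        with pytest.raises(NetworkError):
            override_cpt(toy_net, "A", [0.5, 0.6])

    def test_yaml_round_trip(self, toy_net, tmp_path):
        path = tmp_path / "net.yaml"
        toy_net.to_yaml(path)
        back = BayesianNetwork.from_yaml(path)
        assert back.dag == toy_net.dag
        for node in toy_net.dag.nodes:
            np.testing.assert_allclose(back.cpts[node].table, toy_net.cpts[node].table)


class TestExactMarginal:
    def test_marginals_normalize_and_degenerate_evidence(self, toy_net):
        for var in ("A", "B"):
            assert exact_marginal(toy_net, var).sum() == pytest.approx(1.0)
        one_hot = exact_marginal(toy_net, "A", {"A": "1", "B": "0"})
        np.testing.assert_allclose(one_hot, [0.0, 1.0])

    def test_too_large_state_space_raises(self, toy_net):
        with pytest.raises(NetworkError, match="sampling"):
            exact_marginal(toy_net, "A", max_states=1)


@pytest.mark.parametrize("seed", range(4))
def test_sampling_agrees_with_enumeration_on_random_networks(seed):
    """Property: forward and evidence sampling match brute-force inference."""
    rng = np.random.default_rng(seed)
    n_nodes = int(rng.integers(2, 5))
    names = [f"V{i}" for i in range(n_nodes)]
    edges = tuple(
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < 0.5
    )
    dag = Dag(tuple(names), edges)
    levels = {nm: ("0", "1", "2")[: int(rng.integers(2, 4))] for nm in names}
    cpts = {}
    for nm in names:
        ps = dag.parents(nm)
        q = int(np.prod([len(levels[p]) for p in ps])) if ps else 1
        raw = rng.random((q, len(levels[nm]))) + 0.1
        cpts[nm] = Cpt(nm, ps, raw / raw.sum(axis=1, keepdims=True))
    net = BayesianNetwork(dag=dag, cpts=cpts, level_index=levels)

    n = 30_000
    frame = logic_sample(net, n, seed=seed)
    for nm in names:
        exact = exact_marginal(net, nm)
        for k, level in enumerate(levels[nm]):
            emp = (frame[nm] == level).mean()
            assert abs(emp - exact[k]) < max(three_se(exact[k], n), 1e-3)

    ev_var = names[-1]
    ev_val = levels[ev_var][0]
    cond = sample_with_evidence(net, {ev_var: ev_val}, n, seed=seed + 1)
    target = names[0]
    exact = exact_marginal(net, target, {ev_var: ev_val})
    for k, level in enumerate(levels[target]):
        emp = (cond[target] == level).mean()
        assert abs(emp - exact[k]) < max(3.5 * np.sqrt(exact[k] * (1 - exact[k]) / n), 2e-3)
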