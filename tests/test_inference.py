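"""CPT fitting, variable elimination, interventions, influence diagrams."""

import numpy as np
import pandas as pd
import pytest

from conftest import enumerate_posterior, random_discrete_net
from exacbn.bayesnet import (DiscreteBayesNet, InconsistentEvidenceError,
                             bayesnet_from_spec, counterfactual_compare,
                             fit_cpts, intervene_do, joint_probability,
                             predict_exacerbation_risk, variable_elimination)
from exacbn.graphs import NetworkStructure
from exacbn.influence import (DecisionNode, InfluenceDiagram, UtilityNode,
                              evaluate_influence_diagram)


def chain_net():
    dag = NetworkStructure(("A", "B"), {("A", "B")})
    return DiscreteBayesNet(
        dag, {"A": ["0", "1"], "B": ["0", "1"]},
        {"A": np.array([0.4, 0.6]),
         "B": np.array([[0.8, 0.2], [0.1, 0.9]])})


class TestFitCpts:
    def test_ml_counts_ratio(self):
        df = pd.DataFrame({"A": ["1"] * 40 + ["0"] * 10,
                           "B": ["1"] * 30 + ["0"] * 10 + ["0"] * 10})
        dag = NetworkStructure(("A", "B"), {("A", "B")})
        net = fit_cpts(dag, df, smoothing_alpha=0.0)
        # P(B=1 | A=1) = 30 / 40
        ia = net.levels["A"].index("1")
        ib = net.levels["B"].index("1")
        assert net.cpts["B"][ia, ib] == pytest.approx(0.75)

    def test_large_alpha_tends_uniform(self):
        df = pd.DataFrame({"A": ["1"] * 90 + ["0"] * 10})
        dag = NetworkStructure(("A",))
        net = fit_cpts(dag, df, smoothing_alpha=1e9)
        np.testing.assert_allclose(net.cpts["A"], [0.5, 0.5], atol=1e-6)

    def test_rows_normalized_and_unobserved_config_uniform(self):
        df = pd.DataFrame({"A": ["0"] * 50 + ["1"] * 50,
                           "B": ["0"] * 100,
                           "C": ["x"] * 100})
        dag = NetworkStructure(("A", "B", "C"), {("A", "C"), ("B", "C")})
        net = fit_cpts(dag, df, smoothing_alpha=1.0)
        for n, cpt in net.cpts.items():
            rows = cpt.reshape(-1, cpt.shape[-1])
            np.testing.assert_allclose(rows.sum(1), 1.0, atol=1e-12)

    def test_alpha_zero_warns_on_empty_configs(self):
        df = pd.DataFrame({"A": ["0", "1"] * 10, "B": ["0", "1"] * 10,
                           "C": ["0", "1"] * 10})
        dag = NetworkStructure(("A", "B", "C"), {("A", "C"), ("B", "C")})
        with pytest.warns(UserWarning):
            fit_cpts(dag, df, smoothing_alpha=0.0)

    def test_consistency_against_generator(self, core9):
        # alpha=0 CPTs at n=100k match the generating tables within 0.01
        from exacbn.synthetic import sample_cohort
        df = sample_cohort(core9, 100_000, seed=21)
        bands = core9.discretize(df)
        net = fit_cpts(core9.dag(), bands, smoothing_alpha=0.0)
        for node in ("crs", "bec", "feno"):
            ps_spec = core9.parents[node]
            fitted = _reorder_to(net, node, ps_spec, core9)
            true = core9.cpts[node]
            counts = _config_counts(bands, ps_spec, core9)
            cnt = np.broadcast_to(counts, fitted.shape)
            # binomial sampling floor: ±0.01 once counts support it, else 4.5 SE
            tol = np.maximum(0.01, 4.5 * np.sqrt(true * (1 - true)
                                                 / np.maximum(cnt, 1)))
            ok = cnt >= 500
            assert np.all(np.abs(fitted - true)[ok] < tol[ok]), node


def _reorder_to(net, node, ps_spec, spec):
    """Fitted CPT with parent axes and level order matching the spec."""
    ps_fit = net.parent_order[node]
    cpt = net.cpts[node]
    perm = [ps_fit.index(p) for p in ps_spec]
    cpt = np.transpose(cpt, perm + [len(ps_fit)])
    for ax, p in enumerate(list(ps_spec) + [node]):
        order = [net.levels[p].index(str(l)) for l in spec.levels[p]]
        cpt = np.take(cpt, order, axis=ax)
    return cpt


def _config_counts(bands, ps_spec, spec):
    import numpy as np
    idx = np.zeros(len(bands), dtype=np.int64)
    shape = []
    for p in ps_spec:
        codes = np.array([spec.levels[p].index(str(v)) for v in bands[p]])
        idx = idx * len(spec.levels[p]) + codes
        shape.append(len(spec.levels[p]))
    counts = np.bincount(idx, minlength=int(np.prod(shape)) if shape else 1)
    return counts.reshape(shape + [1]) if shape else counts.reshape(1)


class TestVariableElimination:
    def test_chain_total_probability(self):
        post = variable_elimination(chain_net(), "B")
        np.testing.assert_allclose(post, [0.38, 0.62], atol=1e-12)

    def test_matches_enumeration_on_random_networks(self, rng):
        for _ in range(10):
            net = random_discrete_net(rng)
            nodes = list(net.dag.nodes)
            q = nodes[int(rng.integers(len(nodes)))]
            ev = {}
            for m in nodes:
                if m != q and rng.random() < 0.3:
                    ev[m] = int(rng.integers(len(net.levels[m])))
            try:
                got = variable_elimination(net, q, ev)
            except InconsistentEvidenceError:
                continue
            want = enumerate_posterior(net, q, ev)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_posterior_sums_to_one(self, rng):
        net = random_discrete_net(rng)
        q = list(net.dag.nodes)[0]
        assert variable_elimination(net, q).sum() == pytest.approx(1.0,
                                                                   abs=1e-12)

    def test_evidence_on_query_rejected(self):
        with pytest.raises(ValueError):
            variable_elimination(chain_net(), "B", {"B": "1"})

    def test_impossible_evidence_raises(self):
        dag = NetworkStructure(("A", "B"), {("A", "B")})
        net = DiscreteBayesNet(
            dag, {"A": ["0", "1"], "B": ["0", "1"]},
            {"A": np.array([1.0, 0.0]),
             "B": np.array([[1.0, 0.0], [0.5, 0.5]])})
        with pytest.raises(InconsistentEvidenceError):
            variable_elimination(net, "A", {"B": "1"})

    def test_chain_rule_joint_matches_enumeration_cell(self, rng):
        net = random_discrete_net(rng)
        nodes = list(net.dag.nodes)
        a = {m: int(rng.integers(len(net.levels[m]))) for m in nodes}
        p = joint_probability(net, a)
        q = nodes[0]
        full = enumerate_posterior(net, q, {m: v for m, v in a.items()
                                            if m != q})
        marg = variable_elimination(net, q, {m: v for m, v in a.items()
                                             if m != q})
        np.testing.assert_allclose(full, marg, atol=1e-12)
        assert p >= 0


class TestInterventions:
    def test_do_on_root_equals_conditioning(self, core9):
        net = bayesnet_from_spec(core9)
        by_do = variable_elimination(intervene_do(net, "sex", "Female"),
                                     "crs")
        by_cond = variable_elimination(net, "crs", {"sex": "Female"})
        np.testing.assert_allclose(by_do, by_cond, atol=1e-12)

    def test_do_on_sink_changes_nothing_else(self, core9):
        net = bayesnet_from_spec(core9)
        mut = intervene_do(net, "future_exac", "2")
        for m in ("age", "crs", "bec"):
            np.testing.assert_allclose(variable_elimination(mut, m),
                                       variable_elimination(net, m),
                                       atol=1e-12)

    def test_non_descendant_invariance_on_random_dags(self, rng):
        for _ in range(20):
            net = random_discrete_net(rng, max_nodes=6)
            nodes = list(net.dag.nodes)
            target = nodes[int(rng.integers(len(nodes)))]
            desc = _descendants(net.dag, target)
            mut = intervene_do(net, target, 0)
            for m in nodes:
                if m == target or m in desc:
                    continue
                np.testing.assert_allclose(
                    variable_elimination(mut, m),
                    variable_elimination(net, m), atol=1e-10)

    def test_crs_intervention_moves_downstream_only(self, core9, cohort_20k):
        bands = core9.discretize(cohort_20k)
        net = fit_cpts(core9.dag(), bands, smoothing_alpha=1.0)
        mut = intervene_do(net, "crs", "CRSwoNP")
        for m in ("bec", "feno", "fev1pp"):
            assert not np.allclose(variable_elimination(mut, m),
                                   variable_elimination(net, m), atol=1e-4)
        for m in ("age", "sex"):
            np.testing.assert_allclose(variable_elimination(mut, m),
                                       variable_elimination(net, m),
                                       atol=1e-12)

    def test_unknown_level_rejected(self, core9):
        net = bayesnet_from_spec(core9)
        with pytest.raises(KeyError):
            intervene_do(net, "crs", "Wrong")


def _descendants(dag, node):
    out, stack = set(), [node]
    while stack:
        x = stack.pop()
        for c in dag.children(x):
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


class TestRiskPrediction:
    def test_empty_evidence_gives_cohort_marginal(self, core9):
        net = bayesnet_from_spec(core9)
        pred = predict_exacerbation_risk(net, {})
        np.testing.assert_allclose(pred.probabilities,
                                   core9.marginal("future_exac"), atol=1e-9)
        assert pred.p_ge1 >= pred.p_ge2

    def test_full_parent_evidence_returns_cpt_row(self, core9):
        net = bayesnet_from_spec(core9)
        ev = {"prior_exac": "2", "bec": ">=300", "feno": ">=50",
              "fev1pp": "<60", "macrolide": "1"}
        pred = predict_exacerbation_risk(net, ev)
        sel = tuple(net.levels[p].index(ev[p])
                    for p in net.parent_order["future_exac"])
        np.testing.assert_allclose(pred.probabilities,
                                   net.cpts["future_exac"][sel], atol=1e-9)

    def test_mean_prediction_matches_empirical_rate(self, core9):
        from exacbn.synthetic import sample_cohort
        net = bayesnet_from_spec(core9)
        df = sample_cohort(core9, 10000, seed=31)
        bands = core9.discretize(df)
        parents = list(net.parent_order["future_exac"])
        rows = bands[parents].astype(str)
        cache = {}
        preds = np.empty(len(df))
        for i, tup in enumerate(map(tuple, rows.to_numpy())):
            if tup not in cache:
                cache[tup] = predict_exacerbation_risk(
                    net, dict(zip(parents, tup))).p_ge1
            preds[i] = cache[tup]
        emp = (df.future_exac >= 1).mean()
        assert abs(preds.mean() - emp) < 0.02

    def test_unknown_evidence_level_names_node(self, core9):
        net = bayesnet_from_spec(core9)
        with pytest.raises(KeyError, match="crs"):
            predict_exacerbation_risk(net, {"crs": "huh"})


class TestCounterfactualCompare:
    def test_monotone_over_crs_levels(self, core9):
        net = bayesnet_from_spec(core9)
        cf = counterfactual_compare(net, "crs", ["None", "CRSwoNP", "CRSwNP"])
        assert cf.p_ge1.is_monotonic_increasing
        assert cf.delta_p_ge1.iloc[0] == 0.0

    def test_repeated_level_zero_delta(self, core9):
        net = bayesnet_from_spec(core9)
        cf = counterfactual_compare(net, "crs", ["None", "None"])
        assert cf.delta_p_ge1.abs().max() == 0.0

    def test_sink_node_interventions_are_inert(self, core9):
        net = bayesnet_from_spec(core9)
        cf = counterfactual_compare(net, "ige", ["<150", ">=600"],
                                    target="future_exac")
        assert cf.delta_p_ge1.abs().max() < 1e-12


class TestInfluenceDiagram:
    def _one_chance(self):
        dag = NetworkStructure(("S",))
        return DiscreteBayesNet(dag, {"S": ["good", "mid", "bad"]},
                                {"S": np.array([0.7, 0.2, 0.1])})

    def test_no_decision_expected_utility(self):
        diag = InfluenceDiagram(
            self._one_chance(), [],
            [UtilityNode("u", ("S",), np.array([1.0, 0.5, 0.0]))])
        eu, _ = evaluate_influence_diagram(diag, "optimal")
        assert eu == pytest.approx(0.80)

    def test_dominant_action_chosen(self):
        treat = DecisionNode("treat", ("no", "yes"))
        table = np.array([[0.0, -1.0], [0.5, -0.2]])  # yes dominates state-wise
        diag = InfluenceDiagram(
            self._one_chance_binary(), [treat],
            [UtilityNode("u", ("treat", "S"), table)])
        eu, policy = evaluate_influence_diagram(diag, "optimal")
        assert policy["treat"] == {0: 1}

    def _one_chance_binary(self):
        dag = NetworkStructure(("S",))
        return DiscreteBayesNet(dag, {"S": ["ok", "exac"]},
                                {"S": np.array([0.8, 0.2])})

    def test_optimal_matches_policy_enumeration(self, rng):
        # small random diagram: optimal == max over explicitly scored policies
        net = random_discrete_net(rng, max_nodes=3)
        first = list(net.dag.nodes)[0]
        d = DecisionNode("act", ("a", "b", "c"), observes=(first,))
        table = rng.normal(size=(3, len(net.levels[first])))
        diag = InfluenceDiagram(net, [d],
                                [UtilityNode("u", ("act", first), table)])
        eu, _ = evaluate_influence_diagram(diag, "optimal")
        from exacbn.influence import _policies, _policy_value
        brute = max(_policy_value(diag, p) for p in _policies(diag))
        assert eu == pytest.approx(brute, abs=1e-12)

    def test_incomplete_policy_rejected(self):
        treat = DecisionNode("treat", ("no", "yes"), observes=("S",))
        diag = InfluenceDiagram(
            self._one_chance_binary(), [treat],
            [UtilityNode("u", ("treat", "S"), np.zeros((2, 2)))])
        with pytest.raises(KeyError):
            evaluate_influence_diagram(diag, {"treat": {0: 1}})
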