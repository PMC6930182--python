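import numpy as np
import pytest

from allonet.simstudy import (
    HUB_NODE,
    TRUE_EDGES,
    EvalMetrics,
    SimScenario,
    build_true_network,
    evaluate_network,
    run_scenarios,
    simulate_network_data,
    solve_true_system,
    true_components,
)


@pytest.fixture(scope="module")
def spec():
    return build_true_network()


class TestTrueNetwork:
    def test_topology(self, spec):
        assert len(spec.nodes) == 14
        assert len(spec.edges) == 18
        assert all(dst != HUB_NODE for _, dst in spec.edges)  # hub in-degree 0
        out_deg = sum(1 for src, _ in spec.edges if src == HUB_NODE)
        assert out_deg == 9

    def test_edges_into_hub_rejected(self):
        bad = list(TRUE_EDGES) + [("Q1", "Q2")]
        with pytest.raises(ValueError):
            build_true_network(edges=bad)

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError):
            build_true_network(edges=[("Q1", "Q1")])

    def test_same_seed_same_parameters(self):
        a = build_true_network(seed=3)
        b = build_true_network(seed=3)
        assert a.beta == b.beta and a.alpha == b.alpha

    def test_component_truth_additivity(self, spec):
        T = 20
        t, Q = solve_true_system(spec, T=T)
        ind, dep = true_components(spec, T)
        for i, n in enumerate(spec.nodes):
            total = Q[i, 0] + ind[n] + sum(d for (s, dst), d in dep.items() if dst == n)
            assert np.max(np.abs(total - Q[i])) < 5e-3  # quadrature tolerance


class TestSimulation:
    def test_zero_noise_returns_exact_solution(self, spec):
        scen = SimScenario(T=15, nu2=0.0)
        curves, truth = simulate_network_data(spec, scen)
        for c, tr in zip(curves, truth):
            assert np.array_equal(c.values, tr.values)

    def test_output_dimensions(self, spec):
        scen = SimScenario(T=12, nu2=0.1)
        curves, truth = simulate_network_data(spec, scen,
                                              rng=np.random.default_rng(0))
        assert len(curves) == 14
        assert all(len(c.values) == 12 for c in curves)

    def test_residual_variance_matches_nu2(self, spec):
        scen = SimScenario(T=10, nu2=0.2)
        devs = []
        rng = np.random.default_rng(1)
        for _ in range(200):
            curves, truth = simulate_network_data(spec, scen, rng=rng)
            devs.append(np.concatenate(
                [c.values - tr.values for c, tr in zip(curves, truth)]))
        var = np.var(np.concatenate(devs))
        assert abs(var - 0.2) / 0.2 < 0.1


class TestEvaluation:
    def test_perfect_inference(self, spec):
        m = evaluate_network(set(spec.edges), spec)
        assert (m.TP, m.FP, m.TPR, m.FPR) == (18, 0, 1.0, 0.0)

    def test_empty_inference(self, spec):
        m = evaluate_network(set(), spec)
        assert (m.TP, m.TPR, m.FPR) == (0, 0.0, 0.0)

    def test_random_scores_give_chance_auc(self, spec):
        rng = np.random.default_rng(0)
        aucs = []
        pairs = [(a, b) for a in spec.nodes for b in spec.nodes if a != b]
        for _ in range(100):
            scores = {p: rng.random() for p in pairs}
            aucs.append(evaluate_network(set(), spec, score_curve=scores).AUC)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_foreign_edge_rejected(self, spec):
        with pytest.raises(ValueError):
            evaluate_network({("Q99", "Q1")}, spec)

    def test_metric_bounds_enforced(self):
        with pytest.raises(ValueError):
            EvalMetrics(TP=1, FP=1, TPR=1.5, FPR=0.0, AUC=0.5)


class TestScenarios:
    def test_report_shape_and_determinism(self, spec):
        t1 = run_scenarios(spec, replicates=2, seed=9)
        t2 = run_scenarios(spec, replicates=2, seed=9)
        assert t1.shape[0] == 4
        assert set(zip(t1["nu2"], t1["T"])) == {(0.05, 10), (0.5, 10),
                                                (0.05, 30), (0.5, 30)}
        assert t1.equals(t2)

    def test_replicates_floor(self, spec):
        with pytest.raises(ValueError):
            run_scenarios(spec, replicates=1, seed=0)

    def test_metric_bounds_in_report(self, spec):
        t = run_scenarios(spec, replicates=2, seed=4)
        assert ((t["TPR"] >= 0) & (t["TPR"] <= 1)).all()
        assert ((t["FPR"] >= 0) & (t["FPR"] <= 1)).all()
        assert (t["TP"] <= 18).all()
        assert (t["FP"] <= 164).all()
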