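import numpy as np
import pytest

from allonet.funmap import EffectCurve
from allonet.netode import (
    NetworkEdge,
    NetworkNode,
    QTLNetwork,
    classify_interactions,
    decompose_effects,
    detect_hubs,
    export_network,
    fit_qdode,
    group_lasso_path,
    infer_network,
    read_network,
    select_regulators,
)


def _curve(name, t, v):
    return EffectCurve(name, "piQTL", t, t, np.asarray(v, float))


class TestSelection:
    def test_planted_regulator_found(self, effect_curve_trio):
        A, B, C = effect_curve_trio
        assert select_regulators(A, [B, C], smooth=False) == ["B"]

    def test_infinite_penalty_shrinks_everything(self, effect_curve_trio):
        A, B, C = effect_curve_trio
        assert select_regulators(A, [B, C], lam=1e9, smooth=False) == []

    def test_constant_zero_candidates_never_selected(self, effect_curve_trio):
        A, _, _ = effect_curve_trio
        t = np.asarray(A.grid)
        z = _curve("Z", t, np.zeros_like(t))
        assert select_regulators(A, [z], smooth=False) == []

    def test_flat_focal_returns_empty(self, effect_curve_trio):
        _, B, C = effect_curve_trio
        t = np.asarray(B.grid)
        flat = _curve("F", t, np.ones_like(t))
        assert select_regulators(flat, [B, C], smooth=False) == []

    def test_grid_mismatch_rejected(self, effect_curve_trio):
        A, B, _ = effect_curve_trio
        other = _curve("X", np.linspace(0, 5, 12), np.ones(12))
        with pytest.raises(ValueError):
            select_regulators(A, [other], smooth=False)

    def test_lasso_sparsity_monotone_in_lambda(self, effect_curve_trio):
        A, B, C = effect_curve_trio
        lambdas, norms, _ = group_lasso_path(A, [B, C], r=2, smooth=False)
        active = (norms > 1e-6).sum(axis=1)
        # lambdas descend, so the active count must be non-decreasing
        assert np.all(np.diff(active) >= 0)


class TestODEFit:
    def test_exponential_oracle(self):
        # dP/dt = 0.3 P has closed form P0 exp(0.3 t)
        t = np.linspace(0.0, 5.0, 30)
        P = 0.8 * np.exp(0.3 * t)
        focal = _curve("A", t, P)
        fits = fit_qdode([focal], {"A": []}, basis_order=2, smooth=False)
        ind, dep, tot = decompose_effects(fits["A"], [focal])
        assert np.max(np.abs(tot - P)) < 1e-4
        assert dep == {}
        # linear rate recovered: U(P) ~= 0.3 P over the observed range
        from numpy.polynomial import legendre
        lo, hi = fits["A"].self_range
        grid = np.linspace(lo, hi, 50)
        u = 2 * (grid - lo) / (hi - lo) - 1
        rate = legendre.legval(u, fits["A"].phi_self)
        assert np.max(np.abs(rate - 0.3 * grid)) / (0.3 * hi) < 0.01

    def test_all_zero_curves_give_zero_fit(self):
        t = np.linspace(0, 5, 20)
        z1, z2 = _curve("A", t, np.zeros(20)), _curve("B", t, np.zeros(20))
        fits = fit_qdode([z1, z2], {"A": ["B"]}, basis_order=2, smooth=False)
        assert fits["A"].objective == 0.0
        assert np.allclose(fits["A"].phi_self, 0) and np.allclose(fits["A"].phi_dep["B"], 0)

    def test_planted_regulator_component_recovered(self, effect_curve_trio):
        A, B, C = effect_curve_trio
        fits = fit_qdode([A, B], {"A": ["B"]}, basis_order=2, smooth=False)
        ind, dep, tot = decompose_effects(fits["A"], [A, B])
        true_dep = np.asarray(A.values) - A.values[0]  # A is purely B-driven
        assert np.corrcoef(dep["B"], true_dep)[0, 1] > 0.99
        assert np.max(np.abs(tot - A.values)) < 1e-3

    def test_unknown_focal_rejected(self, effect_curve_trio):
        A, B, _ = effect_curve_trio
        with pytest.raises(ValueError):
            fit_qdode([A, B], {"nope": []})


class TestDecomposition:
    def test_additivity_identity(self, effect_curve_trio):
        A, B, C = effect_curve_trio
        fits = fit_qdode([A, B, C], {"A": ["B", "C"]}, basis_order=2, smooth=False)
        ind, dep, tot = decompose_effects(fits["A"], [A, B, C])
        recon = A.values[0] + ind + sum(dep.values())
        assert np.max(np.abs(recon - tot)) < 1e-8

    def test_no_regulators_dependent_map_empty(self):
        t = np.linspace(0, 5, 20)
        P = _curve("A", t, 1 + 0.1 * t**2)
        fits = fit_qdode([P], {"A": []}, basis_order=2, smooth=False)
        ind, dep, tot = decompose_effects(fits["A"], [P])
        assert dep == {}
        assert np.allclose(ind, tot - P.values[0], atol=1e-12)

    def test_rk4_step_halving_stable(self, effect_curve_trio):
        A, B, _ = effect_curve_trio
        fits = fit_qdode([A, B], {"A": ["B"]}, basis_order=2, smooth=False, n_sub=4)
        _, _, tot4 = decompose_effects(fits["A"], [A, B], n_sub=4)
        _, _, tot8 = decompose_effects(fits["A"], [A, B], n_sub=8)
        assert np.max(np.abs(tot4 - tot8)) < 1e-6


class TestInteractionsAndHubs:
    def test_classification_table(self):
        nodes = [NetworkNode(id=i) for i in ("A", "B", "C")]
        edges = [NetworkEdge("A", "B", sign=1, weight=0.3),
                 NetworkEdge("A", "C", sign=1, weight=0.2),
                 NetworkEdge("C", "A", sign=-1, weight=0.1)]
        net = QTLNetwork(nodes=nodes, edges=edges)
        labels = classify_interactions(net)
        assert labels[frozenset(("A", "B"))] == "directional positive epistasis"
        assert labels[frozenset(("B", "C"))] == "symbiosis"
        assert labels[frozenset(("A", "C"))] == "altruistic or repressive epistasis"

    def test_mutual_signs(self):
        nodes = [NetworkNode(id=i) for i in ("A", "B")]
        plus = QTLNetwork(nodes=nodes, edges=[NetworkEdge("A", "B", 1, 1.0),
                                              NetworkEdge("B", "A", 1, 1.0)])
        minus = QTLNetwork(nodes=nodes, edges=[NetworkEdge("A", "B", -1, 1.0),
                                               NetworkEdge("B", "A", -1, 1.0)])
        assert classify_interactions(plus)[frozenset(("A", "B"))] == \
            "symmetric positive epistasis"
        assert classify_interactions(minus)[frozenset(("A", "B"))] == \
            "negative epistasis"

    def test_star_graph_center_is_unique_hub(self):
        nodes = [NetworkNode(id=i) for i in ("hub", "a", "b", "c", "d")]
        edges = [NetworkEdge("hub", leaf, 1, 1.0) for leaf in ("a", "b", "c", "d")]
        net = QTLNetwork(nodes=nodes, edges=edges)
        assert detect_hubs(net) == ["hub"]

    def test_edgeless_network_has_no_hubs(self):
        net = QTLNetwork(nodes=[NetworkNode(id="A"), NetworkNode(id="B")], edges=[])
        assert detect_hubs(net) == []

    def test_self_edges_forbidden(self):
        with pytest.raises(ValueError):
            QTLNetwork(nodes=[NetworkNode(id="A")],
                       edges=[NetworkEdge("A", "A", 1, 1.0)])


class TestExport:
    def test_tsv_round_trip(self, tmp_path, effect_curve_trio):
        A, B, C = effect_curve_trio
        net = infer_network([A, B, C], smooth=False)
        path = tmp_path / "edges.tsv"
        export_network(net, path)
        back = read_network(path, nodes=[n.id for n in net.nodes])
        assert len(back.edges) == len(net.edges)
        for e1, e2 in zip(net.edges, back.edges):
            assert (e1.src, e1.dst, e1.sign) == (e2.src, e2.dst, e2.sign)
            assert abs(e1.weight - e2.weight) < 1e-12

    def test_empty_network_header_only(self, tmp_path):
        net = QTLNetwork(nodes=[NetworkNode(id="A")], edges=[])
        path = tmp_path / "empty.tsv"
        export_network(net, path)
        lines = path.read_text().splitlines()
        assert lines == ["from\tto\tsign\tweight\tpair_type"]

    def test_unknown_format_lists_supported(self, tmp_path):
        net = QTLNetwork(nodes=[NetworkNode(id="A")], edges=[])
        with pytest.raises(ValueError, match="tsv"):
            export_network(net, tmp_path / "x", fmt="xml")

    def test_graphml_and_dot_writable(self, tmp_path, effect_curve_trio):
        A, B, C = effect_curve_trio
        net = infer_network([A, B, C], smooth=False)
        export_network(net, tmp_path / "n.graphml", fmt="graphml")
        export_network(net, tmp_path / "n.dot", fmt="dot")
        assert (tmp_path / "n.graphml").stat().st_size > 0
        assert "digraph" in (tmp_path / "n.dot").read_text()
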