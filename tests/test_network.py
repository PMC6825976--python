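import numpy as np
import pytest

from regmaster.io import ExpressionMatrix
from regmaster.network import (Edge, TranscriptionalNetwork, apply_dpi,
                               assign_modes, auto_bins, infer_edges,
                               mutual_information)


class TestMutualInformation:
    def test_self_information_dominates_shuffles(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        mi_self = mutual_information(x, x)
        beaten = sum(
            mutual_information(x, rng.permutation(x)) < mi_self
            for _ in range(100))
        assert beaten >= 99

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(1)
        for rho in (0.5, 0.8, 0.95):
            x = rng.normal(size=1000)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=1000)
            closed = -0.5 * np.log(1 - rho**2)
            assert mutual_information(x, y) == pytest.approx(closed, rel=0.15)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(2)
        small = sum(
            mutual_information(rng.normal(size=1000), rng.normal(size=1000))
            < 0.05
            for _ in range(100))
        assert small >= 95

    def test_constant_vector_returns_zero(self):
        assert mutual_information(np.ones(50), np.arange(50.0)) == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            mutual_information(np.arange(5.0), np.arange(5.0))

    def test_auto_bins_clamped(self):
        assert auto_bins(10) == 2
        assert auto_bins(300) == 7
        assert auto_bins(10000) == 16


def _benchmark_expr(seed=0, n=120, n_tfs=4, n_targets=6, n_bg=40,
                    noise=0.5):
    rng = np.random.default_rng(seed)
    genes, rows, planted = [], [], set()
    tfs = [f"TF{i}" for i in range(n_tfs)]
    for i, tf in enumerate(tfs):
        act = rng.normal(size=n)
        genes.append(tf)
        rows.append(act)
        for j in range(n_targets):
            sign = -1 if (i + j) % 3 == 0 else 1
            genes.append(f"T{i}_{j}")
            rows.append(sign * act + rng.normal(0, noise, n))
            planted.add((tf, f"T{i}_{j}", sign))
    for b in range(n_bg):
        genes.append(f"BG{b}")
        rows.append(rng.normal(size=n))
    expr = ExpressionMatrix(genes, [f"S{i:03d}" for i in range(n)],
                            np.vstack(rows))
    return expr, tfs, planted


class TestInferEdges:
    def test_planted_edges_recovered_background_rejected(self):
        expr, tfs, planted = _benchmark_expr()
        net = infer_edges(expr, tfs, n_perm=300, null_pairs_per_perm=400,
                          seed=5)
        edges = net.edge_set()
        pairs = {(tf, g) for tf, g, _ in planted}
        assert len(edges & pairs) / len(pairs) >= 0.95
        bg_hits = [e for e in edges if e[1].startswith("BG")]
        assert len(bg_hits) <= 2

    def test_zero_permutations_rejected(self):
        expr, tfs, _ = _benchmark_expr()
        with pytest.raises(ValueError, match="n_perm"):
            infer_edges(expr, tfs, n_perm=0)

    def test_support_threshold_monotone(self):
        expr, tfs, _ = _benchmark_expr(seed=3)
        strict = infer_edges(expr, tfs, n_perm=200, support_min=1.0, seed=7)
        loose = infer_edges(expr, tfs, n_perm=200, support_min=0.95, seed=7)
        assert strict.edge_set() <= loose.edge_set()

    def test_sample_order_invariance(self):
        expr, tfs, _ = _benchmark_expr(seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(expr.sample_ids))
        shuffled = ExpressionMatrix(
            expr.gene_ids, [expr.sample_ids[i] for i in perm],
            expr.values[:, perm])
        a = infer_edges(expr, tfs, n_perm=200, seed=9)
        b = infer_edges(shuffled, tfs, n_perm=200, seed=9)
        assert a.edge_set() == b.edge_set()


class TestDPI:
    def test_weakest_triangle_edge_removed(self):
        net = TranscriptionalNetwork(
            ["TF1", "TF2"],
            [Edge("TF1", "TF2", 0.9), Edge("TF2", "g", 0.8),
             Edge("TF1", "g", 0.3)])
        pruned = apply_dpi(net)
        assert pruned.edge_set() == {("TF1", "TF2"), ("TF2", "g")}

    def test_full_tolerance_removes_nothing(self):
        net = TranscriptionalNetwork(
            ["TF1", "TF2"],
            [Edge("TF1", "TF2", 0.9), Edge("TF2", "g", 0.8),
             Edge("TF1", "g", 0.3)])
        assert apply_dpi(net, tolerance=1.0).edge_set() == net.edge_set()

    def test_negative_tolerance_rejected(self):
        net = TranscriptionalNetwork(["TF1"], [])
        with pytest.raises(ValueError):
            apply_dpi(net, tolerance=-0.1)

    def test_dpi_only_removes_edges(self):
        expr, tfs, _ = _benchmark_expr(seed=6)
        net = infer_edges(expr, tfs, n_perm=200, seed=2)
        pruned = apply_dpi(net)
        assert pruned.edge_set() <= net.edge_set()
        mi_before = {(e.tf, e.target): e.mi for e in net.edges}
        for e in pruned.edges:
            assert e.mi == mi_before[(e.tf, e.target)]

    def test_tie_between_two_weakest_keeps_both(self):
        net = TranscriptionalNetwork(
            ["TF1", "TF2"],
            [Edge("TF1", "TF2", 0.9), Edge("TF2", "g", 0.3),
             Edge("TF1", "g", 0.3)])
        assert apply_dpi(net).edge_set() == net.edge_set()


class TestAssignModes:
    def test_modes_match_planted_signs(self):
        expr, tfs, planted = _benchmark_expr(seed=8)
        net = infer_edges(expr, tfs, n_perm=200, seed=3)
        regulons = {r.tf_id: r for r in assign_modes(net, expr)}
        checked = correct = 0
        for tf, g, sign in planted:
            if tf in regulons and g in regulons[tf].members:
                checked += 1
                correct += regulons[tf].members[g] == sign
        assert checked > 0
        assert correct / checked >= 0.98

    def test_anticorrelated_pair_gets_negative_mode(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        expr = ExpressionMatrix(["TF1", "g"], [f"S{i}" for i in range(50)],
                                np.vstack([x, -x]))
        net = TranscriptionalNetwork(["TF1"], [Edge("TF1", "g", 0.5)])
        regs = assign_modes(net, expr)
        assert regs[0].members == {"g": -1}

    def test_tf_without_targets_emits_no_regulon(self):
        rng = np.random.default_rng(0)
        expr = ExpressionMatrix(
            ["TF1", "TF2", "g"], [f"S{i}" for i in range(30)],
            rng.normal(size=(3, 30)))
        net = TranscriptionalNetwork(["TF1", "TF2"],
                                     [Edge("TF1", "g", 0.4)])
        regs = assign_modes(net, expr)
        assert [r.tf_id for r in regs] == ["TF1"]


def test_edge_invariants():
    with pytest.raises(ValueError, match="self-edges"):
        Edge("A", "A", 0.1)
    with pytest.raises(ValueError, match="MI"):
        Edge("A", "B", -0.1)
    with pytest.raises(ValueError, match="support"):
        Edge("A", "B", 0.1, support=1.5)
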