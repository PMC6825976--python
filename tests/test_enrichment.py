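import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import ks_running_sum_oracle
from regmaster.enrichment import (gsea2_study, gsea_es, gsva_scores,
                                  two_tailed_gsea)
from regmaster.io import ExpressionMatrix
from regmaster.network import Regulon
from regmaster.synthetic import (SimParams, generate_case_control,
                                 generate_reference_cohort)
from regmaster.diffexp import fit_differential


class TestGseaES:
    def test_exhaustive_small_instances_match_oracle(self):
        """Every non-empty subset at N<=10 against the literal running sum."""
        rng = np.random.default_rng(0)
        for n in (4, 7, 10):
            ranking = [f"G{i}" for i in range(n)]
            metric = np.sort(rng.normal(size=n))[::-1]
            for r in range(1, n + 1):
                for combo in itertools.combinations(range(n), r):
                    es = gsea_es(ranking, metric, {f"G{i}" for i in combo})
                    w = np.abs(metric[list(combo)])
                    if w.sum() == 0:
                        w = np.ones(len(combo))
                    _, _, expected = ks_running_sum_oracle(n, combo, w)
                    assert es == pytest.approx(expected, abs=1e-12)

    def test_random_large_instances_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(50, 500))
            ranking = [f"G{i}" for i in range(n)]
            metric = np.sort(rng.normal(size=n))[::-1]
            size = int(rng.integers(1, n))
            pos = rng.choice(n, size, replace=False)
            es = gsea_es(ranking, metric, {f"G{i}" for i in pos})
            _, _, expected = ks_running_sum_oracle(
                n, sorted(pos), np.abs(metric[np.sort(pos)]))
            assert es == pytest.approx(expected, abs=1e-12)

    def test_top_gene_unweighted(self):
        ranking = [f"G{i}" for i in range(20)]
        es = gsea_es(ranking, None, {"G0"}, weight_exp=0)
        assert es == pytest.approx(1.0)

    def test_whole_ranking_set_gives_one(self):
        ranking = [f"G{i}" for i in range(15)]
        metric = np.linspace(3, -3, 15)
        assert gsea_es(ranking, metric, set(ranking)) == pytest.approx(1.0)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            gsea_es(["A", "B"], np.array([1.0, 0.5]), {"Z"})


def _deg_table(metric: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame({"logFC": pd.Series(metric),
                         "t": pd.Series(metric)})


class TestTwoTailedGsea:
    def test_metric_negation_flips_des_exactly(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(100)]
        metric = dict(zip(genes, rng.normal(size=100)))
        reg = Regulon("R", {g: (1 if i % 3 else -1)
                            for i, g in enumerate(genes[:20])})
        a = two_tailed_gsea(reg, _deg_table(metric), n_perm=50, seed=1)
        b = two_tailed_gsea(
            reg, _deg_table({g: -v for g, v in metric.items()}),
            n_perm=50, seed=1)
        assert a.des == pytest.approx(-b.des, abs=1e-12)

    def test_single_mode_regulon_flagged(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(50)]
        metric = dict(zip(genes, rng.normal(size=50)))
        reg = Regulon("R", {g: 1 for g in genes[:10]})
        res = two_tailed_gsea(reg, _deg_table(metric), n_perm=50, seed=1)
        assert res.one_sided_subset
        assert res.des == res.es_a

    def test_planted_activated_regulon_detected(self):
        detected = 0
        n_seeds = 10
        for s in range(n_seeds):
            p = SimParams(n_tfs=6, targets_per_tf=20,
                          n_background_genes=400, n_studies=1,
                          n_disease_mrs=2, seed=700 + s)
            _, truth = generate_reference_cohort(p)
            table = fit_differential(generate_case_control(p, truth)[0])
            regs = [Regulon(tf, {t.gene: t.sign
                                 for t in truth.planted_regulons[tf]})
                    for tf in truth.tf_ids]
            out = gsea2_study(regs, table, n_perm=500, seed=s).set_index(
                "regulon")
            ok = True
            for tf, direction in truth.disease_mrs.items():
                expected = "activated" if direction > 0 else "repressed"
                ok &= out.loc[tf, "call"] == expected
            detected += ok
        assert detected >= 0.9 * n_seeds

    def test_same_seed_reproduces_p(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(80)]
        metric = dict(zip(genes, rng.normal(size=80)))
        reg = Regulon("R", {g: (1 if i % 2 else -1)
                            for i, g in enumerate(genes[:16])})
        a = two_tailed_gsea(reg, _deg_table(metric), n_perm=200, seed=9)
        b = two_tailed_gsea(reg, _deg_table(metric), n_perm=200, seed=9)
        assert a.p == b.p


def _expr_matrix(values, prefix="S"):
    return ExpressionMatrix(
        [f"G{i}" for i in range(values.shape[0])],
        [f"{prefix}{j}" for j in range(values.shape[1])], values)


class TestGsva:
    def test_sample_permutation_permutes_columns_bit_exactly(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(60, 30))
        regs = [Regulon("R", {f"G{i}": 1 for i in range(10)})]
        base = gsva_scores(_expr_matrix(vals), regs)
        perm = rng.permutation(30)
        expr2 = ExpressionMatrix(
            [f"G{i}" for i in range(60)], [f"S{j}" for j in perm],
            vals[:, perm])
        shuffled = gsva_scores(expr2, regs)
        np.testing.assert_array_equal(
            base.loc["R", [f"S{j}" for j in perm]].to_numpy(),
            shuffled.loc["R"].to_numpy())

    def test_raising_regulon_expression_raises_score(self):
        for s in range(10):
            rng = np.random.default_rng(40 + s)
            vals = rng.normal(size=(80, 25))
            regs = [Regulon("R", {f"G{i}": 1 for i in range(12)})]
            base = gsva_scores(_expr_matrix(vals), regs)
            bumped = vals.copy()
            bumped[:12, 0] += 2.0 * vals.std()
            up = gsva_scores(_expr_matrix(bumped), regs)
            assert up.loc["R", "S0"] > base.loc["R", "S0"]

    def test_background_regulon_scores_centred(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(300, 200))
        regs = [Regulon(f"R{k}", {f"G{i}": 1
                                  for i in rng.choice(300, 20, replace=False)})
                for k in range(10)]
        scores = gsva_scores(_expr_matrix(vals), regs)
        assert abs(scores.mean(axis=1)).max() < 0.05

    def test_small_regulon_skipped(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(20, 15))
        regs = [Regulon("TINY", {"G0": 1}),
                Regulon("OK", {f"G{i}": 1 for i in range(5)})]
        scores = gsva_scores(_expr_matrix(vals), regs)
        assert list(scores.index) == ["OK"]

    def test_signed_diff_mode_flips_with_modes(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(50, 20))
        pos = Regulon("R", {f"G{i}": 1 for i in range(8)})
        neg = Regulon("R", {f"G{i}": -1 for i in range(8)})
        expr = _expr_matrix(vals)
        a = gsva_scores(expr, [pos], mode_handling="signed_diff")
        b = gsva_scores(expr, [neg], mode_handling="signed_diff")
        np.testing.assert_allclose(a.loc["R"], -b.loc["R"], atol=1e-12)

    def test_too_few_samples_rejected(self):
        vals = np.random.default_rng(9).normal(size=(20, 5))
        with pytest.raises(ValueError, match="10 samples"):
            gsva_scores(_expr_matrix(vals),
                        [Regulon("R", {"G0": 1, "G1": 1})])
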