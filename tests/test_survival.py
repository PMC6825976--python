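import numpy as np
import pandas as pd
import pytest

from conftest import logrank_two_sample_oracle
from regmaster.survival import (CoxResult, fit_cox_regulon, km_logrank,
                                merge_and_discretize, per_gene_cox,
                                survival_consensus)
from regmaster.synthetic import SimParams, generate_reference_cohort, \
    generate_survival_cohort


def _cohort(seed=0, beta=0.7, n=300):
    p = SimParams(n_tfs=3, targets_per_tf=5, n_background_genes=20,
                  n_survival_mrs=1, n_disease_mrs=1, hazard_beta=beta,
                  n_survival_samples=n, seed=seed)
    _, truth = generate_reference_cohort(p)
    expr, clin = generate_survival_cohort(p, truth)
    tf = next(iter(truth.survival_mrs))
    return expr, clin, tf, truth


class TestCox:
    def test_null_activity_ci_covers_one(self):
        covered = 0
        n_reps = 40
        for s in range(n_reps):
            expr, clin, tf, _ = _cohort(seed=100 + s, beta=0.0, n=150)
            z = pd.Series(expr.row(tf), index=expr.sample_ids)
            res = fit_cox_regulon(z, clin, ["stage", "age"], unit=tf)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 0.85 * n_reps  # ~95% nominal coverage

    def test_planted_effect_recovered(self):
        expr, clin, tf, _ = _cohort(seed=5)
        z = pd.Series(expr.row(tf), index=expr.sample_ids)
        res = fit_cox_regulon(z, clin, ["stage", "age"], unit=tf)
        assert res.coef == pytest.approx(0.7, abs=0.25)
        assert res.hr == pytest.approx(np.exp(res.coef))
        assert res.ci_low <= res.hr <= res.ci_high

    def test_too_few_events_rejected(self):
        expr, clin, tf, _ = _cohort(seed=6, n=300)
        clin = clin.iloc[:12]
        z = pd.Series(expr.row(tf), index=expr.sample_ids)[:12]
        clin = clin.assign(event=[1] * 5 + [0] * 7)
        with pytest.raises(ValueError, match="events"):
            fit_cox_regulon(z, clin, [], unit=tf)


def _cox_result(unit, study, coef, p, converged=True):
    return CoxResult(study, unit, coef, np.exp(coef), 0, 0, p, 50,
                     converged=converged)


class TestSurvivalConsensus:
    def test_half_of_studies_consistent_direction(self):
        res = [_cox_result("R", f"S{i}", 0.5, 0.01) for i in range(5)]
        res += [_cox_result("R", f"S{i}", 0.1, 0.5) for i in range(5, 10)]
        out = survival_consensus(res)
        assert bool(out.loc["R", "consensus"])
        assert out.loc["R", "hr_direction"] == "risk"

    def test_sign_disagreement_blocks_consensus(self):
        coefs = [0.5, 0.6, 0.4, -0.5, -0.3]
        res = [_cox_result("R", f"S{i}", c, 0.01)
               for i, c in enumerate(coefs)]
        res += [_cox_result("R", f"S{i}", 0.0, 0.9) for i in range(5, 10)]
        out = survival_consensus(res)
        assert out.loc["R", "hr_direction"] == "inconsistent"
        assert not bool(out.loc["R", "consensus"])

    def test_below_threshold_no_consensus(self):
        res = [_cox_result("R", f"S{i}", 0.5, 0.01) for i in range(4)]
        res += [_cox_result("R", f"S{i}", 0.1, 0.5) for i in range(4, 10)]
        assert not bool(survival_consensus(res).loc["R", "consensus"])

    def test_unconverged_fits_ignored(self):
        res = [_cox_result("R", f"S{i}", 0.5, 0.001, converged=(i > 4))
               for i in range(10)]
        out = survival_consensus(res)
        assert out.loc["R", "n_studies_significant"] == 5


class TestMergeAndDiscretize:
    def test_quantile_oracle_on_integer_sequence(self):
        scores = {
            "A": pd.Series(np.arange(1.0, 51), index=[f"a{i}" for i in range(50)]),
            "B": pd.Series(np.arange(51.0, 101), index=[f"b{i}" for i in range(50)]),
        }
        groups = merge_and_discretize(scores)
        merged = pd.concat([(s - s.mean()) / s.std(ddof=1)
                            for s in scores.values()])
        q1, q3 = np.quantile(merged, [0.25, 0.75])
        assert (groups == "low").sum() == int((merged < q1).sum())
        assert (groups == "high").sum() == int((merged > q3).sum())
        assert groups.value_counts().sum() == 100

    def test_merged_scores_standardized_per_study(self):
        rng = np.random.default_rng(0)
        scores = {f"S{k}": pd.Series(rng.normal(k, k + 1, 40),
                                     index=[f"s{k}_{i}" for i in range(40)])
                  for k in range(3)}
        groups = merge_and_discretize(scores)
        merged = groups.attrs["merged_scores"]
        for k in range(3):
            part = merged[[f"s{k}_{i}" for i in range(40)]]
            assert part.mean() == pytest.approx(0.0, abs=1e-10)
            assert part.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_group_sizes_near_quarters(self):
        rng = np.random.default_rng(1)
        scores = {f"S{k}": pd.Series(rng.normal(size=100),
                                     index=[f"s{k}_{i}" for i in range(100)])
                  for k in range(2)}
        counts = merge_and_discretize(scores).value_counts()
        assert abs(counts["low"] - 50) <= 1
        assert abs(counts["high"] - 50) <= 1

    def test_zero_variance_study_excluded(self):
        scores = {
            "A": pd.Series(np.ones(20), index=[f"a{i}" for i in range(20)]),
            "B": pd.Series(np.arange(20.0), index=[f"b{i}" for i in range(20)]),
            "C": pd.Series(np.arange(20.0), index=[f"c{i}" for i in range(20)]),
        }
        with pytest.warns(UserWarning, match="zero score variance"):
            groups = merge_and_discretize(scores)
        assert not any(i.startswith("a") for i in groups.index)


class TestKmLogrank:
    def test_matches_first_principles_logrank(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(20, 60))
            clin = pd.DataFrame({
                "sample_id": [f"s{i}" for i in range(n)],
                "time": rng.exponential(5, n).round(2) + 0.01,
                "event": rng.integers(0, 2, n),
            })
            if clin["event"].sum() < 2:
                continue
            groups = pd.Series(
                np.where(rng.random(n) < 0.5, "low", "high"),
                index=clin["sample_id"])
            if groups.nunique() < 2:
                continue
            _, chi2, p = km_logrank(groups, clin)
            expected = logrank_two_sample_oracle(
                clin["time"], clin["event"], groups.to_numpy())
            assert chi2 == pytest.approx(expected, abs=1e-8)

    def test_identical_groups_give_zero_statistic(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        clin = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(10)],
            "time": times * 2,
            "event": [1] * 10,
        })
        groups = pd.Series(["low"] * 5 + ["high"] * 5,
                           index=clin["sample_id"])
        _, chi2, p = km_logrank(groups, clin)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_group_with_zero_events_retained(self):
        clin = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(20)],
            "time": np.linspace(1, 10, 20),
            "event": [1] * 10 + [0] * 10,
        })
        groups = pd.Series(["low"] * 10 + ["high"] * 10,
                           index=clin["sample_id"])
        curves, chi2, p = km_logrank(groups, clin)
        assert set(curves) == {"low", "high"}
        assert np.isfinite(p)


def test_per_gene_cox_counts_and_flags():
    expr, clin, tf, truth = _cohort(seed=9)
    genes = [t.gene for t in truth.planted_regulons[tf]][:3]
    expr.values[expr.gene_ids.index(genes[2])] = 1.0  # constant gene
    fits, consensus = per_gene_cox(
        {"S1": expr, "S2": expr}, {"S1": clin, "S2": clin}, genes,
        covariates=["stage", "age"])
    assert set(fits["gene"]) == set(genes[:2])
    assert "flags" in fits.attrs
    assert consensus.loc[genes[0], "n_studies"] == 2
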