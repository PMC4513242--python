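"""Experiment protocol, performance metrics and group-level statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conntensor.data import CohortTensor
from conntensor.evaluate import (
    ExperimentConfig,
    bagged_fit,
    compare_methods_ttest,
    elementwise_ttest_map,
    ensemble_predict_proba,
    mcnemar_test,
    metric_group_tests,
    performance_metrics,
    run_experiment,
    standardize_columns,
    undersample,
)
from conntensor.logreg import fit_sparse_logreg
from conntensor.simulate import SyntheticSpec, generate_cohort
from conntensor.tensor import extract_hosvd


class TestStandardize:
    def test_training_columns_zero_mean_unit_sd(self, rng):
        train = rng.normal(loc=3.0, scale=2.0, size=(20, 4))
        tr, _, _, _ = standardize_columns(train)
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(tr.std(axis=0), 1.0, atol=1e-10)

    def test_constant_column_becomes_zero_in_both(self):
        train = np.column_stack([np.full(5, 7.0), np.arange(5.0)])
        test = np.column_stack([np.full(3, 7.0), np.arange(3.0)])
        tr, te, _, sds = standardize_columns(train, test)
        assert np.all(tr[:, 0] == 0.0) and np.all(te[:, 0] == 0.0)
        assert sds[0] == 0.0

    def test_matches_direct_mean_sd_oracle(self):
        train = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 60.0]])
        test = np.array([[2.0, 30.0]])
        tr, te, means, sds = standardize_columns(train, test)
        np.testing.assert_allclose(means, [2.0, 30.0])
        np.testing.assert_allclose(tr, (train - means) / train.std(axis=0))
        np.testing.assert_allclose(te, (test - means) / train.std(axis=0))


class TestUndersample:
    def test_minority_size_forces_draw(self, rng):
        y = np.array([1.0] * 39 + [-1.0] * 51)
        idx = undersample(y, 0)
        assert idx.size == 78
        assert np.sum(y[idx] > 0) == 39 and np.sum(y[idx] < 0) == 39

    def test_balanced_input_keeps_everything(self):
        y = np.array([1.0, -1.0] * 10)
        np.testing.assert_array_equal(undersample(y, 3), np.arange(20))

    def test_fixed_seed_identical_draw(self):
        y = np.array([1.0] * 10 + [-1.0] * 30)
        np.testing.assert_array_equal(undersample(y, 7), undersample(y, 7))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            undersample(np.ones(10), 0)


class TestBaggedFit:
    def test_single_bag_equals_single_undersampled_fit(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.array([1.0] * 15 + [-1.0] * 25)
        models = bagged_fit(X, y, 0.05, n_bags=1, seed=9)
        idx = undersample(y, np.random.default_rng(9))
        direct = fit_sparse_logreg(X[idx], y[idx], 0.05)
        np.testing.assert_array_equal(models[0].w, direct.w)

    def test_balanced_data_all_bags_identical(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.array([1.0, -1.0] * 10)
        models = bagged_fit(X, y, 0.1, n_bags=5, seed=2)
        probs = ensemble_predict_proba(models, X)
        np.testing.assert_allclose(probs, models[0].predict_proba(X), atol=1e-12)

    def test_ensemble_beats_single_bag_on_average(self):
        """Averaging undersampled models reduces the variance introduced by
        discarding majority samples; over many draws the ensemble's test
        accuracy is at least the single bag's."""
        rng = np.random.default_rng(5)
        wins = []
        for _ in range(30):
            w_true = np.zeros(10)
            w_true[:3] = 1.0
            X = rng.normal(size=(90, 10))
            p = 1 / (1 + np.exp(-(X @ w_true - 0.5)))
            y = np.where(rng.random(90) < p, 1.0, -1.0)
            tr, te = np.arange(60), np.arange(60, 90)
            seed = int(rng.integers(2**31))
            ens = bagged_fit(X[tr], y[tr], 0.05, n_bags=11, seed=seed, tol=1e-6, max_iter=1000)
            one = ens[:1]
            for models in (ens, one):
                probs = ensemble_predict_proba(models, X[te])
                pred = np.where(probs >= 0.5, 1.0, -1.0)
                wins.append(np.mean(pred == y[te]))
        ens_acc = np.mean(wins[0::2])
        single_acc = np.mean(wins[1::2])
        assert ens_acc >= single_acc


class TestPerformanceMetrics:
    def test_perfect_predictions(self):
        truth = np.array([1.0, 1.0, -1.0, -1.0])
        probs = np.array([0.9, 0.8, 0.1, 0.2])
        pred = np.where(probs >= 0.5, 1.0, -1.0)
        assert performance_metrics(probs, pred, truth) == (1.0, 1.0, 1.0, 1.0)

    def test_constant_probabilities_auc_half_by_midranks(self):
        truth = np.array([1.0, 1.0, -1.0, -1.0])
        probs = np.full(4, 0.5)
        *_, auc = performance_metrics(probs, np.ones(4), truth)
        assert auc == 0.5

    def test_worked_six_sample_example(self):
        truth = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        probs = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
        pred = np.where(probs >= 0.5, 1.0, -1.0)
        acc, sens, spec, auc = performance_metrics(probs, pred, truth)
        assert acc == pytest.approx(4 / 6)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(2 / 3)
        # pair-counting oracle: 9 (pos, neg) pairs, 3 + 3 + 2 concordant
        assert auc == pytest.approx(8 / 9)

    def test_auc_matches_pair_counting_oracle(self, rng):
        truth = np.where(rng.random(30) < 0.4, 1.0, -1.0)
        truth[:2] = [1.0, -1.0]
        probs = np.round(rng.random(30), 1)  # coarse grid forces ties
        *_, auc = performance_metrics(probs, np.sign(probs - 0.5), truth)
        pos, neg = probs[truth > 0], probs[truth < 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_truth_flags_undefined(self):
        with pytest.warns(UserWarning, match="single-class"):
            acc, sens, spec, auc = performance_metrics(
                np.array([0.9, 0.2]), np.array([1.0, -1.0]), np.array([1.0, 1.0])
            )
        assert acc == 0.5
        assert np.isnan(sens) and np.isnan(spec) and np.isnan(auc)


class TestElementwiseTtests:
    def test_identical_groups_give_t_zero_p_one(self):
        from conntensor.data import PhenotypeRecord

        rng = np.random.default_rng(0)
        data = rng.normal(size=(8, 5, 5))
        data = (data + np.transpose(data, (0, 2, 1))) / 2
        for d in data:
            np.fill_diagonal(d, 0.0)
        phen = [
            PhenotypeRecord(f"S{i}", "AD" if i < 8 else "NC", 70.0, "F") for i in range(16)
        ]
        dup = CohortTensor(np.concatenate([data, data]), phen)
        t_map, p_map, mask, _ = elementwise_ttest_map(dup, "AD", "NC")
        np.testing.assert_allclose(t_map, 0.0, atol=1e-12)
        np.testing.assert_allclose(p_map, 1.0, atol=1e-12)
        assert not mask.any()

    def test_bonferroni_threshold_for_113_nodes(self):
        rng = np.random.default_rng(1)
        from conntensor.data import PhenotypeRecord

        data = rng.normal(size=(8, 113, 113))
        data = (data + np.transpose(data, (0, 2, 1))) / 2
        for d in data:
            np.fill_diagonal(d, 0.0)
        phen = [
            PhenotypeRecord(f"S{i}", "AD" if i < 4 else "NC", 70.0, "F") for i in range(8)
        ]
        *_, threshold = elementwise_ttest_map(CohortTensor(data, phen), "AD", "NC")
        assert threshold == pytest.approx(0.05 / 6328)
        assert f"{threshold:.1e}" == "7.9e-06"

    def test_single_edge_matches_direct_t_formula(self):
        from conntensor.data import PhenotypeRecord, matrix_from_upper_triangle

        a_vals, b_vals = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        data = np.stack(
            [matrix_from_upper_triangle(np.array([v]), 2) for v in a_vals + b_vals]
        )
        phen = [
            PhenotypeRecord(f"S{i}", "AD" if i < 3 else "NC", 70.0, "F") for i in range(6)
        ]
        t_map, p_map, _, _ = elementwise_ttest_map(CohortTensor(data, phen), "AD", "NC")
        t_oracle, p_oracle = stats.ttest_ind(a_vals, b_vals, equal_var=True)
        assert t_map[0, 1] == pytest.approx(t_oracle)
        assert p_map[0, 1] == pytest.approx(p_oracle)

    def test_symmetry_of_output_maps(self, two_group_cohort):
        cohort, _ = two_group_cohort
        t_map, p_map, mask, _ = elementwise_ttest_map(cohort, "AD", "NC")
        np.testing.assert_array_equal(t_map, t_map.T)
        np.testing.assert_array_equal(p_map, p_map.T)
        np.testing.assert_array_equal(mask, mask.T)


class TestMetricGroupTests:
    def test_threshold_is_one_percent_and_neg_log10_two(self, rng):
        table = rng.normal(size=(12, 5))
        labels = np.array(["AD"] * 6 + ["NC"] * 6)
        res = metric_group_tests(table, labels, ("AD", "NC"))
        assert res.attrs["threshold"] == pytest.approx(0.01)
        assert -np.log10(res.attrs["threshold"]) == pytest.approx(2.0)

    def test_identical_groups_p_one(self):
        table = np.tile(np.arange(5.0), (12, 1)) + np.tile(
            np.arange(6.0).repeat(2)[:, None], (1, 5)
        )
        labels = np.array(["AD", "NC"] * 6)
        res = metric_group_tests(table, labels, ("AD", "NC"))
        np.testing.assert_allclose(res["p"], 1.0)

    def test_named_columns_preserved(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 5)), columns=["MOD", "MCC", "CPL", "GLOB", "SW"])
        labels = np.array(["AD"] * 5 + ["NC"] * 5)
        res = metric_group_tests(df, labels, ("AD", "NC"))
        assert list(res.index) == ["MOD", "MCC", "CPL", "GLOB", "SW"]


class TestCompareMethods:
    def test_equal_vectors_give_half_by_convention(self):
        a = np.full(20, 0.7)
        assert compare_methods_ttest(a, a.copy()) == 0.5

    def test_constant_positive_difference_gives_zero(self):
        a = np.full(20, 0.8)
        assert compare_methods_ttest(a, a - 0.05) == 0.0
        assert compare_methods_ttest(a - 0.05, a) == 1.0

    def test_strong_consistent_improvement_is_significant(self, rng):
        b = 0.7 + rng.normal(scale=0.01, size=20)
        a = b + 0.05 + rng.normal(scale=0.01, size=20)
        assert compare_methods_ttest(a, b) < 0.001

    def test_null_calibration_uniform_p(self):
        """Mean-zero differences: one-sided p-values are uniform on (0,1)."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(400):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            pvals.append(compare_methods_ttest(a, b))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestMcnemar:
    def test_identical_predictions_p_one(self):
        preds = np.array([1.0, -1.0, 1.0])
        assert mcnemar_test(preds, preds.copy(), np.array([1.0, 1.0, -1.0])) == 1.0

    def test_one_sided_discordance_exact_binomial(self):
        truth = np.ones(10)
        preds_a = np.ones(10)  # all correct
        preds_b = -np.ones(10)  # all wrong: b=10, c=0
        p = mcnemar_test(preds_a, preds_b, truth)
        assert p == pytest.approx(2 * 0.5**10)

    def test_balanced_discordance_matches_binomial_summation(self):
        truth = np.ones(10)
        preds_a = np.array([1.0] * 5 + [-1.0] * 5)
        preds_b = np.array([-1.0] * 5 + [1.0] * 5)  # b = c = 5
        p = mcnemar_test(preds_a, preds_b, truth)
        oracle = min(1.0, 2 * stats.binom.cdf(5, 10, 0.5))
        assert p == pytest.approx(min(oracle, 1.0))

    def test_large_discordance_uses_chi_square(self):
        truth = np.ones(60)
        preds_a = np.concatenate([np.ones(40), -np.ones(20)])
        preds_b = np.concatenate([-np.ones(30), np.ones(10), -np.ones(10), np.ones(10)])
        # b = 30 (a right, b wrong), c = 10 (a wrong, b right)
        p = mcnemar_test(preds_a, preds_b, truth)
        chi2 = (abs(30 - 10) - 1) ** 2 / (30 + 10)
        assert p == pytest.approx(stats.chi2.sf(chi2, 1))


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def strong_cohort(self):
        spec = SyntheticSpec(
            n_per_group={"AD": 60, "NC": 60, "MCI": 1},
            p=30, base_rank=3, effect_edges=30, effect_size=2.0,
            effect_pattern="random", noise_sd=0.1, seed=21,
        )
        cohort, _ = generate_cohort(spec)
        return cohort

    def test_repeat_count_contract(self, strong_cohort):
        fm = extract_hosvd(strong_cohort, k=6)
        config = ExperimentConfig(
            comparison=("AD", "NC"), n_repeats=3, lambda_grid_size=4,
            master_seed=1, solver_tol=1e-5, solver_max_iter=500,
        )
        res = run_experiment(fm, strong_cohort.labels, config)
        assert len(res.per_repeat) == 3
        assert set(res.per_repeat.columns) == {"accuracy", "sensitivity", "specificity", "auc"}
        assert ((res.per_repeat >= 0) & (res.per_repeat <= 1)).all().all()

    def test_same_master_seed_bitwise_identical(self, strong_cohort):
        fm = extract_hosvd(strong_cohort, k=6)
        config = ExperimentConfig(
            comparison=("AD", "NC"), n_repeats=2, lambda_grid_size=4,
            master_seed=5, solver_tol=1e-5, solver_max_iter=500,
        )
        r1 = run_experiment(fm, strong_cohort.labels, config)
        r2 = run_experiment(fm, strong_cohort.labels, config)
        assert r1.to_json() == r2.to_json()

    def test_strong_signal_reaches_high_accuracy(self, strong_cohort):
        """Effect of 2 SD on 30 edges: the protocol should classify nearly
        perfectly (mean accuracy > 0.9).  Raw edge features suit this
        sparse planted contrast."""
        from conntensor.tensor import extract_raw

        fm = extract_raw(strong_cohort)
        config = ExperimentConfig(
            comparison=("AD", "NC"), n_repeats=5, lambda_grid_size=6,
            master_seed=3, solver_tol=1e-6, solver_max_iter=1000,
        )
        res = run_experiment(fm, strong_cohort.labels, config)
        assert res.mean["accuracy"] > 0.9

    def test_even_bag_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ExperimentConfig(n_bags=20)

    def test_positive_class_is_worse_diagnosis(self):
        assert ExperimentConfig(comparison=("NC", "AD")).positive_label == "AD"
        assert ExperimentConfig(comparison=("MCI", "NC")).positive_label == "MCI"
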