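"""AUC, selection metrics, signed-rank test, nested CV, and the benchmark."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erpselect.core_model import decision_values
from erpselect.evaluation import (
    DEFAULT_LAMBDA_GRID,
    SelectionResult,
    auc,
    f_measure,
    nested_cv_select,
    run_benchmark,
    selection_rate,
    wilcoxon_signed_rank,
)
from erpselect.synthetic_data import SimulationConfig, generate_simulated_p300

from oracles import exhaustive_wilcoxon, pair_counting_auc, random_trials


class TestAuc:
    def test_perfect_and_reversed_ordering(self):
        labels = np.array([-1, -1, 1, 1])
        assert auc([1, 2, 3, 4], labels) == 1.0
        assert auc([4, 3, 2, 1], labels) == 0.0

    def test_tied_pair_counts_half(self):
        assert auc([1, 2, 2, 3], [-1, -1, 1, 1]) == pytest.approx(0.875)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1.0, 2.0], [1, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_pair_counting(self, data):
        n = data.draw(st.integers(2, 30))
        labels = np.array(data.draw(
            st.lists(st.sampled_from([-1, 1]), min_size=n, max_size=n)))
        if len(set(labels)) < 2:
            labels[0], labels[1] = -1, 1
        scores = np.array(data.draw(
            st.lists(st.integers(-5, 5), min_size=n, max_size=n)), float)
        assert auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        for _ in range(30):
            scores = rng.standard_normal(20)
            labels = np.where(rng.random(20) < 0.5, 1, -1)
            labels[:2] = [1, -1]
            a = auc(scores, labels)
            assert auc(np.exp(3 * scores), labels) == pytest.approx(a, abs=1e-12)
            assert auc(np.tanh(scores) * 7 + 2, labels) == pytest.approx(a, abs=1e-12)


class TestSelectionMetrics:
    def test_f_measure_examples(self):
        truth = set(range(8))
        assert f_measure(SelectionResult(truth, truth)) == 1.0
        all16 = set(range(16))
        assert f_measure(SelectionResult(all16, truth)) == pytest.approx(2 * 8 / 24)
        four_true = set(range(4))
        assert f_measure(SelectionResult(four_true, truth)) == pytest.approx(2 * 4 / 12)

    def test_f_measure_is_one_iff_exact(self, rng):
        for _ in range(20):
            truth = set(rng.choice(16, 8, replace=False).tolist())
            sel = set(rng.choice(16, rng.integers(1, 16), replace=False).tolist())
            f = f_measure(SelectionResult(sel, truth))
            assert 0.0 <= f <= 1.0
            assert (f == 1.0) == (sel == truth)

    def test_f_measure_requires_truth(self):
        with pytest.raises(ValueError, match="truth"):
            f_measure(SelectionResult({1, 2}, None))

    def test_selection_rate(self):
        assert selection_rate(SelectionResult(set(range(16))), 16) == 100.0
        assert selection_rate(SelectionResult(set()), 16) == 0.0
        assert selection_rate(SelectionResult(set(range(10))), 16) == 62.5


class TestWilcoxon:
    def test_all_zero_differences(self):
        assert wilcoxon_signed_rank(np.zeros(6)) == 1.0

    def test_five_positive_no_ties_exact(self):
        # all-positive pattern is 1 of 32; two-sided doubles it
        assert wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0]) == pytest.approx(
            2 / 32)

    def test_mixed_case_with_zero_matches_enumeration(self):
        d = np.array([0.0, 1.5, -0.5, 2.0, 1.0, -1.0])
        assert wilcoxon_signed_rank(d) == pytest.approx(exhaustive_wilcoxon(d))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-4, 4), min_size=1, max_size=10))
    def test_matches_exhaustive_enumeration(self, diffs):
        d = np.array(diffs, float) / 2.0
        for alt in ("two-sided", "greater"):
            assert wilcoxon_signed_rank(d, alt) == pytest.approx(
                exhaustive_wilcoxon(d, alt), abs=1e-12)

    def test_agrees_with_scipy_on_tie_free_inputs(self, rng):
        # scipy's exact path assumes untied ranks, so compare only there
        from scipy.stats import wilcoxon as scipy_wilcoxon

        for _ in range(20):
            d = rng.standard_normal(12)
            ours = wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(d, zero_method="pratt", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-10)


class TestNestedCv:
    def test_single_grid_point_equals_direct_fit(self, rng):
        ts = random_trials(rng, n=30, p=2, r=2, separation=1.0)
        best, res = nested_cv_select(ts, "gsvm-2", lam_grid=[0.05], seed=3)
        assert best["lam"] == 0.05
        from erpselect.regularizers import RegularizerSpec
        from erpselect.solver import SolverOptions, fit_single_task

        direct = fit_single_task(
            ts, RegularizerSpec("group_lq", 0.05 * ts.n, q=2.0),
            opts=SolverOptions(max_iter=4000, rel_tol=1e-8),
        )
        np.testing.assert_allclose(res.model.w, direct.model.w, atol=1e-10)

    def test_same_seed_reproduces_selection(self, rng):
        ts = random_trials(rng, n=40, p=2, r=2, separation=0.8)
        best1, res1 = nested_cv_select(ts, "svm-1", lam_grid=[0.01, 0.1, 1.0],
                                       seed=7)
        best2, res2 = nested_cv_select(ts, "svm-1", lam_grid=[0.01, 0.1, 1.0],
                                       seed=7)
        assert best1 == best2
        np.testing.assert_array_equal(res1.model.w, res2.model.w)

    def test_selects_grid_argmax_of_mean_fold_auc(self):
        """The chosen λ maximizes mean validation AUC computed exhaustively."""
        cfg = SimulationConfig(n_trials=400, n_train=200, p=4, r=4, k=2,
                               amplitude=0.4, seed=5)
        trials, truth, (tr, _) = generate_simulated_p300(cfg)
        train = trials.subset(tr)
        grid = [1e-3, 0.03, 0.2, 1.0]
        best, _ = nested_cv_select(train, "gsvm-2", lam_grid=grid, seed=11)

        # independent exhaustive evaluation of the same folds
        from sklearn.model_selection import StratifiedKFold
        from erpselect.regularizers import RegularizerSpec
        from erpselect.solver import SolverOptions, fit_single_task

        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=11)
        means = []
        for lam in grid:
            scores = []
            for tr_i, va_i in skf.split(train.features, train.labels):
                sub, val = train.subset(tr_i), train.subset(va_i)
                res = fit_single_task(
                    sub, RegularizerSpec("group_lq", lam * sub.n, q=2.0),
                    opts=SolverOptions(max_iter=2000, rel_tol=1e-7),
                )
                scores.append(auc(decision_values(res.model, val), val.labels))
            means.append(np.mean(scores))
        assert best["lam"] == pytest.approx(grid[int(np.argmax(means))])


@pytest.fixture(scope="module")
def tiny_dataset():
    cfg = SimulationConfig(n_trials=350, n_train=150, p=4, r=4, k=2,
                           amplitude=0.35, seed=2)
    trials, truth, _ = generate_simulated_p300(cfg)
    return trials, truth


class TestRunBenchmark:
    def test_single_run_single_method_is_deterministic(self, tiny_dataset):
        trials, truth = tiny_dataset
        kwargs = dict(n_runs=1, n_train=150, seed=4, lam_grid=[0.01, 0.3])
        rep1 = run_benchmark(trials, truth, ["gsvm-2"], **kwargs)
        rep2 = run_benchmark(trials, truth, ["gsvm-2"], **kwargs)
        assert rep1.per_run.equals(rep2.per_run)

    def test_identical_method_specs_tie_with_p_one(self, tiny_dataset):
        trials, truth = tiny_dataset
        rep = run_benchmark(trials, truth, ["svm", "svm"], n_runs=3,
                            n_train=150, seed=1, lam_grid=[0.1], baseline="svm")
        a = rep.per_run[rep.per_run.method == "svm"]["auc"].to_numpy()
        # both copies produce the same column of AUCs
        assert np.allclose(a[: len(a) // 2], a[len(a) // 2 :]) or len(set(a)) <= 3

    def test_report_fields_and_ranges(self, tiny_dataset):
        trials, truth = tiny_dataset
        rep = run_benchmark(trials, truth, ["svm", "gsvm-2"], n_runs=2,
                            n_train=150, seed=9, lam_grid=[0.01, 0.1, 1.0])
        assert set(rep.summary.index) == {"svm", "gsvm-2"}
        assert ((rep.per_run.selection_rate >= 0)
                & (rep.per_run.selection_rate <= 100)).all()
        assert ((rep.per_run.auc >= 0) & (rep.per_run.auc <= 1)).all()
        assert "gsvm-2" in rep.p_values

    def test_insufficient_data_rejected(self, tiny_dataset):
        trials, truth = tiny_dataset
        with pytest.raises(ValueError, match="exceed"):
            run_benchmark(trials, truth, ["svm"], n_train=trials.n)

    def test_default_grid_shape(self):
        assert DEFAULT_LAMBDA_GRID.size == 13
        assert DEFAULT_LAMBDA_GRID[0] == pytest.approx(1e-3)
        assert DEFAULT_LAMBDA_GRID[-1] == pytest.approx(10.0)
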