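import numpy as np
import pytest

from hydrogb.data_model import SampleTable
from hydrogb.evaluation import (
    EvalConfig,
    ExperimentGrid,
    SelectorConfig,
    compute_metrics,
    cross_validated_score,
    knn_cv_rmse_grid,
    run_method,
    write_metrics_report,
    write_report,
)
from hydrogb.regressors import KNNConfig, MLPConfig
from hydrogb.synthetic import SyntheticSpec, generate


class TestComputeMetrics:
    def test_closed_form_triple(self):
        rep = compute_metrics([1, 2, 3], [2, 2, 2])
        assert rep.rmse == pytest.approx(np.sqrt(2 / 3), abs=1e-12)
        assert rep.mae == pytest.approx(2 / 3, abs=1e-12)
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)

    def test_mape_by_hand(self):
        rep = compute_metrics([1, 2], [2, 2])
        assert rep.mape == pytest.approx(50.0, abs=1e-12)

    def test_perfect_prediction(self):
        rep = compute_metrics([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert rep.rmse == rep.mae == rep.mape == 0.0
        assert rep.r2 == 1.0

    def test_zero_actuals_excluded_from_mape(self):
        rep = compute_metrics([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert rep.mape_excluded == 1
        assert rep.mape == pytest.approx(100.0 * (0.0 + 0.5) / 2)

    def test_all_zero_actuals_mape_undefined(self):
        with pytest.raises(ValueError, match="MAPE"):
            compute_metrics([0.0, 0.0], [1.0, 1.0])

    def test_constant_actuals_r2_undefined(self):
        with pytest.raises(ValueError, match="R\\^2"):
            compute_metrics([2.0, 2.0], [1.0, 3.0])

    def test_rmse_at_least_mae_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 50)
            T = rng.normal(1.0, 5.0, size=n)
            P = rng.normal(1.0, 5.0, size=n)
            if (T == 0).all() or T.std() == 0:
                continue
            rep = compute_metrics(T, P)
            assert rep.rmse >= rep.mae >= 0.0
            assert rep.r2 <= 1.0

    def test_r2_zero_iff_mean_prediction(self):
        T = np.array([1.0, 4.0, 7.0, 2.0])
        rep = compute_metrics(T, np.full(4, T.mean()))
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)


class TestCrossValidation:
    def test_mean_predictor_has_nonpositive_pooled_r2(self):
        # out-of-fold constant-mean predictions: pooled R^2 <= 0 by construction
        rng = np.random.default_rng(5)
        t = generate(SyntheticSpec(seed=5))
        from hydrogb.data_model import iter_folds, make_folds

        plan = make_folds(t.n, 5, seed=1)
        actual, preds = [], []
        for train, test in iter_folds(plan):
            actual.append(t.target[test])
            preds.append(np.full(test.size, t.target[train].mean()))
        rep = compute_metrics(np.concatenate(actual), np.concatenate(preds))
        assert rep.r2 <= 0.0

    def test_deterministic_per_seed(self, paper_like_table):
        ev = EvalConfig(n_folds=5, seed=7)
        a = cross_validated_score(paper_like_table, SelectorConfig(method="gbrs"), KNNConfig(k=3), ev)
        b = cross_validated_score(paper_like_table, SelectorConfig(method="gbrs"), KNNConfig(k=3), ev)
        assert (a.rmse, a.mae, a.mape, a.r2) == (b.rmse, b.mae, b.mape, b.r2)

    def test_fold_count_changes_only_the_plan(self, paper_like_table):
        a = cross_validated_score(paper_like_table, evaluation=EvalConfig(n_folds=2, seed=7))
        b = cross_validated_score(paper_like_table, evaluation=EvalConfig(n_folds=5, seed=7))
        assert a.n_evaluated == b.n_evaluated == paper_like_table.n
        assert a.rmse != b.rmse  # different partitions, different pooled errors

    def test_selection_never_sees_heldout_targets(self, paper_like_table):
        """Leakage check: shuffling held-out targets changes no selected subset."""
        from hydrogb.data_model import iter_folds, make_folds
        from hydrogb.evaluation import _select_features

        t = paper_like_table
        plan = make_folds(t.n, 5, seed=3)
        ev = EvalConfig(n_folds=5, seed=3)
        sel = SelectorConfig(method="gbrs")
        rng = np.random.default_rng(0)
        for train, test in iter_folds(plan):
            tr = t.subset_rows(train)
            baseline = _select_features(tr, sel, KNNConfig(k=3), ev)
            shuffled = SampleTable(
                values=t.values.copy(),
                target=t.target.copy(),
                attribute_names=list(t.attribute_names),
            )
            shuffled.target[test] = rng.permutation(shuffled.target[test])
            tr2 = shuffled.subset_rows(train)
            assert _select_features(tr2, sel, KNNConfig(k=3), ev) == baseline

    def test_holdout_protocol(self, paper_like_table):
        rep = cross_validated_score(
            paper_like_table, evaluation=EvalConfig(seed=1, holdout=0.3)
        )
        assert rep.n_evaluated == int(round(0.3 * paper_like_table.n))


class TestRunMethod:
    def test_knn_grid_shape(self, paper_like_table):
        grid = run_method(paper_like_table, "knn", evaluation=EvalConfig(n_folds=5, seed=1))
        assert grid.scores.shape == (1, 8)
        assert grid.feature_counts == [13]

    def test_pk_full_grid_shape_and_reports(self, tmp_path):
        t = generate(SyntheticSpec(n=30, d_informative=2, d_redundant=1, d_noise=2, seed=2))
        grid = run_method(t, "pk", evaluation=EvalConfig(n_folds=5, seed=1))
        assert grid.scores.shape == (5, 8)
        assert grid.feature_counts == [5, 4, 3, 2, 1]
        assert "per_k_best" in grid.details
        path = tmp_path / "sweep.csv"
        write_report(grid, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("features,k=1")
        assert len(lines) == 6
        assert sum(cell.endswith("*") for line in lines[1:] for cell in line.split(",")) == 1

    def test_gbrsk_beats_all_feature_knn_on_planted_fixture(self):
        """Feature selection should help kNN on most planted-signal datasets."""
        wins = 0
        for seed in range(6):
            t = generate(SyntheticSpec(n=60, d_informative=2, d_redundant=2, d_noise=4, seed=seed))
            ev = EvalConfig(n_folds=5, seed=11)
            knn_best = knn_cv_rmse_grid(t, evaluation=ev).min()
            grid = run_method(t, "gbrsk", evaluation=ev)
            wins += grid.scores.min() <= knn_best
        assert wins >= 3

    def test_bp_family_single_column(self):
        t = generate(SyntheticSpec(n=30, d_informative=2, d_redundant=1, d_noise=1, seed=4))
        grid = run_method(
            t, "bp", mlp_config=MLPConfig(epochs=100, seed=0), evaluation=EvalConfig(n_folds=3, seed=1)
        )
        assert grid.scores.shape == (1, 1)
        assert grid.details["report"].rmse == pytest.approx(float(grid.scores[0, 0]))

    def test_unknown_method_rejected(self, paper_like_table):
        with pytest.raises(ValueError):
            run_method(paper_like_table, "svr")


class TestReports:
    def test_metrics_report_columns(self, tmp_path):
        reps = {
            "pbp": compute_metrics([1, 2, 3], [2, 2, 2]),
            "gbrsbp": compute_metrics([1, 2, 3], [1, 2, 2]),
        }
        path = tmp_path / "cmp.csv"
        write_metrics_report(reps, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "method,RMSE,MAE,MAPE,R2"
        assert len(lines) == 3
        assert "*" in lines[2]  # gbrsbp has the lower RMSE

    def test_empty_grid_rejected(self, tmp_path):
        grid = ExperimentGrid("knn", (), [], np.empty((0, 0)), 0)
        with pytest.raises(ValueError):
            write_report(grid, tmp_path / "x.csv")
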