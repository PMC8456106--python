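import numpy as np
import pandas as pd
import pytest

from tcrkernel.features import FeatureTable
from tcrkernel.mkl import (
    SIGMA_PERCENTILES,
    build_bank,
    easymkl_weights,
    evaluate,
    fit,
    gamma_heuristic,
    predict,
    repeated_holdout,
    train_model,
)


def table_from_array(X, feature_sets=("distances",), ids=None):
    """Wrap a plain array (or dict feature_set → array) as a FeatureTable."""
    if not isinstance(X, dict):
        X = {feature_sets[0]: np.asarray(X, dtype=float)}
    frames = []
    for fset, arr in X.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        cols = pd.MultiIndex.from_tuples([(fset, f"c{j}") for j in range(arr.shape[1])])
        frames.append(pd.DataFrame(arr, columns=cols))
    df = pd.concat(frames, axis=1)
    df.index = ids or [f"s{i}" for i in range(len(df))]
    return FeatureTable(df)


class TestGammaHeuristic:
    def test_single_distance(self):
        t = table_from_array([[0.0], [1.0]])
        sigmas, gammas = gamma_heuristic(t, [1, -1], "distances")
        assert np.allclose(sigmas, 1.0)
        assert np.allclose(gammas, 0.5)

    def test_formula_at_sigma_two(self):
        t = table_from_array([[0.0], [2.0]])
        sigmas, gammas = gamma_heuristic(t, [1, -1], "distances")
        assert np.allclose(sigmas, 2.0)
        assert np.allclose(gammas, 0.125)  # gamma = 1 / (2 * sigma^2)

    def test_brute_force_percentile_oracle(self):
        """20 positives × 20 negatives: sigma percentiles must match a manual
        enumeration of all 400 cross-class distances with hand-rolled linear
        interpolation."""
        rng = np.random.default_rng(17)
        X = rng.normal(size=(40, 6))
        y = np.array([1] * 20 + [-1] * 20)
        t = table_from_array(X)
        sigmas, gammas = gamma_heuristic(t, y, "distances")

        dists = sorted(
            float(np.sqrt(((X[i] - X[j]) ** 2).sum()))
            for i in range(20)
            for j in range(20, 40)
        )
        assert len(dists) == 400

        def manual_percentile(sorted_vals, q):
            h = (len(sorted_vals) - 1) * q / 100.0
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        expected = [manual_percentile(dists, q) for q in SIGMA_PERCENTILES]
        assert np.allclose(sigmas, expected, rtol=1e-12)
        assert np.allclose(gammas, 1.0 / (2.0 * np.array(expected) ** 2))

    def test_duplicate_rows_cap_gamma(self):
        t = table_from_array([[0.0], [0.0]])
        with pytest.warns(UserWarning, match="sigma=0"):
            _, gammas = gamma_heuristic(t, [1, -1], "distances")
        assert np.isfinite(gammas).all()

    def test_single_class_errors(self):
        t = table_from_array([[0.0], [1.0]])
        with pytest.raises(ValueError):
            gamma_heuristic(t, [1, 1], "distances")


class TestBuildBank:
    @pytest.fixture()
    def bank(self):
        rng = np.random.default_rng(4)
        X = {"distances": rng.normal(size=(16, 5)), "atchley": rng.normal(size=(16, 8))}
        y = np.array([1] * 8 + [-1] * 8)
        return build_bank(table_from_array(X), y, ["distances", "atchley"]), y

    def test_seven_grams_per_feature_set(self, bank):
        b, _ = bank
        assert len(b.grams) == 14
        assert len(b.gammas("distances")) == 7

    def test_unit_diagonal_and_identical_rows(self):
        X = np.array([[0.0, 1.0], [0.0, 1.0], [2.0, 3.0], [4.0, 0.0]])
        b = build_bank(table_from_array(X), [1, 1, -1, -1], ["distances"])
        for K in b.grams:
            assert np.allclose(np.diag(K), 1.0)
            assert K[0, 1] == pytest.approx(1.0)  # identical rows

    def test_grams_positive_semidefinite(self, bank):
        b, _ = bank
        for K in b.grams:
            assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestEasyMkl:
    def test_single_gram_weight_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        K = np.exp(-((X[:, None] - X[None]) ** 2).sum(-1))
        y = np.array([1] * 5 + [-1] * 5)
        eta, _ = easymkl_weights([K], y)
        assert eta == pytest.approx([1.0])

    def test_identical_grams_split_evenly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        K = np.exp(-((X[:, None] - X[None]) ** 2).sum(-1))
        y = np.array([1] * 5 + [-1] * 5)
        eta, _ = easymkl_weights([K, K], y)
        assert eta == pytest.approx([0.5, 0.5])

    @pytest.fixture()
    def signal_noise_instance(self):
        """12 samples; one label-aligned kernel, one pure-noise kernel."""
        rng = np.random.default_rng(9)
        y = np.array([1] * 6 + [-1] * 6)
        x_sig = y + 0.1 * rng.normal(size=12)
        x_noise = rng.normal(size=12)
        K_sig = np.exp(-0.5 * (x_sig[:, None] - x_sig[None]) ** 2)
        K_noise = np.exp(-0.5 * (x_noise[:, None] - x_noise[None]) ** 2)
        return [K_sig, K_noise], y

    def test_signal_kernel_outweighs_noise(self, signal_noise_instance):
        grams, y = signal_noise_instance
        eta, _ = easymkl_weights(grams, y)
        assert eta[0] > eta[1]

    def test_gamma_star_is_bisimplex_optimum(self, signal_noise_instance):
        """Objective at the solver's optimum is no worse than at 1000 random
        feasible bi-simplex points (and than an independent SLSQP solve)."""
        grams, y = signal_noise_instance
        K_bar = sum(grams) / len(grams)
        YKY = y[:, None] * K_bar * y[None, :]
        _, g_star = easymkl_weights(grams, y)
        obj_star = g_star @ YKY @ g_star

        rng = np.random.default_rng(3)
        pos, neg = y > 0, y < 0
        for _ in range(1000):
            g = np.zeros(12)
            g[pos] = rng.dirichlet(np.ones(pos.sum()))
            g[neg] = rng.dirichlet(np.ones(neg.sum()))
            assert obj_star <= g @ YKY @ g + 1e-9

        from scipy.optimize import LinearConstraint, minimize

        A_pos = pos.astype(float)
        A_neg = neg.astype(float)
        res = minimize(
            lambda g: g @ YKY @ g,
            np.where(pos, 1 / 6, 1 / 6),
            jac=lambda g: 2 * YKY @ g,
            bounds=[(0, 1)] * 12,
            constraints=[
                LinearConstraint(A_pos, 1.0, 1.0),
                LinearConstraint(A_neg, 1.0, 1.0),
            ],
            method="SLSQP",
        )
        assert obj_star <= res.fun + 1e-8

    def test_weights_match_grid_search_on_margin_objective(self, signal_noise_instance):
        """The solver's weighting agrees with an exhaustive search over convex
        combinations w·K₁+(1−w)·K₂: the convex combination implied by η must
        achieve (within tolerance) the best class-hull separation found on a
        fine w grid, using an independent SLSQP inner solver."""
        from scipy.optimize import LinearConstraint, minimize

        grams, y = signal_noise_instance
        pos, neg = y > 0, y < 0

        def hull_distance_sq(K):
            YKY = y[:, None] * K * y[None, :]
            res = minimize(
                lambda g: g @ YKY @ g,
                np.full(12, 1 / 6),
                jac=lambda g: 2 * YKY @ g,
                bounds=[(0, 1)] * 12,
                constraints=[
                    LinearConstraint(pos.astype(float), 1.0, 1.0),
                    LinearConstraint(neg.astype(float), 1.0, 1.0),
                ],
                method="SLSQP",
            )
            return res.fun

        eta, _ = easymkl_weights(grams, y)
        d_eta = hull_distance_sq(eta[0] * grams[0] + eta[1] * grams[1])
        grid = np.linspace(0, 1, 101)
        d_grid = [hull_distance_sq(w * grams[0] + (1 - w) * grams[1]) for w in grid]
        best_w = grid[int(np.argmax(d_grid))]
        # larger hull distance = larger margin; eta should be near-optimal
        assert d_eta >= max(d_grid) * 0.9
        assert abs(eta[0] - best_w) < 0.25

    def test_empty_bank_errors(self):
        with pytest.raises(ValueError):
            easymkl_weights([], [1, -1])


def _separable_table(n=30, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    X = np.column_stack([y * 2.0 + 0.1 * rng.normal(size=n), rng.normal(size=n)])
    return table_from_array(X), y


class TestFitPredict:
    def test_separable_data_training_auc_one(self):
        t, y = _separable_table()
        bank = build_bank(t, y, ["distances"])
        model = fit(bank, y, train_table=t, seed=0)
        scores = model.svc.decision_function(model.combined_train_gram())
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, scores) == 1.0

    def test_permuted_labels_internal_cv_near_chance(self):
        t, y = _separable_table(n=40, seed=1)
        y_perm = np.random.default_rng(12).permutation(y)
        bank = build_bank(t, y_perm, ["distances"])
        model = fit(bank, y_perm, train_table=t, seed=0)
        best_auc = max(v for v in model.internal_cv_auc.values() if np.isfinite(v))
        assert 0.25 <= best_auc <= 0.75  # chance-level with small-fold noise

    def test_refit_determinism(self):
        t, y = _separable_table()
        bank = build_bank(t, y, ["distances"])
        m1 = fit(bank, y, train_table=t, seed=3)
        m2 = fit(bank, y, train_table=t, seed=3)
        assert m1.summary() == m2.summary()

    def test_predict_reproduces_training_scores(self):
        t, y = _separable_table()
        model = train_model(t, y, ["distances"], seed=0)
        train_scores = model.svc.decision_function(model.combined_train_gram())
        pred = predict(model, t)
        assert np.allclose(pred, train_scores, atol=1e-9)

    def test_duplicated_training_row_same_score(self):
        t, y = _separable_table()
        model = train_model(t, y, ["distances"], seed=0)
        one = FeatureTable(t.data.iloc[[0]])
        assert predict(model, one)[0] == pytest.approx(predict(model, t)[0])

    def test_too_few_samples_errors(self):
        t, y = _separable_table(n=10)
        bank = build_bank(t, y, ["distances"])
        with pytest.raises(ValueError, match="20"):
            fit(bank, y)


class TestRepeatedHoldout:
    def test_ten_repeats_ten_aucs(self):
        t, y = _separable_table(n=40, seed=2)
        res = repeated_holdout(t, y, ["distances"], n_repeats=10, seed=0)
        assert len(res.aucs) == 10
        assert res.mean_auc > 0.9  # strongly separable 1-D signal

    def test_test_split_size(self):
        t, y = _separable_table(n=100, seed=3)
        res = repeated_holdout(t, y, ["distances"], n_repeats=2, test_frac=0.30, seed=0)
        # every test split holds 30 of 100 rows: AUC defined on 30 samples
        assert len(res.aucs) == 2

    def test_permuted_labels_near_half(self):
        t, y = _separable_table(n=60, seed=4)
        y_perm = np.random.default_rng(7).permutation(y)
        res = repeated_holdout(t, y_perm, ["distances"], n_repeats=10, seed=1)
        sd = max(res.sd_auc, 0.05)
        assert abs(res.mean_auc - 0.5) <= 2 * sd


class TestEvaluate:
    def test_perfect_ranking(self):
        y = [1, 1, -1, -1]
        m = evaluate([2.0, 1.5, -0.5, -1.0], y)
        assert m["roc_auc"] == 1.0
        assert m["average_precision"] == 1.0
        assert m["accuracy"] == 1.0

    def test_inverted_ranking(self):
        y = [1, 1, -1, -1]
        m = evaluate([-2.0, -1.5, 0.5, 1.0], y)
        assert m["roc_auc"] == 0.0

    def test_per_epitope_minimum_counts(self):
        y = [1, 1, -1, -1, 1, -1]
        s = [1.0, 0.5, -0.5, -1.0, 0.2, -0.2]
        eps = ["A", "A", "A", "A", "B", "B"]  # B has only 1 pos + 1 neg
        m = evaluate(s, y, epitopes=eps)
        assert set(m["per_epitope_auc"]) == {"A"}
        assert m["per_epitope_auc"]["A"] == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            evaluate([0.1, 0.2], [1, 1])
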