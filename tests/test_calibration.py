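"""Linear/logistic calibration engines, runs test, ROC, prediction intervals."""

import math

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from phagedls.calibration import (
    DEFAULT_THRESHOLDS,
    PairedObservation,
    fit_linear,
    fit_logistic,
    load_model,
    model_from_dict,
    model_to_dict,
    predict_titer_loss,
    rank_roc_auc,
    read_pairs_csv,
    roc_curve,
    runs_test_linearity,
    runs_test_pvalue,
    save_model,
    threshold_sweep,
    tjur_r2,
    write_pairs_csv,
)


def pairs_from(x, y, censored=None):
    censored = censored or [False] * len(x)
    return [
        PairedObservation(auc_delta=float(a), titer_loss_log10=float(b), censored=c)
        for a, b, c in zip(x, y, censored)
    ]


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


class TestFitLinear:
    def test_exact_collinear_points(self):
        m = fit_linear(pairs_from([0, 10, 20], [0, 1, 2]))
        assert m.slope == pytest.approx(0.1, abs=1e-12)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_on_random_data(self, rng):
        x = rng.uniform(0, 200, 40)
        y = 0.03 * x + rng.normal(0, 0.5, 40)
        m = fit_linear(pairs_from(x, y))
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        assert m.slope == pytest.approx(beta[1], abs=1e-10)
        assert m.r_squared == pytest.approx(m.r**2, abs=1e-12)

    def test_pearson_p_matches_permutation_test(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 200, 20)
        y = 0.0012 * x + rng.normal(0, 0.6, 20)
        m = fit_linear(pairs_from(x, y))
        r_obs = abs(stats.pearsonr(x, y)[0])
        perm_rng = np.random.default_rng(99)
        n_shuffles = 10_000
        hits = 0
        for _ in range(n_shuffles):
            r = stats.pearsonr(x, perm_rng.permutation(y))[0]
            if abs(r) >= r_obs - 1e-15:
                hits += 1
        p_perm = (hits + 1) / (n_shuffles + 1)
        mc_sd = math.sqrt(p_perm * (1 - p_perm) / n_shuffles)
        assert abs(m.p_value - p_perm) < 4 * mc_sd + 0.01

    def test_shift_and_scale_equivariance(self, rng):
        x = rng.uniform(0, 200, 30)
        y = 0.04 * x + rng.normal(0, 0.3, 30)
        base = fit_linear(pairs_from(x, y))
        shifted = fit_linear(pairs_from(x, y + 2.5))
        assert shifted.slope == pytest.approx(base.slope, rel=1e-12)
        assert shifted.intercept == pytest.approx(base.intercept + 2.5, rel=1e-9)
        scaled = fit_linear(pairs_from(x / 2.0, y))
        assert scaled.slope == pytest.approx(base.slope * 2.0, rel=1e-9)

    def test_too_few_points_and_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_linear(pairs_from([0, 10], [0, 1]))
        with pytest.raises(ValueError, match="no variation"):
            fit_linear(pairs_from([5, 5, 5], [0, 1, 2]))

    def test_censored_pairs_can_be_excluded(self):
        pairs = pairs_from([0, 50, 100, 150], [0, 2, 4, 5], censored=[False, False, False, True])
        m_all = fit_linear(pairs)
        m_trim = fit_linear(pairs, include_censored=False)
        assert m_all.n == 4 and m_trim.n == 3

    def test_slope_recovery_with_ci_coverage(self):
        # pairs drawn from loss = 0.05 * x + N(0, 0.3); the fitted slope
        # should land inside its own 95% CI in >= 90% of seeded runs
        hits = 0
        runs = 200
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 200, 50)
            y = 0.05 * x + rng.normal(0, 0.3, 50)
            m = fit_linear(pairs_from(x, y))
            se_slope = m.residual_sd / math.sqrt(m.sxx)
            tcrit = stats.t.ppf(0.975, m.n - 2)
            if abs(m.slope - 0.05) <= tcrit * se_slope:
                hits += 1
        assert hits / runs >= 0.90


# ---------------------------------------------------------------------------
# runs test
# ---------------------------------------------------------------------------


def _exact_runs_two_sided(signs):
    """Enumeration oracle: exact two-sided runs-test p by brute force over
    all arrangements (feasible for tiny n)."""
    from itertools import permutations

    signs = tuple(signs)
    n_runs = lambda s: 1 + sum(a != b for a, b in zip(s, s[1:]))
    observed = n_runs(signs)
    counts = {}
    for perm in set(permutations(signs)):
        counts[n_runs(perm)] = counts.get(n_runs(perm), 0) + 1
    total = sum(counts.values())
    lo = sum(c for r, c in counts.items() if r <= observed) / total
    hi = sum(c for r, c in counts.items() if r >= observed) / total
    return min(1.0, 2 * min(lo, hi))


class TestRunsTest:
    def test_alternating_signs_detected_as_nonrandom(self):
        signs = [1, -1] * 5
        res = runs_test_pvalue(signs)
        assert res.n_runs == 10
        assert res.p_value == pytest.approx(2 * 2 / 252, abs=1e-12)
        assert res.p_value < 0.05

    def test_two_block_sequence_matches_enumeration(self):
        signs = [1] * 5 + [-1] * 5
        res = runs_test_pvalue(signs)
        assert res.n_runs == 2
        assert res.p_value == pytest.approx(_exact_runs_two_sided(signs), abs=1e-12)

    @pytest.mark.parametrize(
        "signs",
        [
            [1, 1, -1, 1, -1, -1, 1],
            [1, -1, -1, -1, 1, 1, -1, 1],
        ],
    )
    def test_exact_distribution_matches_enumeration(self, signs):
        assert runs_test_pvalue(signs).p_value == pytest.approx(
            _exact_runs_two_sided(signs), abs=1e-12
        )

    def test_large_n_uses_normal_approximation(self, rng):
        signs = rng.choice([-1, 1], size=200)
        res = runs_test_pvalue(signs)
        assert 0.0 <= res.p_value <= 1.0

    def test_perfectly_linear_data_returns_p_one(self):
        pairs = pairs_from([0, 10, 20, 30], [0, 1, 2, 3])
        m = fit_linear(pairs)
        res = runs_test_linearity(m, pairs)
        assert res.p_value == 1.0
        assert "zero" in res.note

    def test_curvature_yields_few_runs_and_small_p(self):
        x = np.linspace(0, 200, 24)
        y = (x / 100.0) ** 2  # convex: residual signs cluster (+ - +)
        m = fit_linear(pairs_from(x, y))
        res = runs_test_linearity(m, pairs_from(x, y))
        assert res.n_runs <= 4
        assert res.p_value < 0.01


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


class TestPredictTiterLoss:
    def test_exact_fit_gives_zero_width_interval(self):
        m = fit_linear(pairs_from([0, 10, 20], [0, 1, 2]))
        pred = predict_titer_loss(m, 15.0)
        assert pred.predicted_loss_log10 == pytest.approx(1.5, abs=1e-9)
        lo, hi = pred.interval_log10
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_interval_narrowest_at_training_mean(self, rng):
        x = rng.uniform(0, 200, 30)
        y = 0.04 * x + rng.normal(0, 0.4, 30)
        m = fit_linear(pairs_from(x, y))
        widths = []
        for q in [m.x_mean - 50, m.x_mean, m.x_mean + 50]:
            lo, hi = predict_titer_loss(m, float(np.clip(q, 0, 200))).interval_log10
            widths.append(hi - lo)
        assert widths[1] == min(widths)

    def test_extrapolation_flagged_outside_training_range(self, rng):
        x = rng.uniform(50, 100, 20)
        y = 0.05 * x + rng.normal(0, 0.2, 20)
        m = fit_linear(pairs_from(x, y))
        assert predict_titer_loss(m, 150.0).extrapolated
        assert not predict_titer_loss(m, 75.0).extrapolated

    def test_recovered_model_predicts_near_truth_at_x100(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 200, 50)
        y = 0.05 * x + rng.normal(0, 0.3, 50)
        m = fit_linear(pairs_from(x, y))
        pred = predict_titer_loss(m, 100.0)
        assert pred.predicted_loss_log10 == pytest.approx(5.0, abs=0.2)


# ---------------------------------------------------------------------------
# logistic classifiers
# ---------------------------------------------------------------------------


class TestFitLogistic:
    def test_null_case_shuffled_outcome(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 200, 400)
        y = rng.permutation((x > 100).astype(float) * 2.0)  # loss decoupled from x
        clf = fit_logistic(pairs_from(x, y), 1.0)
        assert abs(clf.or_pct_per_unit) < 1.0
        assert clf.roc_auc == pytest.approx(0.5, abs=0.1)
        assert clf.or_ci95[0] <= clf.or_pct_per_unit <= clf.or_ci95[1]

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 200, 300)
        lam = x / 200.0
        y = 6 * lam + rng.normal(0, 1.5, 300)
        clf = fit_logistic(pairs_from(x, y), 2.0)
        fit = sm.GLM(
            (y > 2.0).astype(float), sm.add_constant(x), family=sm.families.Binomial()
        ).fit()
        assert clf.beta0 == pytest.approx(fit.params[0], rel=1e-6)
        assert clf.beta1 == pytest.approx(fit.params[1], rel=1e-6)
        assert clf.or_pct_per_unit == pytest.approx(
            100 * (math.exp(fit.params[1]) - 1), rel=1e-6
        )

    def test_perfect_separation_flagged_not_raised(self):
        # wide gap between classes: the MLE diverges
        pairs = pairs_from([10, 20, 30, 40, 110, 120, 130, 140], [0, 0, 0, 0, 2, 2, 2, 2])
        clf = fit_logistic(pairs, 1.0)
        assert clf.separation_flag
        assert clf.tjur_r2 == pytest.approx(1.0, abs=1e-6)

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="degenerate outcome"):
            fit_logistic(pairs_from([0, 50, 100], [0.1, 0.2, 0.3]), 1.0)

    def test_tjur_r2_definition(self):
        assert tjur_r2([0, 0, 1, 1], [0.0, 0.0, 1.0, 1.0]) == 1.0
        assert tjur_r2([0, 1], [0.5, 0.5]) == 0.0


class TestThresholdSweep:
    def test_single_threshold_consistent_with_direct_fit(self, rng):
        x = rng.uniform(0, 200, 100)
        y = x / 40.0 + rng.normal(0, 0.8, 100)
        (entry,) = threshold_sweep(pairs_from(x, y), thresholds=[1.0])
        direct = fit_logistic(pairs_from(x, y), 1.0)
        assert entry.classifier.beta1 == pytest.approx(direct.beta1, rel=1e-12)

    def test_infeasible_thresholds_skipped(self):
        pairs = pairs_from([0, 50, 100, 150], [0.1, 0.2, 0.3, 0.4])
        entries = threshold_sweep(pairs, thresholds=DEFAULT_THRESHOLDS)
        assert all(e.classifier is None for e in entries)
        assert all("degenerate" in e.skipped_reason for e in entries)

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_sweep(pairs_from([0, 100], [0, 2]), thresholds=[])


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def _brute_force_auc(y, scores):
    pos = [s for s, yy in zip(scores, y) if yy == 1]
    neg = [s for s, yy in zip(scores, y) if yy == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_rank_auc_equals_brute_force_with_ties(self):
        y = [1, 1, 0, 0]
        scores = [0.9, 0.8, 0.8, 0.3]
        assert rank_roc_auc(y, scores) == pytest.approx(_brute_force_auc(y, scores), abs=1e-12)
        assert rank_roc_auc(y, scores) == pytest.approx(0.875, abs=1e-12)

    def test_rank_auc_matches_sklearn_on_random_scores(self, rng):
        y = rng.integers(0, 2, 200)
        y[0], y[1] = 0, 1  # ensure both classes
        scores = rng.uniform(0, 1, 200)
        assert rank_roc_auc(y, scores) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(21)
        y = np.repeat([0, 1], 1000)
        scores = rng.uniform(0, 1, 2000)
        assert rank_roc_auc(y, scores) == pytest.approx(0.5, abs=0.04)

    def test_curve_area_equals_rank_statistic(self, rng):
        x = rng.uniform(0, 200, 120)
        y = x / 40.0 + rng.normal(0, 1.0, 120)
        pairs = pairs_from(x, y)
        clf = fit_logistic(pairs, 2.0)
        pts = roc_curve(clf, pairs)
        fpr = np.array([p[0] for p in pts])
        tpr = np.array([p[1] for p in pts])
        assert float(np.trapezoid(tpr, fpr)) == pytest.approx(clf.roc_auc, abs=1e-9)

    def test_perfectly_separated_scores_area_one(self):
        pairs = pairs_from([0, 10, 20, 180, 190, 200], [0, 0, 0, 3, 3, 3])
        clf = fit_logistic(pairs, 1.0)
        assert clf.roc_auc == 1.0


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


class TestSerialization:
    def test_linear_model_json_round_trip(self, rng, tmp_path):
        x = rng.uniform(0, 200, 30)
        y = 0.04 * x + rng.normal(0, 0.3, 30)
        m = fit_linear(pairs_from(x, y))
        path = tmp_path / "model.json"
        save_model(m, path)
        back = load_model(path)
        assert back == m

    def test_logistic_model_json_round_trip(self, rng, tmp_path):
        x = rng.uniform(0, 200, 100)
        y = x / 40.0 + rng.normal(0, 0.8, 100)
        clf = fit_logistic(pairs_from(x, y), 1.0)
        path = tmp_path / "clf.json"
        save_model(clf, path)
        assert load_model(path) == clf

    def test_unknown_schema_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            model_from_dict({"schema_version": 99, "model_type": "linear"})

    def test_pairs_csv_round_trip(self, tmp_path):
        pairs = pairs_from([0.0, 55.5, 200.0], [0.0, 2.25, 8.4], censored=[False, False, True])
        path = tmp_path / "pairs.csv"
        write_pairs_csv(pairs, path)
        back = read_pairs_csv(path)
        assert back == pairs
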