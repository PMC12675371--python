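import numpy as np
import pytest

from netsurv.errors import ValidationError
from netsurv.evaluate import (
    brier_score,
    concordance_index,
    evaluate_feature_set,
    group_hazard_ratio,
    integrated_brier,
    logrank_test,
    prognostic_index,
    stratify_by_pi,
    summarize_metrics,
)
from netsurv.models import make_model
from netsurv.simulate import SimConfig, generate_cohort, simulate_aft_data


class TestConcordance:
    @pytest.mark.parametrize(
        "risk,expected",
        [((3, 2, 1), 1.0), ((1, 2, 3), 0.0), ((3, 1, 2), 2 / 3)],
    )
    def test_three_subject_examples(self, risk, expected):
        assert concordance_index(risk, [1, 2, 3], [1, 1, 1]) == pytest.approx(expected)

    def test_perfect_orderings_with_noise_risks(self, rng):
        time = rng.exponential(5, 40)
        assert concordance_index(-time, time, np.ones(40)) == 1.0
        assert concordance_index(time, time, np.ones(40)) == 0.0

    def test_ties_count_half(self):
        assert concordance_index([1, 1], [1, 2], [1, 1]) == pytest.approx(0.5)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValidationError):
            concordance_index([1, 2], [3, 3], [0, 0])


class TestBrier:
    def test_constant_half_prediction_scores_quarter(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, int)
        for t in (0.5, 1.5, 3.5):
            assert brier_score(np.full(4, 0.5), time, event, t) == pytest.approx(0.25)

    def test_oracle_predictions_score_zero(self):
        time = np.array([1.0, 2.0, 3.0])
        event = np.ones(3, int)
        for t in (0.5, 1.5, 2.5):
            surv = (time > t).astype(float)  # S=1 before each event, 0 after
            assert brier_score(surv, time, event, t) == pytest.approx(0.0)

    def test_hand_computed_ipcw_weights(self):
        # subjects: events at 1 and 3, censored at 2, event at 4; t = 2.5
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 0, 1, 1])
        surv = np.array([0.4, 0.5, 0.7, 0.9])
        # censoring KM: drop only at 2 -> G(t) = 1 for t<2, 2/3 for t>=2
        # died before 2.5: subject 1, weight 1/G(1-)=1, contributes 0.4^2
        # alive at 2.5: subjects 3,4, weight 1/G(2.5)=3/2
        expected = (0.4**2 * 1 + 0 + 1.5 * (1 - 0.7) ** 2 + 1.5 * (1 - 0.9) ** 2) / 4
        assert brier_score(surv, time, event, 2.5) == pytest.approx(expected)

    def test_ibs_of_constant_prediction(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.ones(5, int)
        ibs = integrated_brier(lambda ts: np.full((5, len(ts)), 0.5), time, event)
        assert ibs == pytest.approx(0.25)

    def test_ibs_of_oracle_is_zero(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, int)

        def oracle(ts):
            return (time[:, None] > np.asarray(ts)[None, :]).astype(float)

        assert integrated_brier(oracle, time, event) == pytest.approx(0.0, abs=1e-12)

    def test_ibs_stable_under_grid_refinement(self, rng):
        # exponential truth with the matching smooth prediction: BS(t) has
        # only O(1/n) jumps, so doubling the grid density barely moves the
        # integral
        n = 400
        time = rng.exponential(10, n)
        event = np.ones(n, int)

        def smooth(ts):
            return np.tile(np.exp(-np.asarray(ts, float) / 10.0), (n, 1))

        from netsurv.evaluate import _censoring_survival

        ckm = _censoring_survival(time, event)
        grid = np.r_[0.0, np.unique(time)]
        bs = np.array([brier_score(smooth([t])[:, 0], time, event, t, ckm) for t in grid])
        coarse = np.trapezoid(bs, grid) / grid[-1]
        fine_grid = np.union1d(grid, (grid[:-1] + grid[1:]) / 2)
        bs_f = np.array(
            [brier_score(smooth([t])[:, 0], time, event, t, ckm) for t in fine_grid]
        )
        fine = np.trapezoid(bs_f, fine_grid) / fine_grid[-1]
        assert abs(coarse - fine) < 1e-3


class TestStratify:
    def test_median_split(self):
        np.testing.assert_array_equal(stratify_by_pi([1, 2, 3, 4], 2), [0, 0, 1, 1])

    def test_tertiles_of_six(self):
        np.testing.assert_array_equal(
            stratify_by_pi([1, 2, 3, 4, 5, 6], 3), [0, 0, 1, 1, 2, 2]
        )

    def test_equal_pi_rank_stable_split(self):
        labels = stratify_by_pi(np.zeros(5), 2)
        assert sorted(np.bincount(labels)) == [2, 3]

    @pytest.mark.parametrize("n,groups", [(7, 2), (8, 3), (11, 3)])
    def test_group_sizes_differ_by_at_most_one(self, rng, n, groups):
        labels = stratify_by_pi(rng.normal(size=n), groups)
        sizes = np.bincount(labels, minlength=groups)
        assert sizes.max() - sizes.min() <= 1


class TestLogrankTest:
    def test_identical_groups_give_zero_statistic(self):
        time = np.r_[np.arange(1.0, 6.0), np.arange(1.0, 6.0)]
        groups = np.r_[np.zeros(5), np.ones(5)]
        stat, p = logrank_test(groups, time, np.ones(10, int))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # groups {1,2} vs {3,4}, all events; observed-expected over 4 risk sets:
        # O1=2, E1 = 2/4 + 1/3 + 0 + 0 = 5/6; V = sum of hypergeometric variances
        time = np.array([1.0, 2.0, 3.0, 4.0])
        groups = np.array([0, 0, 1, 1])
        v = (2 * 2 * 1 * 3) / (16 * 3) + (1 * 2 * 1 * 2) / (9 * 2)
        expected_chi2 = (2 - 5 / 6) ** 2 / v
        stat, _ = logrank_test(groups, time, np.ones(4, int))
        assert stat == pytest.approx(expected_chi2, rel=1e-10)

    def test_pvalues_uniform_under_permutation(self):
        rng = np.random.default_rng(13)
        n, reps = 30, 1000
        time = rng.exponential(10, n)
        event = rng.integers(0, 2, n)
        event[:5] = 1
        pvals = []
        for _ in range(reps):
            groups = rng.permutation(np.r_[np.zeros(15), np.ones(15)])
            pvals.append(logrank_test(groups, time, event)[1])
        from scipy import stats as sps

        ks = sps.kstest(pvals, "uniform")
        assert ks.statistic < 0.05


class TestGroupHazardRatio:
    def test_null_groups_hr_near_one(self, rng):
        time = rng.exponential(10, 200)
        groups = np.r_[np.zeros(100), np.ones(100)]
        hr = group_hazard_ratio(groups, time, np.ones(200, int))
        assert hr.ci_lower < 1.0 < hr.ci_upper

    def test_planted_hr_recovered(self):
        rng = np.random.default_rng(17)
        n = 400
        groups = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        rate = np.where(groups == 1, 2.0, 1.0)  # true HR = 2
        time = rng.exponential(1.0 / rate)
        hr = group_hazard_ratio(groups, time, np.ones(n, int))
        assert 1.6 <= hr.hr <= 2.5

    def test_label_swap_inverts_hr(self, rng):
        time = rng.exponential(10, 60)
        event = np.ones(60, int)
        groups = (rng.random(60) < 0.5).astype(int)
        a = group_hazard_ratio(groups, time, event).hr
        b = group_hazard_ratio(1 - groups, time, event).hr
        assert a * b == pytest.approx(1.0, rel=1e-6)


class TestPrognosticIndex:
    def test_cox_pi_is_linear_predictor(self):
        X, time, event = simulate_aft_data(80, [0.5, -0.5], 0.5, seed=1)
        model = make_model("cox_ph").fit(X, time, event)
        np.testing.assert_allclose(prognostic_index(model, X), X @ model.beta)
        x = np.array([[2.0, 1.0]])
        assert prognostic_index(model, x)[0] == pytest.approx(
            float((x @ model.beta)[0])
        )

    def test_duplicated_sample_same_pi(self):
        X, time, event = simulate_aft_data(60, [0.4], 0.5, seed=2)
        for kind in ("cox_ph", "rsf", "surv_svm"):
            params = {"n_estimators": 50} if kind == "rsf" else {}
            model = make_model(kind, seed=0, **params).fit(X, time, event)
            pi = prognostic_index(model, np.vstack([X[:1], X[:1]]))
            assert pi[0] == pi[1]

    def test_rsf_pi_tracks_true_hazard_rank(self):
        rng = np.random.default_rng(31)
        n = 300
        X = rng.normal(size=(n, 3))
        hazard = X @ np.array([1.0, -1.0, 0.0])
        time = rng.exponential(np.exp(-hazard))
        model = make_model("rsf", seed=0, n_estimators=200).fit(X, time, np.ones(n, int))
        pi = prognostic_index(model, X)
        from scipy import stats as sps

        assert sps.spearmanr(pi, hazard).statistic > 0.5


@pytest.fixture(scope="module")
def planted_cohort():
    config = SimConfig(n_patients=70, n_samples=76, n_genes=40, n_prognostic=5,
                       block_size=14)
    cohort, truth = generate_cohort(config, seed=8)
    return cohort, truth


class TestEvaluateFeatureSet:
    def test_planted_signal_beats_chance_and_report_shape(self, planted_cohort):
        cohort, truth = planted_cohort
        features = list(truth.prognostic)
        metrics, strat = evaluate_feature_set(
            cohort, features, models=("cox_ph",), k=3, replicates=3, seed=0,
            feature_set_name="planted",
        )
        summary = summarize_metrics(metrics)
        assert summary.shape[0] == 1
        assert summary.loc[0, "cindex_mean"] > 0.6
        assert 0.0 <= summary.loc[0, "ibs_mean"] <= 1.0
        assert set(strat["n_groups"]) == {2, 3}

    def test_noise_features_score_near_chance(self, planted_cohort):
        cohort, truth = planted_cohort
        noise = [g for g in cohort.expression.gene_ids
                 if g not in truth.prognostic][:5]
        metrics, _ = evaluate_feature_set(
            cohort, noise, models=("cox_ph",), k=3, replicates=3, seed=1,
            feature_set_name="noise",
        )
        assert abs(metrics["cindex"].mean() - 0.5) < 0.1

    def test_all_model_kinds_produce_metrics(self, planted_cohort):
        cohort, truth = planted_cohort
        features = list(truth.prognostic)
        metrics, strat = evaluate_feature_set(
            cohort, features,
            models=("cox_ph", "elastic_cox", "rsf", "surv_svm"),
            k=2, replicates=1, seed=2, feature_set_name="planted",
            model_params={"rsf": {"n_estimators": 50}, "elastic_cox": {"lam": 0.1}},
        )
        assert set(metrics["model"]) == {"cox_ph", "elastic_cox", "rsf", "surv_svm"}
        assert metrics["cindex"].between(0, 1).all()
        assert metrics["ibs"].between(0, 1).all()
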