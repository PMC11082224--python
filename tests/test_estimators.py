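import numpy as np
import pytest

from activetest import (
    ContractError,
    ExperimentConfig,
    LabelLedger,
    LossSpec,
    MetricSpec,
    SamplingPlan,
    SyntheticSpec,
    UndefinedMetricError,
    aiipw_estimate,
    aiipw_ratio_metric,
    cross_entropy_loss,
    full_data_benchmark,
    generate_pool,
    ipw_oracle_estimate,
    lur_estimate,
    lur_weight,
    run_repetitions,
    weighted_curve_metrics,
)
from conftest import census_ledger


class TestLurWeight:
    @pytest.mark.parametrize(
        "N, s, j, expected",
        [
            (10, 1, 1, 1.0),
            (10, 2, 1, 8.0 / 9.0),
            (10000, 10, 5, 10000 * 9990 / (9995 * 9996)),
        ],
    )
    def test_printed_formula(self, N, s, j, expected):
        assert lur_weight(N, s, j) == pytest.approx(expected, rel=1e-12)

    def test_weight_tends_to_one_for_large_pools(self):
        assert lur_weight(10 ** 6, 10, 5) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("N, s, j", [(10, 2, 3), (10, 10, 1), (10, 0, 0)])
    def test_index_contract(self, N, s, j):
        with pytest.raises(ContractError):
            lur_weight(N, s, j)


def _four_record_ledger():
    """N=4, one step, records 0 and 1 labeled with pi = 0.5 and 0.25."""
    ledger = LabelLedger(4)
    mask = np.array([True, True, False, False])
    ledger.record_step(mask, np.array([0.5, 0.25]))
    ledger.set_estimated_probs(mask, np.array([0.5, 0.25]))
    return ledger


class TestLossEstimators:
    def test_lur_hand_evaluation(self):
        ledger = _four_record_ledger()
        losses = np.array([0.2, 0.4, np.nan, np.nan])
        assert lur_estimate(ledger, losses, "true") == pytest.approx(0.5)
        assert lur_estimate(ledger, losses, "estimated") == pytest.approx(0.5)

    def test_aiipw_hand_evaluation(self):
        ledger = _four_record_ledger()
        losses = np.array([0.2, 0.4, np.nan, np.nan])
        weights = np.array([0.5, 0.25, 1.0, 1.0])
        assert aiipw_estimate(ledger, losses, weights) == pytest.approx(0.5)
        assert ipw_oracle_estimate(ledger, losses, weights) == pytest.approx(0.5)

    def test_single_step_ipw_coincides_with_lur(self):
        # at s=1, w_1 = 1 and E{delta^1|g} = pi, so the two forms agree
        ledger = _four_record_ledger()
        losses = np.array([0.3, 0.7, np.nan, np.nan])
        ipw = ipw_oracle_estimate(ledger, losses, np.array([0.5, 0.25, 1, 1]))
        assert ipw == pytest.approx(lur_estimate(ledger, losses, "true"))

    def test_flat_weights_reduce_to_labeled_mean(self):
        n = 10
        ledger = LabelLedger(n)
        mask = np.zeros(n, dtype=bool)
        mask[:4] = True
        ledger.record_step(mask, np.full(4, 0.4))
        losses = np.full(n, np.nan)
        losses[:4] = [0.1, 0.2, 0.3, 0.4]
        est = aiipw_estimate(ledger, losses, np.full(n, 0.4))
        assert est == pytest.approx(np.mean([0.1, 0.2, 0.3, 0.4]))

    def test_missing_probability_is_contract_error(self):
        ledger = LabelLedger(4)
        ledger.record_step(np.array([True, False, False, False]), np.array([0.5]))
        with pytest.raises(ContractError):
            lur_estimate(ledger, np.zeros(4), "estimated")  # never stored

    def test_nonpositive_weight_is_contract_error(self):
        ledger = _four_record_ledger()
        with pytest.raises(ContractError):
            aiipw_estimate(ledger, np.zeros(4), np.array([0.0, 0.5, 1, 1]))

    def test_census_identity_for_all_estimators(self, fixture_pool):
        pool, bench = fixture_pool
        ledger = census_ledger(pool.n_records)
        losses = cross_entropy_loss(pool.scores, pool.full_labels())
        ones = np.ones(pool.n_records)
        assert lur_estimate(ledger, losses, "true") == pytest.approx(bench["cross_entropy"])
        assert lur_estimate(ledger, losses, "estimated") == pytest.approx(bench["cross_entropy"])
        assert aiipw_estimate(ledger, losses, ones) == pytest.approx(bench["cross_entropy"])

    def test_memory_contract_survives_history_loss(self):
        # AIIPW needs only (delta^s, weights, losses): wiping the per-step
        # probability history must not affect it
        ledger = _four_record_ledger()
        ledger.true_selection_prob[:] = np.nan
        ledger.estimated_selection_prob[:] = np.nan
        losses = np.array([0.2, 0.4, np.nan, np.nan])
        est = aiipw_estimate(ledger, losses, np.array([0.5, 0.25, 1, 1]))
        assert est == pytest.approx(0.5)


class TestRatioMetrics:
    def test_census_equals_full_data_benchmark(self, fixture_pool):
        pool, bench = fixture_pool
        ledger = census_ledger(pool.n_records)
        labels = pool.full_labels()
        ones = np.ones(pool.n_records)
        for name in ("TPR", "PPV", "F1"):
            est = aiipw_ratio_metric(ledger, MetricSpec(name), pool.scores, labels, ones)
            assert est == pytest.approx(bench[f"{name}@0.5"])

    def test_equal_weight_hand_count(self):
        ledger = LabelLedger(2)
        ledger.record_step(np.array([True, True]), np.array([0.5, 0.5]))
        est = aiipw_ratio_metric(ledger, MetricSpec("TPR"), np.array([0.9, 0.2]),
                                 np.array([1, 1]), np.full(2, 0.5))
        assert est == pytest.approx(0.5)

    def test_weight_rescaling_invariance(self, fixture_pool):
        pool, _ = fixture_pool
        ledger = census_ledger(pool.n_records)
        labels = pool.full_labels()
        w = np.linspace(0.2, 1.0, pool.n_records)
        a = aiipw_ratio_metric(ledger, MetricSpec("TPR"), pool.scores, labels, w)
        b = aiipw_ratio_metric(ledger, MetricSpec("TPR"), pool.scores, labels, 0.3 * w)
        assert a == pytest.approx(b)

    def test_zero_denominator_names_metric_and_step(self):
        ledger = LabelLedger(2)
        ledger.record_step(np.array([True, True]), np.array([0.5, 0.5]))
        with pytest.raises(UndefinedMetricError, match="TPR.*step 1"):
            aiipw_ratio_metric(ledger, MetricSpec("TPR"), np.array([0.9, 0.2]),
                               np.array([0, 0]), np.ones(2))


class TestWeightedCurveMetrics:
    def test_perfect_separation_auc_is_one(self):
        ledger = census_ledger(6)
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        auc, auprc = weighted_curve_metrics(ledger, scores, labels, np.ones(6))
        assert auc == pytest.approx(1.0)
        assert auprc == pytest.approx(1.0)

    def test_census_matches_pairwise_concordance_oracle(self):
        pool = generate_pool(SyntheticSpec(n_records=200, seed=3))
        ledger = census_ledger(200)
        y = pool.full_labels()
        auc, _ = weighted_curve_metrics(ledger, pool.scores, y, np.ones(200))
        pos, neg = pool.scores[y == 1], pool.scores[y == 0]
        conc = ((pos[:, None] > neg[None, :]).mean()
                + 0.5 * (pos[:, None] == neg[None, :]).mean())
        assert auc == pytest.approx(conc, abs=1e-9)

    def test_uninformative_scores_give_half_auc(self):
        rng = np.random.default_rng(12)
        n = 4000
        scores = rng.uniform(0.05, 0.95, n)
        labels = (rng.random(n) < 0.4).astype(int)
        ledger = census_ledger(n)
        auc, _ = weighted_curve_metrics(ledger, scores, labels, np.ones(n))
        assert auc == pytest.approx(0.5, abs=4 / np.sqrt(n))

    def test_single_class_is_undefined(self):
        ledger = census_ledger(3)
        with pytest.raises(UndefinedMetricError):
            weighted_curve_metrics(ledger, np.array([0.2, 0.5, 0.8]),
                                   np.array([1, 1, 1]), np.ones(3))


class TestUnbiasednessSimulation:
    def test_estimator_means_match_benchmark_under_entropy_sampling(self, packaged_pool):
        """Over repeated runs each estimator's mean tracks the full-data
        cross-entropy benchmark within Monte-Carlo resolution."""
        config = ExperimentConfig(
            plan=SamplingPlan(total_steps=2, expected_subsample_size=100),
            estimators=("LUR", "AILUR", "AIIPW", "IPW_oracle"),
            prob_update="Ori", repetitions=150, seed=10)
        result = run_repetitions(packaged_pool, config)
        bench = full_data_benchmark(packaged_pool, LossSpec("cross_entropy"))
        final = result.estimates[result.estimates.step == 2]
        for est, sub in final.groupby("estimator"):
            se = sub["value"].std() / np.sqrt(len(sub))
            assert abs(sub["value"].mean() - bench) <= 3 * se, est
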