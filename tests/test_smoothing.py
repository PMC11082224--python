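import numpy as np
import pytest

from activetest import (
    ContractError,
    KernelSpec,
    LabelLedger,
    estimate_cumulative_inclusion,
    estimate_step_selection_prob,
    nw_regress,
    silverman_bandwidth,
    true_cumulative_inclusion,
)
from activetest.smoothing import nw_self_regress


class TestNWRegress:
    def test_single_support_point_is_constant(self):
        out = nw_regress(np.array([0.7]), np.array([0.3]), np.array([0.0, 0.9]))
        np.testing.assert_allclose(out, 0.7)

    def test_flat_kernel_limit_is_mean(self):
        rng = np.random.default_rng(0)
        r = rng.random(50)
        x = rng.random(50)
        out = nw_regress(r, x, np.array([0.2, 0.8]), KernelSpec(bandwidth=1e6))
        np.testing.assert_allclose(out, r.mean(), atol=1e-6)

    def test_symmetric_supports_average_at_midpoint(self):
        out = nw_regress(np.array([0.0, 1.0]), np.array([-1.0, 1.0]),
                         np.array([0.0]), KernelSpec(bandwidth=0.5))
        assert out[0] == pytest.approx(0.5)

    def test_binary_responses_stay_in_unit_interval(self):
        rng = np.random.default_rng(3)
        r = (rng.random(200) < 0.4).astype(float)
        x = rng.random(200)
        out = nw_regress(r, x, np.linspace(0, 1, 50), KernelSpec(bandwidth=0.02))
        assert np.all(out >= 0) and np.all(out <= 1)

    def test_compact_kernel_zero_denominator_falls_back_to_mean(self):
        out = nw_regress(np.array([0.2, 0.6]), np.array([0.0, 0.1]),
                         np.array([5.0]), KernelSpec("epanechnikov", bandwidth=0.1))
        assert out[0] == pytest.approx(0.4)

    def test_empty_support_is_contract_error(self):
        with pytest.raises(ContractError):
            nw_regress(np.array([]), np.array([]), np.array([0.5]))

    def test_grid_evaluation_close_to_exact(self):
        rng = np.random.default_rng(4)
        x = rng.random(3000)
        r = (rng.random(3000) < x).astype(float)
        exact = nw_regress(r, x, x, KernelSpec(bandwidth=0.05))
        grid = nw_regress(r, x, x, KernelSpec(bandwidth=0.05, grid=256))
        assert np.max(np.abs(exact - grid)) < 1e-3


class TestSilvermanBandwidth:
    def test_hand_formula_on_balanced_binary_values(self):
        values = np.array([0.0] * 50 + [1.0] * 50)
        sd = np.std(values, ddof=1)
        expected = 0.9 * min(sd, 1.0 / 1.34) * 100 ** (-0.2)
        assert silverman_bandwidth(values) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_spread_warns_and_falls_back(self):
        with pytest.warns(UserWarning, match="spread"):
            b = silverman_bandwidth(np.full(10, 0.3))
        assert b > 0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.random(200)
        assert silverman_bandwidth(3.5 * x) == pytest.approx(3.5 * silverman_bandwidth(x))

    def test_too_few_values_is_contract_error(self):
        with pytest.raises(ContractError):
            silverman_bandwidth(np.array([0.2]))


def _ledger_with_new_selection(mask: np.ndarray, probs: np.ndarray) -> LabelLedger:
    ledger = LabelLedger(mask.size)
    ledger.record_step(mask, probs)
    return ledger


class TestStepSelectionProbability:
    def test_constant_covariate_collapses_to_proportion(self):
        mask = np.zeros(100, dtype=bool)
        mask[:30] = True
        ledger = _ledger_with_new_selection(mask, np.full(30, 0.3))
        _, est = estimate_step_selection_prob(ledger, np.full(100, 0.5), KernelSpec())
        np.testing.assert_allclose(est, 0.30, atol=1e-12)

    def test_flat_kernel_limit_is_overall_fraction(self):
        rng = np.random.default_rng(0)
        mask = np.zeros(200, dtype=bool)
        mask[rng.choice(200, 40, replace=False)] = True
        ledger = _ledger_with_new_selection(mask, np.full(40, 0.2))
        _, est = estimate_step_selection_prob(
            ledger, rng.random(200), KernelSpec(bandwidth=1e6))
        np.testing.assert_allclose(est, 0.2, atol=1e-6)

    def test_consistency_when_truth_is_the_score(self):
        # selections drawn with P(select | g) = g: Silverman-bandwidth NW
        # recovers the identity curve with small mean absolute error
        rng = np.random.default_rng(7)
        n = 5000
        g = rng.uniform(0.05, 0.95, n)
        sel = rng.random(n) < g
        ledger = _ledger_with_new_selection(sel, g[sel])
        _, est = estimate_step_selection_prob(ledger, g, KernelSpec())
        assert np.mean(np.abs(est - g)) < 0.05

    def test_estimates_stored_for_new_selections(self):
        mask = np.zeros(50, dtype=bool)
        mask[:10] = True
        ledger = _ledger_with_new_selection(mask, np.full(10, 0.2))
        estimate_step_selection_prob(ledger, np.linspace(0.1, 0.9, 50), KernelSpec())
        assert np.isfinite(ledger.estimated_selection_prob[:10]).all()
        assert np.isnan(ledger.estimated_selection_prob[10:]).all()


class TestCumulativeInclusion:
    def test_uniform_sampling_constant_covariate(self):
        mask = np.zeros(100, dtype=bool)
        mask[:25] = True
        ledger = _ledger_with_new_selection(mask, np.full(25, 0.25))
        est = estimate_cumulative_inclusion(ledger, np.full(100, 0.4), KernelSpec())
        np.testing.assert_allclose(est, 0.25, atol=1e-12)

    def test_flat_kernel_limit(self):
        rng = np.random.default_rng(2)
        mask = np.zeros(150, dtype=bool)
        mask[rng.choice(150, 30, replace=False)] = True
        ledger = _ledger_with_new_selection(mask, np.full(30, 0.2))
        est = estimate_cumulative_inclusion(ledger, rng.random(150),
                                            KernelSpec(bandwidth=1e6))
        np.testing.assert_allclose(est, 0.2, atol=1e-6)

    def test_no_labels_is_contract_error(self):
        with pytest.raises(ContractError):
            estimate_cumulative_inclusion(LabelLedger(10), np.linspace(0.1, 0.9, 10))

    def test_error_decreases_with_pool_size(self):
        errors = []
        for n, seed in [(500, 0), (2000, 1), (8000, 2)]:
            rng = np.random.default_rng(seed)
            g = rng.uniform(0.05, 0.95, n)
            sel = rng.random(n) < g
            ledger = _ledger_with_new_selection(sel, g[sel])
            est = estimate_cumulative_inclusion(ledger, g, KernelSpec())
            errors.append(np.mean(np.abs(est - g)))
        assert errors[0] > errors[1] > errors[2]


class TestTrueCumulativeInclusion:
    def test_constant_probability_closed_form(self):
        g = np.linspace(0.1, 0.9, 5)
        q = 0.2
        out = true_cumulative_inclusion([lambda _: np.full(5, q)] * 4, g)
        np.testing.assert_allclose(out, 1 - (1 - q) ** 4, atol=1e-12)

    def test_single_step_is_the_probability_itself(self):
        g = np.linspace(0.1, 0.9, 9)
        out = true_cumulative_inclusion([lambda z: z], g)
        np.testing.assert_allclose(out, g)

    def test_certain_first_step_is_absorbing(self):
        g = np.array([0.3, 0.6])
        out = true_cumulative_inclusion(
            [np.ones(2), np.full(2, 0.1), np.full(2, 0.5)], g)
        np.testing.assert_allclose(out, 1.0)

    def test_kernel_estimate_matches_recursion_on_simulated_run(self):
        # two uniform-probability steps on a large pool: NW estimate of the
        # cumulative indicator agrees with the exact product-form recursion
        rng = np.random.default_rng(8)
        n = 5000
        g = rng.uniform(0.05, 0.95, n)
        ledger = LabelLedger(n)
        q = 0.06
        for _ in range(2):
            unl = ~ledger.labeled_mask
            sel = unl & (rng.random(n) < q)
            ledger.record_step(sel, np.full(int(sel.sum()), q))
        est = estimate_cumulative_inclusion(ledger, g, KernelSpec())
        truth = true_cumulative_inclusion([np.full(n, q)] * 2, g)
        assert np.sqrt(np.mean((est - truth) ** 2)) < 0.05


class TestSelfWeightedRegression:
    def test_unit_self_weight_matches_plain_nw(self):
        rng = np.random.default_rng(9)
        x = rng.random(300)
        r = (rng.random(300) < 0.5).astype(float)
        spec = KernelSpec(bandwidth=0.05)
        np.testing.assert_allclose(nw_self_regress(r, x, spec),
                                   nw_regress(r, x, x, spec), atol=1e-12)

    def test_matched_self_weight_shrinks_own_indicator_pull(self):
        # at an isolated selected point the matched-weight estimate is
        # strictly below the full-self-inclusion estimate
        x = np.array([0.1, 0.11, 0.12, 0.5])
        r = np.array([0.0, 0.0, 0.0, 1.0])
        spec_full = KernelSpec(bandwidth=0.05)
        spec_matched = KernelSpec(bandwidth=0.05, self_weight="matched")
        assert nw_self_regress(r, x, spec_matched)[3] < nw_self_regress(r, x, spec_full)[3]
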