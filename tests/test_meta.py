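"""Inverse-variance pooling and heterogeneity statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ethnometa import EffectEstimate, estimate_from_ci, heterogeneity, i2_label, pool
from ethnometa.exceptions import PoolingError


def _est(log_or: float, se: float) -> EffectEstimate:
    return EffectEstimate(log_or=log_or, se=se)


class TestPool:
    def test_equal_weight_closed_form(self):
        result = pool([_est(0.1, 0.05), _est(0.1, 0.05)], model="random")
        assert result.pooled_log_or == pytest.approx(0.1)
        assert result.pooled_se == pytest.approx(0.035355, abs=1e-6)
        assert result.tau2 == 0.0

    def test_single_study_passes_through(self):
        est = estimate_from_ci(1.31, 1.20, 1.44)
        result = pool([est], model="random")
        assert result.pooled_log_or == est.log_or
        assert result.pooled_se == est.se
        assert result.k == 1
        assert result.q_stat == 0.0
        assert result.i2 == 0.0
        assert result.q_p is None
        assert result.ci_low < result.pooled_or < result.ci_high

    def test_two_study_panel_pools_toward_the_larger_study(self, pooled_by_snp):
        # big study OR 1.09 (1.06-1.12) dominates small OR 1.14 (0.99-1.31)
        result = pooled_by_snp["rs16861329"]
        assert round(result.pooled_or, 2) == 1.09
        assert result.k == 2

    def test_empty_list_rejected(self):
        with pytest.raises(PoolingError):
            pool([])

    def test_fixed_se_never_exceeds_inputs_and_random_never_below_fixed(self):
        estimates = [_est(0.0, 0.05), _est(0.3, 0.08), _est(-0.1, 0.2)]
        fixed = pool(estimates, model="fixed")
        random = pool(estimates, model="random")
        assert fixed.pooled_se <= min(e.se for e in estimates)
        assert random.pooled_se >= fixed.pooled_se

    @given(
        data=st.lists(
            st.tuples(st.floats(-1.0, 1.0), st.floats(0.02, 0.5)),
            min_size=2,
            max_size=6,
        ),
        seed=st.integers(0, 100),
    )
    def test_pooling_is_permutation_invariant(self, data, seed):
        estimates = [_est(t, s) for t, s in data]
        rng = np.random.default_rng(seed)
        shuffled = [estimates[i] for i in rng.permutation(len(estimates))]
        a = pool(estimates)
        b = pool(shuffled)
        assert a.pooled_log_or == pytest.approx(b.pooled_log_or, rel=1e-12)
        assert a.tau2 == pytest.approx(b.tau2, rel=1e-12, abs=1e-15)

    def test_random_equals_fixed_when_tau2_zero(self):
        estimates = [_est(0.10, 0.05), _est(0.11, 0.06), _est(0.09, 0.04)]
        random = pool(estimates, model="random")
        fixed = pool(estimates, model="fixed")
        assert random.tau2 == 0.0
        assert random.pooled_log_or == fixed.pooled_log_or
        assert random.pooled_se == fixed.pooled_se


class TestHeterogeneity:
    def test_identical_estimates_have_no_dispersion(self):
        het = heterogeneity([_est(0.2, 0.1)] * 3)
        assert het.q_stat == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0
        assert het.tau2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_equal_weight_case(self):
        # weights 400 each, grand mean 0.1: Q = 400*0.01*2 = 8, I2 = 7/8
        het = heterogeneity([_est(0.0, 0.05), _est(0.2, 0.05)])
        assert het.q_stat == pytest.approx(8.0)
        assert het.q_df == 1
        assert het.i2 == pytest.approx(0.875)

    def test_single_estimate_df_zero_convention(self):
        het = heterogeneity([_est(0.5, 0.1)])
        assert het == (0.0, 0, None, 0.0, 0.0, "negligible")

    def test_labels_follow_band_thresholds(self):
        assert i2_label(0.10) == "negligible"
        assert i2_label(0.30) == "minimal"
        assert i2_label(0.60) == "moderate"
        assert i2_label(0.90) == "high"


class TestAgainstIndependentImplementation:
    def test_dl_pool_matches_statsmodels(self):
        """Cross-check DerSimonian-Laird pooling against
        statsmodels.stats.meta_analysis.combine_effects."""
        from statsmodels.stats.meta_analysis import combine_effects

        log_ors = [0.10, 0.25, -0.05, 0.18]
        ses = [0.10, math.sqrt(0.02), math.sqrt(0.015), math.sqrt(0.008)]
        mine = pool([_est(t, s) for t, s in zip(log_ors, ses)], model="random")
        ref = combine_effects(np.array(log_ors), np.array(ses) ** 2, method_re="dl")
        frame = ref.summary_frame()
        assert mine.tau2 == pytest.approx(ref.tau2, rel=1e-10)
        assert mine.pooled_log_or == pytest.approx(
            frame.loc["random effect", "eff"], rel=1e-10
        )
        assert mine.pooled_se == pytest.approx(
            frame.loc["random effect", "sd_eff"], rel=1e-10
        )
        assert mine.q_stat == pytest.approx(ref.q, rel=1e-10)
        fixed = pool([_est(t, s) for t, s in zip(log_ors, ses)], model="fixed")
        assert fixed.pooled_log_or == pytest.approx(
            frame.loc["fixed effect", "eff"], rel=1e-10
        )

    def test_pooled_or_recovers_simulation_truth_without_heterogeneity(self):
        """With tau2 = 0 and large studies, the pooled OR lands within
        3 Monte-Carlo standard errors of the generating truth.

        The allelic analysis estimates the model's realized case-vs-control
        allelic log-OR (which exceeds ln(true_or) at 10% prevalence because
        controls are depleted of risk alleles), so that is the target.
        """
        from ethnometa import (
            SimulationConfig,
            estimate_from_record,
            implied_allelic_log_or,
            simulate_studies,
        )

        config = SimulationConfig(
            true_or=1.25, raf=0.3, tau2=0.0, seed=20240 + 7,
            n_cases_per_study=[20000] * 10,
        )
        records = simulate_studies(config)
        estimates = [estimate_from_record(r, fisher=False) for r in records]
        result = pool(estimates, model="random")
        truth = implied_allelic_log_or(0.3, 1.25, 0.10)
        assert result.pooled_log_or == pytest.approx(truth, abs=3 * result.pooled_se)
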