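"""Additive-model case-control power and sample size."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ethnometa import PowerSpec, case_control_freqs, power, sample_size
from ethnometa.exceptions import InfeasibleModelError, UnattainablePowerError


class TestCaseControlFreqs:
    def test_null_or_leaves_frequencies_at_raf(self):
        p_case, p_control = case_control_freqs(0.37, 1.0, 0.10)
        assert p_case == pytest.approx(0.37, abs=1e-12)
        assert p_control == pytest.approx(0.37, abs=1e-12)

    def test_agrees_with_allele_odds_approximation(self):
        # odds_case = odds_pop * OR gives 0.52153; the prevalence-constrained
        # model must land within 0.002 of it
        p_case, _ = case_control_freqs(0.5, 1.09, 0.10)
        approx = (0.5 / 0.5 * 1.09) / (1 + 0.5 / 0.5 * 1.09)
        assert approx == pytest.approx(0.52153, abs=1e-5)
        assert p_case == pytest.approx(approx, abs=0.002)

    def test_rare_disease_limit_controls_approach_population(self):
        _, p_control = case_control_freqs(0.3, 1.5, 1e-6)
        assert p_control == pytest.approx(0.3, abs=1e-5)

    def test_risk_ordering_under_positive_or(self):
        p_case, p_control = case_control_freqs(0.42, 1.29, 0.10)
        assert p_case > 0.42 > p_control

    def test_prevalence_too_large_for_or_is_infeasible(self):
        with pytest.raises(InfeasibleModelError):
            case_control_freqs(0.9, 50.0, 0.95)


class TestPower:
    @pytest.mark.parametrize(
        "or_alt, raf, n_cases, expected",
        [
            (1.09, 0.50, 2307, 0.54),
            (1.07, 0.14, 1670, 0.16),
        ],
    )
    def test_published_designs(self, or_alt, raf, n_cases, expected):
        result = power(PowerSpec(or_alt=or_alt, raf=raf, n_cases=n_cases))
        assert round(result.power, 2) == expected

    def test_null_alternative_power_equals_alpha(self):
        result = power(PowerSpec(or_alt=1.0, raf=0.3, n_cases=5000))
        assert result.power == pytest.approx(0.05, abs=1e-6)

    def test_power_increases_with_sample_size_toward_one(self):
        powers = [
            power(PowerSpec(or_alt=1.15, raf=0.3, n_cases=n)).power
            for n in (100, 500, 2000, 10000, 100000)
        ]
        assert powers == sorted(powers)
        assert powers[-1] > 0.999

    def test_power_increases_with_effect_size(self):
        powers = [
            power(PowerSpec(or_alt=o, raf=0.3, n_cases=2000)).power
            for o in (1.05, 1.10, 1.20, 1.40)
        ]
        assert powers == sorted(powers)

    @given(
        raf=st.floats(0.05, 0.95),
        log_or=st.floats(0.05, 0.5),
        n=st.integers(200, 5000),
    )
    def test_allele_relabelling_symmetry(self, raf, log_or, n):
        """Swapping which allele is 'risk' (raf -> 1-raf, OR -> 1/OR)
        cannot change the power of a two-sided test."""
        direct = power(PowerSpec(or_alt=math.exp(log_or), raf=raf, n_cases=n))
        relabelled = power(
            PowerSpec(or_alt=math.exp(-log_or), raf=1 - raf, n_cases=n)
        )
        assert direct.power == pytest.approx(relabelled.power, rel=1e-9)


class TestSampleSize:
    @pytest.mark.parametrize(
        "or_alt, raf, published",
        [
            (1.09, 0.50, 4231),
            (1.29, 0.42, 496),
        ],
    )
    def test_published_designs_within_five_percent(self, or_alt, raf, published):
        n = sample_size(PowerSpec(or_alt=or_alt, raf=raf))
        assert abs(n - published) / published < 0.05

    def test_large_effect_closed_form_oracle(self):
        # (z_.975 + z_.80)^2 [1/(p_c q_c) + 1/(p_0 q_0)] / (2 ln^2 1.5) ~ 195
        n = sample_size(PowerSpec(or_alt=1.5, raf=0.5))
        assert n == pytest.approx(195, abs=2)

    def test_minimality_round_trip(self):
        from dataclasses import replace

        spec = PowerSpec(or_alt=1.2, raf=0.3)
        n = sample_size(spec, target_power=0.80)
        assert power(replace(spec, n_cases=n)).power >= 0.80
        assert power(replace(spec, n_cases=n - 1)).power < 0.80

    def test_null_or_unattainable(self):
        with pytest.raises(UnattainablePowerError):
            sample_size(PowerSpec(or_alt=1.0, raf=0.3))


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"or_alt": -1.0, "raf": 0.5},
            {"or_alt": 1.1, "raf": 0.0},
            {"or_alt": 1.1, "raf": 0.5, "prevalence": 1.5},
            {"or_alt": 1.1, "raf": 0.5, "alpha": 0.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PowerSpec(**kwargs)
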