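"""Allele-count reconstruction, allelic ORs, CI-derived estimates."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from ethnometa import (
    AlleleTable,
    allelic_or,
    counts_from_raf,
    estimate_from_ci,
    weighted_raf,
)
from ethnometa.exceptions import DegenerateTableError, EstimateError


def fisher_p_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: sum hypergeometric outcomes with probability
    no greater than the observed table's, at fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    observed = hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


class TestCountsFromRaf:
    @pytest.mark.parametrize(
        "raf, n, expected",
        [
            (0.5, 100, (100, 100)),
            (0.31, 1000, (620, 1380)),
            (0.0, 50, (0, 100)),
            (1.0, 50, (100, 0)),
        ],
    )
    def test_examples(self, raf, n, expected):
        assert counts_from_raf(raf, n) == expected

    def test_half_counts_round_to_even(self):
        # 0.25 * 2*25 = 12.5 -> 12 (even), not 13
        assert counts_from_raf(0.25, 25) == (12, 38)

    def test_rejects_raf_outside_unit_interval(self):
        with pytest.raises(ValueError):
            counts_from_raf(1.2, 10)


class TestAllelicOr:
    def test_or_and_log_or_from_counts(self):
        est = allelic_or(AlleleTable(30, 70, 20, 80))
        assert est.odds_ratio == pytest.approx(1.7143, abs=1e-4)
        assert est.log_or == pytest.approx(0.5390, abs=1e-4)
        assert est.p_value == pytest.approx(
            fisher_p_by_enumeration(30, 70, 20, 80), rel=1e-9
        )

    def test_identical_margins_give_null_or_and_p_one(self):
        est = allelic_or(AlleleTable(50, 50, 50, 50))
        assert est.odds_ratio == pytest.approx(1.0)
        assert est.p_value == pytest.approx(1.0)

    def test_zero_cell_gets_haldane_anscombe_correction(self):
        est = allelic_or(AlleleTable(10, 0, 5, 5))
        assert est.odds_ratio == pytest.approx(21.0)

    def test_empty_column_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            allelic_or(AlleleTable(0, 10, 0, 10))

    def test_counts_route_reproduces_frequency_odds_ratio(self):
        # frequencies chosen so counts are exact: no rounding loss
        raf_cases, raf_controls, n = 0.30, 0.20, 1000
        table = AlleleTable.from_frequencies(raf_cases, raf_controls, n, n)
        expected = (raf_cases / (1 - raf_cases)) / (raf_controls / (1 - raf_controls))
        est = allelic_or(table)
        assert est.odds_ratio == pytest.approx(expected, rel=1e-6)

    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    def test_fisher_p_matches_enumeration(self, a, b, c, d):
        est = allelic_or(AlleleTable(a, b, c, d))
        assert est.p_value == pytest.approx(
            fisher_p_by_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
        )


class TestEstimateFromCi:
    def test_se_from_published_interval(self):
        est = estimate_from_ci(1.10, 1.07, 1.13)
        assert est.se == pytest.approx(0.013918, abs=1e-6)
        assert est.log_or == pytest.approx(math.log(1.10))

    def test_closed_form_interval(self):
        est = estimate_from_ci(math.e, 1.0, math.e**2)
        assert est.se == pytest.approx(2 / 3.919928, abs=1e-5)
        assert est.se == pytest.approx(0.51021, abs=1e-5)

    def test_zero_width_interval_rejected(self):
        with pytest.raises(EstimateError, match="zero-width"):
            estimate_from_ci(1.0, 1.0, 1.0)

    @given(
        log_or=st.floats(-1.5, 1.5),
        se=st.floats(0.01, 0.5),
    )
    def test_ci_round_trip(self, log_or, se):
        z = 1.959964
        lo, hi = math.exp(log_or - z * se), math.exp(log_or + z * se)
        est = estimate_from_ci(math.exp(log_or), lo, hi)
        back_lo, back_hi = est.confidence_interval()
        assert back_lo == pytest.approx(lo, abs=1e-4)
        assert back_hi == pytest.approx(hi, abs=1e-4)


class TestWeightedRaf:
    @pytest.mark.parametrize(
        "rafs, sizes, expected",
        [
            ((0.2, 0.4), (100, 300), 0.35),
            ((0.42, 0.42, 0.42), (10, 200, 3000), 0.42),
            ((0.73,), (55,), 0.73),
        ],
    )
    def test_examples(self, rafs, sizes, expected):
        assert weighted_raf(rafs, sizes) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_raf([], [])
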