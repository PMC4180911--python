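"""Converting study summaries into log odds-ratio effect estimates.

Two routes produce an :class:`EffectEstimate`, the common currency of the
pooling, comparison and scoring stages:

* **counts-derived** — reconstruct allele counts from case/control RAFs and
  sample sizes, form the 2x2 allelic table, compute the unadjusted allelic
  OR and a two-sided Fisher exact p-value;
* **ci-derived** — recover log-OR and SE from a published OR with its
  confidence interval (the only faithful route when a consortium publishes
  no variances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import two_sided_normal_p, z_quantile
from .exceptions import DegenerateTableError, EstimateError
from .io import StudyAssociation


@dataclass(frozen=True)
class AlleleTable:
    """2x2 table of risk/other allele counts in cases and controls."""

    case_risk: int
    case_other: int
    control_risk: int
    control_other: int

    def __post_init__(self) -> None:
        for name in ("case_risk", "case_other", "control_risk", "control_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_cases(self) -> int:
        return (self.case_risk + self.case_other) // 2

    @property
    def n_controls(self) -> int:
        return (self.control_risk + self.control_other) // 2

    @classmethod
    def from_frequencies(
        cls, raf_cases: float, raf_controls: float, n_cases: int, n_controls: int
    ) -> "AlleleTable":
        a, b = counts_from_raf(raf_cases, n_cases)
        c, d = counts_from_raf(raf_controls, n_controls)
        return cls(a, b, c, d)

    @classmethod
    def from_record(cls, record: StudyAssociation) -> "AlleleTable":
        if not record.has_counts:
            raise EstimateError(
                f"{record.snp_id} ({record.study_id}): case and control RAFs "
                "required to reconstruct allele counts"
            )
        return cls.from_frequencies(
            record.raf_cases, record.raf_controls, record.n_cases, record.n_controls
        )


@dataclass
class EffectEstimate:
    """A log odds ratio with its standard error.

    ``source`` records the derivation route (``counts-derived`` or
    ``ci-derived``); ``snp_id``/``risk_allele`` are optional identity tags
    used to guard cross-population comparisons.
    """

    log_or: float
    se: float
    p_value: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    source: str = "counts-derived"
    snp_id: str | None = None
    risk_allele: str | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise EstimateError(f"standard error must be positive, got {self.se}")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def variance(self) -> float:
        return self.se**2

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """CI on the OR scale at the given two-sided level."""
        z = z_quantile(1 - (1 - level) / 2)
        return math.exp(self.log_or - z * self.se), math.exp(self.log_or + z * self.se)


def counts_from_raf(raf: float, n_individuals: int) -> tuple[int, int]:
    """Risk/other allele counts implied by a RAF among 2n chromosomes.

    Fractional counts are rounded to the nearest integer with ties going to
    the even count (published frequencies rarely yield whole numbers).
    """
    if not 0.0 <= raf <= 1.0:
        raise ValueError(f"raf={raf} outside [0, 1]")
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    total = 2 * n_individuals
    risk = int(np.rint(raf * total))  # ties to even
    return risk, total - risk


def allelic_or(table: AlleleTable, *, fisher: bool = True) -> EffectEstimate:
    """Unadjusted allelic OR from a 2x2 allele-count table.

    When any cell is zero the Haldane–Anscombe correction (+0.5 to every
    cell) is applied to the OR and SE so single extreme studies remain
    poolable; the Fisher p-value is always computed on the raw counts.

    Parameters
    ----------
    fisher:
        Compute the two-sided Fisher exact p-value (sum of hypergeometric
        outcomes no more probable than the observed table).  Disable in
        tight simulation loops where only the Wald statistic is needed.
    """
    a, b, c, d = table.case_risk, table.case_other, table.control_risk, table.control_other
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DegenerateTableError(f"empty row or column in table {(a, b, c, d)}")
    p_value = None
    if fisher:
        _, p_value = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p_value = float(min(p_value, 1.0))
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        log_or=log_or,
        se=se,
        p_value=p_value,
        n_cases=table.n_cases,
        n_controls=table.n_controls,
        source="counts-derived",
    )


def estimate_from_ci(
    or_point: float,
    ci_low: float,
    ci_high: float,
    level: float = 0.95,
) -> EffectEstimate:
    """Recover (log-OR, SE) from a published OR and confidence interval.

    SE = [ln(hi) - ln(lo)] / (2 z), with the normal quantile held at six
    decimals (z_0.975 = 1.959964) so CI round-trips are stable.  The
    attached p-value is the two-sided normal (Wald) tail.
    """
    if not (0 < ci_low <= or_point <= ci_high):
        raise EstimateError(
            f"need 0 < ci_low <= OR <= ci_high, got ({ci_low}, {or_point}, {ci_high})"
        )
    if ci_low == ci_high:
        raise EstimateError("zero-width confidence interval gives SE 0")
    z = z_quantile(1 - (1 - level) / 2)
    log_or = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * z)
    return EffectEstimate(
        log_or=log_or,
        se=se,
        p_value=two_sided_normal_p(log_or / se),
        source="ci-derived",
    )


def estimate_from_record(
    record: StudyAssociation, *, fisher: bool = True, prefer: str = "ci"
) -> EffectEstimate:
    """Build an effect estimate from whichever data a record carries.

    ``prefer="ci"`` (default) uses the published OR+CI when present, falling
    back to reconstructed counts; ``prefer="counts"`` reverses the order.
    """
    has_ci = all(v is not None for v in (record.or_point, record.ci_low, record.ci_high))
    routes = ("ci", "counts") if prefer == "ci" else ("counts", "ci")
    for route in routes:
        if route == "ci" and has_ci:
            est = estimate_from_ci(record.or_point, record.ci_low, record.ci_high)
            break
        if route == "counts" and record.has_counts:
            est = allelic_or(AlleleTable.from_record(record), fisher=fisher)
            break
    else:  # pragma: no cover - guarded by StudyAssociation invariant
        raise EstimateError(f"{record.snp_id}: no usable effect information")
    est.snp_id = record.snp_id
    est.risk_allele = record.risk_allele
    est.n_cases = record.n_cases
    est.n_controls = record.n_controls
    return est


def weighted_raf(rafs: Sequence[float], sample_sizes: Sequence[int]) -> float:
    """Sample-size-weighted average RAF across reports."""
    if len(rafs) == 0 or len(rafs) != len(sample_sizes):
        raise ValueError("rafs and sample_sizes must be equal-length and non-empty")
    if any(n <= 0 for n in sample_sizes):
        raise ValueError("sample sizes must be positive")
    return float(np.average(np.asarray(rafs, dtype=float), weights=sample_sizes))
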