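"""Weighted genotype (population-burden) score.

The score summarises the aggregate load of a SNP panel on a population:

    score    = Σ ln(OR_i) × RAF_i
    variance = Σ RAF_i² × var[ln(OR_i)]

Using one population's ORs as shared weights for both populations makes the
score difference a pure function of RAF differences, which is the intended
contrast: do the populations carry different frequencies of the same risk
alleles, effect sizes held fixed?
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from ._util import two_sided_normal_p
from .exceptions import ScoreError


@dataclass
class GenotypeScore:
    """Weighted burden score and its variance for one population."""

    population: str
    score: float
    variance: float
    n_snps: int
    weights_source: str
    snp_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ScoreError("score variance cannot be negative")
        if self.n_snps < 1:
            raise ScoreError("a genotype score needs at least one SNP")


def genotype_score(ors: Sequence[float], rafs: Sequence[float]) -> float:
    """Σ ln(OR_i) × RAF_i over a SNP panel."""
    if len(ors) == 0 or len(ors) != len(rafs):
        raise ValueError("ors and rafs must be equal-length and non-empty")
    if any(o <= 0 for o in ors):
        raise ValueError("all ORs must be positive")
    if any(not 0.0 <= r <= 1.0 for r in rafs):
        raise ValueError("all RAFs must lie in [0, 1]")
    return float(sum(math.log(o) * r for o, r in zip(ors, rafs)))


def score_variance(rafs: Sequence[float], var_log_ors: Sequence[float]) -> float:
    """Σ RAF_i² × var[ln(OR_i)] over a SNP panel."""
    if len(rafs) != len(var_log_ors):
        raise ValueError("rafs and var_log_ors must be equal length")
    if any(v < 0 for v in var_log_ors):
        raise ValueError("variances cannot be negative")
    return float(sum(r**2 * v for r, v in zip(rafs, var_log_ors)))


def build_score(
    population: str,
    ors: Sequence[float],
    rafs: Sequence[float],
    var_log_ors: Sequence[float],
    weights_source: str,
    snp_ids: Sequence[str] | None = None,
) -> GenotypeScore:
    """Assemble a :class:`GenotypeScore` from per-SNP inputs."""
    return GenotypeScore(
        population=population,
        score=genotype_score(ors, rafs),
        variance=score_variance(rafs, var_log_ors),
        n_snps=len(ors),
        weights_source=weights_source,
        snp_ids=tuple(snp_ids) if snp_ids is not None else None,
    )


def compare_scores(a: GenotypeScore, b: GenotypeScore) -> tuple[float, float]:
    """Z test of two genotype scores built on the same panel and weights.

    Returns ``(z, p_value)``.  Raises :class:`ScoreError` when the scores
    were built on different SNP sets or weight sources, or when the total
    variance is zero.
    """
    if a.weights_source != b.weights_source:
        raise ScoreError(
            f"scores use different weights ({a.weights_source} vs {b.weights_source})"
        )
    if a.n_snps != b.n_snps:
        raise ScoreError("scores built on different numbers of SNPs")
    if (
        a.snp_ids is not None
        and b.snp_ids is not None
        and set(a.snp_ids) != set(b.snp_ids)
    ):
        raise ScoreError("scores built on different SNP sets")
    total_var = a.variance + b.variance
    if total_var <= 0:
        raise ScoreError("zero total variance: Z test undefined")
    z = (a.score - b.score) / math.sqrt(total_var)
    return z, two_sided_normal_p(z)
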