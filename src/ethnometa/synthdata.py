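"""Synthetic multi-study case-control summary data with known truth.

Each simulated study draws its own log odds ratio from
Normal(ln true_or, τ²), converts it to expected case/control risk-allele
frequencies under the prevalence-constrained log-additive model, and
samples allele counts binomially over 2n chromosomes.  The output records
carry realised RAFs so the whole pipeline — count reconstruction, allelic
ORs, pooling, comparison — can be exercised against a known generating
truth without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import StudyAssociation
from .power import case_control_freqs


@dataclass
class SimulationConfig:
    """Generating parameters for a set of case-control studies.

    ``tau2`` is the between-study variance of the log OR (0 = homogeneous
    studies).  The seed is mandatory: there is no global random state, and
    identical configs always produce identical tables.
    """

    true_or: float
    raf: float
    n_cases_per_study: Sequence[int]
    seed: int
    tau2: float = 0.0
    prevalence: float = 0.10
    control_ratio: float = 1.0
    k_studies: int | None = None
    snp_id: str = "rs0000001"
    gene: str | None = None
    population: str = "simulated"
    risk_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if self.k_studies is None:
            self.k_studies = len(self.n_cases_per_study)
        if self.k_studies != len(self.n_cases_per_study):
            raise ValueError(
                f"k_studies={self.k_studies} but {len(self.n_cases_per_study)} "
                "case counts supplied"
            )
        if self.k_studies < 1:
            raise ValueError("need at least one study")
        if self.tau2 < 0:
            raise ValueError("tau2 cannot be negative")
        if any(n <= 0 for n in self.n_cases_per_study):
            raise ValueError("case counts must be positive")


def simulate_studies(config: SimulationConfig) -> list[StudyAssociation]:
    """Draw one summary record per study under the configured truth."""
    rng = np.random.default_rng(config.seed)
    records = []
    for i, n_cases in enumerate(config.n_cases_per_study):
        theta = rng.normal(math.log(config.true_or), math.sqrt(config.tau2))
        p_case, p_control = case_control_freqs(
            config.raf, math.exp(theta), config.prevalence
        )
        n_controls = max(1, int(round(config.control_ratio * n_cases)))
        case_risk = int(rng.binomial(2 * n_cases, p_case))
        control_risk = int(rng.binomial(2 * n_controls, p_control))
        records.append(
            StudyAssociation(
                study_id=f"sim{i + 1:03d}",
                population=config.population,
                snp_id=config.snp_id,
                gene=config.gene,
                risk_allele=config.risk_allele,
                other_allele=config.other_allele,
                n_cases=n_cases,
                n_controls=n_controls,
                raf_cases=case_risk / (2 * n_cases),
                raf_controls=control_risk / (2 * n_controls),
            )
        )
    return records
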