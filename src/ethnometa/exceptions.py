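"""Exception hierarchy for ethnometa.

Every error raised deliberately by this package derives from
:class:`EthnometaError`, so callers can catch one type at pipeline level.
"""

from __future__ import annotations

from collections.abc import Sequence


class EthnometaError(Exception):
    """Base class for all ethnometa errors."""


class ConfigurationError(EthnometaError):
    """A table dialect or analysis config is unusable (e.g. missing column)."""


class TableValidationError(EthnometaError):
    """One or more rows of a study table failed validation.

    Parameters
    ----------
    problems:
        Human-readable messages, each naming the offending row.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class HarmonizationError(EthnometaError):
    """Risk alleles of two records/populations cannot be reconciled."""


class AmbiguousAlleleError(HarmonizationError):
    """Strand-ambiguous (A/T or C/G) SNPs that cannot be safely flipped."""

    def __init__(self, snp_ids: Sequence[str]):
        self.snp_ids = sorted(set(snp_ids))
        super().__init__(
            "strand-ambiguous SNP(s) cannot be harmonized: "
            + ", ".join(self.snp_ids)
        )


class DegenerateTableError(EthnometaError):
    """A 2x2 allele table has an empty row or column."""


class EstimateError(EthnometaError):
    """An effect estimate cannot be formed (e.g. zero-width CI)."""


class PoolingError(EthnometaError):
    """Meta-analysis input is empty or has non-positive standard errors."""


class InfeasibleModelError(EthnometaError):
    """No baseline risk satisfies the prevalence constraint."""


class UnattainablePowerError(EthnometaError):
    """Requested power cannot be reached (null alternative OR = 1)."""


class ScoreError(EthnometaError):
    """Genotype scores are not comparable (SNP set or weights mismatch)."""
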