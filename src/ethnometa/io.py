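"""Reading, writing and harmonizing study-level SNP summary tables.

The unit of data is one :class:`StudyAssociation`: a single study x SNP x
population summary record carrying sample sizes, risk-allele frequencies
(RAFs) and/or an odds ratio with its 95% CI.  Tables are plain delimited
text (comma or tab, auto-detected from the file extension) with a header
row; a *dialect* mapping lets foreign column layouts be read without
rewriting the file.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import (
    AmbiguousAlleleError,
    ConfigurationError,
    HarmonizationError,
    TableValidationError,
)

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
#: Allele pairs indistinguishable from their reverse-strand complement.
STRAND_AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))

#: Canonical column names, in the order tables are written.
CANONICAL_COLUMNS = (
    "study_id",
    "population",
    "snp_id",
    "gene",
    "chromosome",
    "risk_allele",
    "other_allele",
    "n_cases",
    "n_controls",
    "raf_cases",
    "raf_controls",
    "raf_combined",
    "or_point",
    "ci_low",
    "ci_high",
    "ld_group",
)

_REQUIRED = ("study_id", "population", "snp_id", "risk_allele", "n_cases", "n_controls")
_INT_FIELDS = ("n_cases", "n_controls")
_FLOAT_FIELDS = ("raf_cases", "raf_controls", "raf_combined", "or_point", "ci_low", "ci_high")
_RAF_FIELDS = ("raf_cases", "raf_controls", "raf_combined")


@dataclass
class StudyAssociation:
    """One study x SNP x population summary record.

    Frequencies are fractions in [0, 1]; percentages are rejected at parse
    time to avoid silent unit bugs.  At least one of the pair
    (``raf_cases`` & ``raf_controls``) or the triple (``or_point`` & CI)
    must be present so that an effect estimate can be formed downstream.
    """

    study_id: str
    population: str
    snp_id: str
    risk_allele: str
    n_cases: int
    n_controls: int
    other_allele: str | None = None
    gene: str | None = None
    chromosome: str | None = None
    raf_cases: float | None = None
    raf_controls: float | None = None
    raf_combined: float | None = None
    or_point: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ld_group: str | None = None

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_ALLELES:
            raise ValueError(f"risk_allele must be one of A/C/G/T, got {self.risk_allele!r}")
        if self.other_allele is not None:
            if self.other_allele not in VALID_ALLELES:
                raise ValueError(f"other_allele must be one of A/C/G/T, got {self.other_allele!r}")
            if self.other_allele == self.risk_allele:
                raise ValueError("risk_allele and other_allele must differ")
        for field in _INT_FIELDS:
            value = getattr(self, field)
            if not isinstance(value, int) or value <= 0:
                raise ValueError(f"{field} must be a positive integer, got {value!r}")
        for field in _RAF_FIELDS:
            value = getattr(self, field)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{field}={value!r} outside [0, 1]")
        for field in ("or_point", "ci_low", "ci_high"):
            value = getattr(self, field)
            if value is not None and value <= 0:
                raise ValueError(f"{field} must be positive, got {value!r}")
        if (
            self.or_point is not None
            and self.ci_low is not None
            and self.ci_high is not None
            and not (self.ci_low <= self.or_point <= self.ci_high)
        ):
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket OR {self.or_point}"
            )
        has_freqs = self.raf_cases is not None and self.raf_controls is not None
        has_or = all(v is not None for v in (self.or_point, self.ci_low, self.ci_high))
        if not (has_freqs or has_or):
            raise ValueError(
                "record needs case+control RAFs or an OR with its CI to be analysable"
            )

    @property
    def has_counts(self) -> bool:
        """Whether allele counts can be reconstructed (case & control RAFs)."""
        return self.raf_cases is not None and self.raf_controls is not None

    @property
    def raf(self) -> float | None:
        """Best available population RAF: combined, else control, else case."""
        for value in (self.raf_combined, self.raf_controls, self.raf_cases):
            if value is not None:
                return value
        return None

    def is_monomorphic(self) -> bool:
        """True if any reported frequency is exactly 0 or 1."""
        return any(
            getattr(self, field) in (0.0, 1.0)
            for field in _RAF_FIELDS
            if getattr(self, field) is not None
        )


def _resolve_dialect(columns: Sequence[str], dialect: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical field names to columns present in the file."""
    mapping = {name: name for name in CANONICAL_COLUMNS}
    if dialect:
        unknown = set(dialect) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ConfigurationError(f"dialect maps unknown field(s): {sorted(unknown)}")
        mapping.update(dialect)
    resolved = {field: col for field, col in mapping.items() if col in columns}
    missing = [field for field in _REQUIRED if field not in resolved]
    if missing:
        raise ConfigurationError(
            f"required column(s) not resolvable: {missing}; table has {list(columns)}"
        )
    return resolved


def _delimiter_for(path: Path | str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def parse_study_table(
    source: str | Path | IO[str],
    dialect: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
) -> list[StudyAssociation]:
    """Parse a delimited study table into :class:`StudyAssociation` records.

    Parameters
    ----------
    source:
        File path or open text stream with a header row.
    dialect:
        Optional mapping ``canonical_field -> column name in the file`` for
        tables whose headers differ from :data:`CANONICAL_COLUMNS`.
    delimiter:
        Override the delimiter; by default inferred from the extension
        (``.tsv``/``.tab``/``.txt`` -> tab, otherwise comma) or comma for
        streams.

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved.
    TableValidationError
        Listing every malformed cell/row (1-based data row numbers).
    """
    if delimiter is None:
        delimiter = _delimiter_for(source) if isinstance(source, (str, Path)) else ","
    frame = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    resolved = _resolve_dialect(list(frame.columns), dialect)

    records: list[StudyAssociation] = []
    problems: list[str] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        kwargs: dict[str, object] = {}
        row_ok = True
        for field, col in resolved.items():
            raw = row[col].strip() if isinstance(row[col], str) else row[col]
            if raw == "" or raw is None:
                continue
            if field in _INT_FIELDS:
                try:
                    kwargs[field] = int(raw)
                except ValueError:
                    problems.append(f"row {i}: {field}={raw!r} is not an integer")
                    row_ok = False
            elif field in _FLOAT_FIELDS:
                try:
                    value = float(raw)
                except ValueError:
                    problems.append(f"row {i}: {field}={raw!r} is not a number")
                    row_ok = False
                    continue
                if field in _RAF_FIELDS and not 0.0 <= value <= 1.0:
                    problems.append(
                        f"row {i}: {field}={value} outside [0, 1]; "
                        "frequencies must be fractions, not percentages"
                    )
                    row_ok = False
                    continue
                kwargs[field] = value
            else:
                kwargs[field] = str(raw)
        if not row_ok:
            continue
        try:
            records.append(StudyAssociation(**kwargs))  # type: ignore[arg-type]
        except (TypeError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise TableValidationError(problems)
    return records


def write_study_table(
    records: Iterable[StudyAssociation],
    path: str | Path,
    *,
    delimiter: str | None = None,
) -> None:
    """Write records as a delimited text table with canonical columns."""
    if delimiter is None:
        delimiter = _delimiter_for(path)
    rows = [
        {col: getattr(rec, col) for col in CANONICAL_COLUMNS} for rec in records
    ]
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    frame.to_csv(path, sep=delimiter, index=False)


def _is_strand_ambiguous(pair: frozenset[str]) -> bool:
    return pair in STRAND_AMBIGUOUS_PAIRS


def _flip(record: StudyAssociation, new_risk: str) -> StudyAssociation:
    """Re-express a record in terms of the opposite allele."""
    changes: dict[str, object] = {
        "risk_allele": new_risk,
        "other_allele": record.risk_allele,
    }
    if record.or_point is not None:
        changes["or_point"] = 1.0 / record.or_point
    if record.ci_low is not None and record.ci_high is not None:
        changes["ci_low"] = 1.0 / record.ci_high
        changes["ci_high"] = 1.0 / record.ci_low
    for field in _RAF_FIELDS:
        value = getattr(record, field)
        if value is not None:
            changes[field] = 1.0 - value
    return dataclasses.replace(record, **changes)


def harmonize_alleles(
    records: Iterable[StudyAssociation],
    reference_allele_map: Mapping[str, str],
) -> list[StudyAssociation]:
    """Align every record's risk allele with a reference allele per SNP.

    Records whose risk allele already matches the reference are returned
    unchanged.  Records reported on the opposite allele are flipped:
    OR -> 1/OR, CI -> (1/hi, 1/lo), every RAF -> 1 - RAF, alleles swapped.
    SNPs absent from ``reference_allele_map`` pass through untouched.

    Raises
    ------
    AmbiguousAlleleError
        For A/T or C/G SNPs that would need flipping: a flip cannot be told
        apart from a strand difference, so they are flagged, never flipped.
    HarmonizationError
        If the reference allele matches neither recorded allele of an
        unambiguous SNP.
    """
    out: list[StudyAssociation] = []
    ambiguous: list[str] = []
    for rec in records:
        ref = reference_allele_map.get(rec.snp_id)
        if ref is None or rec.risk_allele == ref:
            out.append(rec)
            continue
        pair = frozenset(
            {rec.risk_allele, rec.other_allele if rec.other_allele else ref}
        )
        if _is_strand_ambiguous(pair) or (
            rec.other_allele is not None
            and _is_strand_ambiguous(frozenset({rec.risk_allele, rec.other_allele}))
        ):
            ambiguous.append(rec.snp_id)
            continue
        if rec.other_allele is not None and ref != rec.other_allele:
            raise HarmonizationError(
                f"{rec.snp_id}: reference allele {ref} matches neither "
                f"{rec.risk_allele} nor {rec.other_allele}"
            )
        log.info("flipping %s in study %s to reference allele %s", rec.snp_id, rec.study_id, ref)
        out.append(_flip(rec, ref))
    if ambiguous:
        raise AmbiguousAlleleError(ambiguous)
    return out
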