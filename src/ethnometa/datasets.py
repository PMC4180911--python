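"""Packaged example datasets.

Three small tables ship with the package:

* ``table1_south_asian`` — per-study summary rows for nine SNPs discovered
  in South Asian genome-wide scans of type 2 diabetes (two multi-study
  SNP panels plus single-study signals), with published ORs and CIs.
* ``table1_diagram`` — the matching white-European (DIAGRAM consortium)
  summary rows for the eight of those SNPs that are polymorphic in
  Europeans (*SGCG* rs9552911 is monomorphic there and has no row).
* ``table2_gwas`` — fifteen established European GWAS signals with their
  discovery ORs, risk-allele frequencies and the South Asian case counts
  available for replication: the inputs of the power/sample-size table.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import StudyAssociation, parse_study_table


def fixture_path(name: str):
    """Traversable path of a packaged data file."""
    return resources.files("ethnometa").joinpath("data", name)


def load_table1_south_asian() -> list[StudyAssociation]:
    """South Asian per-study summary records (novel-SNP panel)."""
    with resources.as_file(fixture_path("table1_south_asian.csv")) as path:
        return parse_study_table(path)


def load_table1_diagram() -> list[StudyAssociation]:
    """White-European (DIAGRAM) summary records for the same SNPs."""
    with resources.as_file(fixture_path("table1_diagram.csv")) as path:
        return parse_study_table(path)


def load_table2_gwas() -> pd.DataFrame:
    """European GWAS signals with RAFs and South Asian case counts."""
    with resources.as_file(fixture_path("table2_gwas.csv")) as path:
        return pd.read_csv(path)
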