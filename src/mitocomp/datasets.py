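"""Bundled reference tables.

Two small published tables ship with the package: the annotation table of
the Bactrocera minax mitogenome (GenBank HM776033) and the per-gene
degenerate-site statistics for the ten-species tephritid comparison. Full
genome sequences are not bundled; ``scripts/fetch_genomes.py`` in the
source tree downloads the GenBank accessions for analyses that need them.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .genome import GeneFeature, read_gene_table


def _data_path(name: str) -> Path:
    return Path(resources.files("mitocomp") / "data" / name)


def bminax_gene_table_path() -> Path:
    return _data_path("bminax_gene_table.tsv")


def load_bminax_gene_table() -> tuple[list[GeneFeature], int]:
    """The B. minax annotation table (features sorted by start, circle length)."""
    features, length = read_gene_table(bminax_gene_table_path())
    assert length is not None
    return features, length


def class_stats_path() -> Path:
    return _data_path("tephritid_class_stats.tsv")


def load_class_stats() -> pd.DataFrame:
    """Per-gene class A+T, substitution-frequency, ratio and ASD columns."""
    return pd.read_csv(class_stats_path(), sep="\t", comment="#")


#: Column pairs of the standard correlation battery over the class-stats table.
STANDARD_CORRELATION_PAIRS = [
    ("AT_0F", "subst_0F"),
    ("AT_2F", "subst_2F"),
    ("AT_4F", "subst_4F"),
    ("AT_0F", "R_0F_all"),
    ("AT_0F", "ASD"),
    ("R_0F_all", "ASD"),
    ("AT_4F", "R_4F_all"),
    ("AT_4F", "ASD"),
    ("R_4F_all", "ASD"),
]
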