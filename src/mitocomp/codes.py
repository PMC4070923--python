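"""Genetic-code tables.

Thin wrapper around Biopython's NCBI codon tables exposing exactly what the
degeneracy and codon-usage machinery needs: a deterministic codon -> amino
acid map that includes stop codons, keyed by NCBI translation-table id.
Table 5 (invertebrate mitochondrial) is the package default because insect
mitogenomes are the primary use case; under it AGA/AGG encode Ser, ATA
encodes Met and TGA encodes Trp.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
STOP = "*"

#: All 64 codons in lexicographic order.
ALL_CODONS = tuple("".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3))

INVERTEBRATE_MITO = 5


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table: codon -> one-letter amino acid, '*' for stops."""

    table_id: int
    name: str
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code table {self.table_id} maps "
                f"{len(self.codon_to_aa)} codons, expected 64"
            )

    def translate_codon(self, codon: str) -> str:
        """Return the one-letter amino acid for ``codon`` ('*' for a stop).

        Raises ``ValueError`` on ambiguous or non-ACGT codons.
        """
        codon = codon.upper()
        try:
            return self.codon_to_aa[codon]
        except KeyError:
            raise ValueError(f"not an unambiguous DNA codon: {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)

    def translate(self, cds: str) -> str:
        """Translate a CDS (length trimmed to a codon multiple; stops as '*')."""
        seq = cds.upper()
        n = len(seq) - len(seq) % 3
        return "".join(self.translate_codon(seq[i : i + 3]) for i in range(0, n, 3))


@lru_cache(maxsize=None)
def genetic_code(table_id: int = INVERTEBRATE_MITO) -> GeneticCode:
    """Look up an NCBI translation table by id (default 5, invertebrate mito)."""
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        raise ValueError(f"unsupported NCBI translation table id: {table_id}") from None
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    return GeneticCode(
        table_id=table_id,
        name=table.names[0] if table.names else str(table_id),
        codon_to_aa=mapping,
        stop_codons=frozenset(table.stop_codons),
    )
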