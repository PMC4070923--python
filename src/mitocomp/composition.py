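"""Nucleotide composition and codon-usage statistics.

Insect mitogenomes are strongly A+T biased, and the bias is structured:
it is strongest at third codon positions and in the control region, and
the two strands differ in A vs T skew. These statistics, together with
relative synonymous codon usage (RSCU), summarise that structure.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .codes import ALL_CODONS, GeneticCode, genetic_code

BASES = "ACGT"

#: Amino acids whose codons are G+C-rich (all bases at the first two codon
#: positions are G or C) vs A+T-rich (first two positions A or T).
GC_RICH_AMINO_ACIDS = frozenset("PARG")  # Pro, Ala, Arg, Gly
AT_RICH_AMINO_ACIDS = frozenset("FIMYNK")  # Phe, Ile, Met, Tyr, Asn, Lys


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as composition tables are printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts for a region, with percentage accessors.

    N (ambiguous) characters are excluded from the percentage denominator
    and counted separately.
    """

    region: str
    counts: dict[str, int]
    n_ambiguous: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, base: str) -> float:
        return self.counts.get(base.upper(), 0) / self.total

    def percent(self, base: str, ndigits: int = 1) -> float:
        return round_half_up(100.0 * self.fraction(base), ndigits)

    @property
    def at_fraction(self) -> float:
        return (self.counts.get("A", 0) + self.counts.get("T", 0)) / self.total

    def at_percent(self, ndigits: int = 1) -> float:
        return round_half_up(100.0 * self.at_fraction, ndigits)

    def merged(self, other: "CompositionProfile", region: str | None = None) -> "CompositionProfile":
        """Count-weighted merge, equal to profiling the concatenation."""
        counts = Counter(self.counts)
        counts.update(other.counts)
        return CompositionProfile(
            region=region or f"{self.region}+{other.region}",
            counts=dict(counts),
            n_ambiguous=self.n_ambiguous + other.n_ambiguous,
        )


def base_composition(seq: str, region: str = "whole") -> CompositionProfile:
    """Exact base counts of a DNA string (Ns tallied separately)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counter = Counter(seq)
    bad = set(counter) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    counts = {b: counter.get(b, 0) for b in BASES}
    if sum(counts.values()) == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return CompositionProfile(region=region, counts=counts, n_ambiguous=counter.get("N", 0))


def composition_by_codon_position(
    cds_set: Iterable[str],
) -> dict[int, CompositionProfile]:
    """Composition at codon positions 1..3, tallied on the coding strand.

    Each CDS is trimmed to a codon multiple (a trailing incomplete stop
    codon is dropped).
    """
    tallies: dict[int, Counter] = {1: Counter(), 2: Counter(), 3: Counter()}
    any_codon = False
    for cds in cds_set:
        seq = cds.upper()
        if len(seq) < 3:
            raise ValueError("CDS shorter than one codon")
        n = len(seq) - len(seq) % 3
        any_codon = True
        for pos in (1, 2, 3):
            tallies[pos].update(seq[pos - 1 : n : 3])
    if not any_codon:
        raise ValueError("empty CDS set")
    out = {}
    for pos, counter in tallies.items():
        counts = {b: counter.get(b, 0) for b in BASES}
        out[pos] = CompositionProfile(
            region=f"codon_position_{pos}",
            counts=counts,
            n_ambiguous=counter.get("N", 0),
        )
    return out


@dataclass(frozen=True)
class CodonUsageTable:
    """Observed codon counts and RSCU grouped by synonymous family.

    ``table`` columns: codon, amino_acid, count, family_size, rscu.
    RSCU is NaN (undefined) for codons of families never observed; within
    every observed family the RSCU values average to 1.
    """

    table: pd.DataFrame
    code_id: int
    include_stops: bool

    def rscu_of(self, codon: str) -> float:
        row = self.table.loc[self.table["codon"] == codon.upper()]
        if row.empty:
            raise KeyError(f"codon {codon!r} not in table")
        return float(row["rscu"].iloc[0])

    def count_of(self, codon: str) -> int:
        row = self.table.loc[self.table["codon"] == codon.upper()]
        if row.empty:
            raise KeyError(f"codon {codon!r} not in table")
        return int(row["count"].iloc[0])


def count_codons(cds_set: Iterable[str], code: GeneticCode) -> Counter:
    """Codon counts over a CDS set; codons containing non-ACGT are skipped."""
    counts: Counter = Counter()
    for cds in cds_set:
        seq = cds.upper()
        n = len(seq) - len(seq) % 3
        for i in range(0, n, 3):
            codon = seq[i : i + 3]
            if set(codon) <= set(BASES):
                counts[codon] += 1
    return counts


def rscu(
    cds_set: Sequence[str],
    code: GeneticCode | None = None,
    include_stops: bool = False,
) -> CodonUsageTable:
    """Relative synonymous codon usage over a CDS set.

    RSCU(c) = count(c) * family_size / family_total, the observed count
    relative to uniform usage within the synonymous family. Stop codons
    are excluded by default; ``include_stops=True`` treats the stop codons
    as one family (the layout of published codon-usage tables that list
    UAA/UAG rows).
    """
    code = code or genetic_code()
    counts = count_codons(cds_set, code)

    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = code.translate_codon(codon)
        if aa == "*" and not include_stops:
            continue
        families.setdefault(aa, []).append(codon)

    rows = []
    for aa, codons in sorted(families.items()):
        size = len(codons)
        total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            value = counts.get(c, 0) * size / total if total > 0 else math.nan
            rows.append((c, aa, counts.get(c, 0), size, value))
    table = pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "family_size", "rscu"])
    return CodonUsageTable(table=table, code_id=code.table_id, include_stops=include_stops)


def gc_at_rich_codon_ratio(table: CodonUsageTable) -> float:
    """Ratio of codon counts for G+C-rich vs A+T-rich amino-acid families.

    Codons are counted by amino-acid family membership (Pro/Ala/Arg/Gly over
    Phe/Ile/Met/Tyr/Asn/Lys), so the ratio measures how the amino-acid
    composition responds to the genome's A+T mutational bias.
    """
    df = table.table
    gc = int(df.loc[df["amino_acid"].isin(GC_RICH_AMINO_ACIDS), "count"].sum())
    at = int(df.loc[df["amino_acid"].isin(AT_RICH_AMINO_ACIDS), "count"].sum())
    if at == 0:
        raise ZeroDivisionError("no codons for A+T-rich amino acids")
    return gc / at
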