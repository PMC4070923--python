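"""Circular mitogenome model: features, boundary arithmetic, sequence slicing.

Coordinates are 1-based inclusive throughout, matching the convention of
published mitogenome annotation tables. A feature whose ``end`` is smaller
than its ``start`` wraps the origin of the circle. Strands are named J
(majority) and N (minority); annotation tables that use F/R are normalised
on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from Bio import SeqIO

from .codes import GeneticCode, genetic_code

logger = logging.getLogger(__name__)

Strand = Literal["J", "N"]
Kind = Literal["PCG", "tRNA", "rRNA", "CR"]

STRAND_ALIASES = {"F": "J", "R": "N", "J": "J", "N": "N"}
KINDS = ("PCG", "tRNA", "rRNA", "CR")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A (circular) genome sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: unexpected characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature with 1-based inclusive circular coordinates."""

    name: str
    start: int
    end: int
    strand: Strand
    kind: Kind
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates must be >= 1")
        if self.strand not in ("J", "N"):
            raise ValueError(f"{self.name}: strand must be J or N, got {self.strand!r}")
        if self.kind not in KINDS:
            raise ValueError(f"{self.name}: kind must be one of {KINDS}")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int | None = None) -> int:
        """Feature length in bp; needs ``genome_length`` for origin-wrapping features."""
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError(f"{self.name} wraps the origin; genome length required")
        return self.end + genome_length - self.start + 1


@dataclass(frozen=True)
class BoundaryGap:
    """Signed gap between two features adjacent on the circle.

    Positive = intergenic spacer, negative = overlap, zero = abutting.
    """

    upstream: str
    downstream: str
    gap: int


@dataclass(frozen=True)
class BoundaryReport:
    """All adjacent-pair gaps around a fully annotated circle, with totals."""

    gaps: tuple[BoundaryGap, ...]
    genome_length: int

    def _select(self, sign: int) -> list[int]:
        return [g.gap for g in self.gaps if (g.gap > 0) == (sign > 0) and g.gap != 0]

    @property
    def spacers(self) -> tuple[BoundaryGap, ...]:
        return tuple(g for g in self.gaps if g.gap > 0)

    @property
    def overlaps(self) -> tuple[BoundaryGap, ...]:
        return tuple(g for g in self.gaps if g.gap < 0)

    @property
    def total_spacer_bp(self) -> int:
        return sum(self._select(+1))

    @property
    def spacer_count(self) -> int:
        return len(self._select(+1))

    @property
    def total_overlap_bp(self) -> int:
        return sum(-g for g in self._select(-1))

    @property
    def overlap_count(self) -> int:
        return len(self._select(-1))

    @property
    def max_spacer(self) -> int | None:
        s = self._select(+1)
        return max(s) if s else None

    @property
    def min_spacer(self) -> int | None:
        s = self._select(+1)
        return min(s) if s else None

    @property
    def max_overlap(self) -> int | None:
        s = self._select(-1)
        return max(-g for g in s) if s else None

    @property
    def min_overlap(self) -> int | None:
        s = self._select(-1)
        return min(-g for g in s) if s else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.upstream, g.downstream, g.gap) for g in self.gaps],
            columns=["upstream", "downstream", "gap"],
        )


class GeneTableError(ValueError):
    """A malformed annotation table (bad strand token, size mismatch, ...)."""


def read_gene_table(
    path: str | Path, genome_length: int | None = None
) -> tuple[list[GeneFeature], int | None]:
    """Read the TSV gene-table dialect.

    Columns: ``gene, strand, start, end, kind, [size], [anticodon]``; lines
    starting with ``#`` are comments, and a comment of the form
    ``# genome_length=N`` declares the circle length. A declared ``size``
    column must match the length computed from the coordinates.

    Returns features sorted by start and the genome length (or None if
    undeclared). Strand tokens F/R are normalised to J/N.
    """
    path = Path(path)
    declared_length = genome_length
    with path.open() as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#") and "genome_length=" in line:
            declared_length = int(line.split("genome_length=")[1].strip())
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    required = {"gene", "strand", "start", "end", "kind"}
    missing = required - set(table.columns)
    if missing:
        raise GeneTableError(f"{path}: missing columns {sorted(missing)}")

    features: list[GeneFeature] = []
    for row in table.itertuples(index=False):
        token = str(row.strand).strip()
        if token in ("", ".", "nan"):
            token = "J"  # unstranded features (the CR) sit on the reference strand
        if token not in STRAND_ALIASES:
            raise GeneTableError(f"{path}: unknown strand token {token!r} for {row.gene}")
        anticodon = getattr(row, "anticodon", None)
        if pd.isna(anticodon):
            anticodon = None
        feature = GeneFeature(
            name=str(row.gene),
            start=int(row.start),
            end=int(row.end),
            strand=STRAND_ALIASES[token],
            kind=str(row.kind),
            anticodon=anticodon,
        )
        if declared_length is not None and (
            feature.start > declared_length or feature.end > declared_length
        ):
            raise GeneTableError(
                f"{path}: {feature.name} coordinates exceed genome length {declared_length}"
            )
        declared_size = getattr(row, "size", None)
        if declared_size is not None and not pd.isna(declared_size):
            computed = feature.length(declared_length)
            if int(declared_size) != computed:
                raise GeneTableError(
                    f"{path}: {feature.name} declares size {int(declared_size)} "
                    f"but spans {computed} bp"
                )
        features.append(feature)
    features.sort(key=lambda f: f.start)
    return features, declared_length


_GENBANK_KINDS = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "CR",
    "misc_feature": "CR",
}


def read_genbank(path: str | Path) -> tuple[list[GeneFeature], GenomeRecord]:
    """Map CDS/tRNA/rRNA/D-loop features of a GenBank flat file onto GeneFeature."""
    record = SeqIO.read(str(path), "genbank")
    genome = GenomeRecord(id=record.id, sequence=str(record.seq).upper())
    features = []
    for feat in record.features:
        kind = _GENBANK_KINDS.get(feat.type)
        if kind is None:
            continue
        name = feat.qualifiers.get("gene", feat.qualifiers.get("product", [feat.type]))[0]
        features.append(
            GeneFeature(
                name=name,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="J" if feat.location.strand != -1 else "N",
                kind=kind,
            )
        )
    features.sort(key=lambda f: f.start)
    return features, genome


def parse_gene_table(
    path: str | Path, genome_length: int | None = None
) -> tuple[list[GeneFeature], GenomeRecord | int | None]:
    """Dispatch on file type: TSV dialect or GenBank flat file."""
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return read_genbank(path)
    return read_gene_table(path, genome_length=genome_length)


def _span(f: GeneFeature, genome_length: int) -> tuple[int, int]:
    end = f.end + genome_length if f.wraps_origin else f.end
    return f.start, end


def compute_boundaries(
    features: Sequence[GeneFeature], genome_length: int
) -> BoundaryReport:
    """Signed gaps between consecutive features around the circle.

    The gap between consecutive features f, g is ``start(g) - end(f) - 1``;
    the final pair wraps the origin. Input must be sorted by start and free
    of containment (one feature entirely inside another), which in an
    annotation table almost always signals a transcription error.
    """
    if not features:
        return BoundaryReport(gaps=(), genome_length=genome_length)
    starts = [f.start for f in features]
    if starts != sorted(starts):
        raise ValueError("features must be sorted by start coordinate")
    spans = [_span(f, genome_length) for f in features]
    for i, (si, ei) in enumerate(spans):
        for j, (sj, ej) in enumerate(spans):
            if i != j and si <= sj and ej <= ei:
                raise ValueError(
                    f"feature {features[j].name} is contained in {features[i].name}"
                )
    gaps = []
    for f, g in zip(features, features[1:]):
        gaps.append(BoundaryGap(f.name, g.name, g.start - f.end - 1))
    last, first = features[-1], features[0]
    wrap_end = last.end if not last.wraps_origin else last.end + genome_length
    wrap_gap = first.start + genome_length - wrap_end - 1
    gaps.append(BoundaryGap(last.name, first.name, wrap_gap))
    return BoundaryReport(gaps=tuple(gaps), genome_length=genome_length)


def extract_feature_sequence(genome: GenomeRecord, feature: GeneFeature) -> str:
    """Coding-strand sequence of a feature (reverse complement for N strand)."""
    L = genome.length
    if feature.start > L or feature.end > L:
        raise ValueError(f"{feature.name}: coordinates exceed genome length {L}")
    if feature.wraps_origin:
        raw = genome.sequence[feature.start - 1 :] + genome.sequence[: feature.end]
    else:
        raw = genome.sequence[feature.start - 1 : feature.end]
    return reverse_complement(raw) if feature.strand == "N" else raw


def start_stop_summary(
    pcg_sequences: dict[str, str], code: GeneticCode | None = None
) -> pd.DataFrame:
    """Start/stop codon table for a set of CDS sequences.

    Mitochondrial PCGs frequently end on an incomplete stop codon (T or TA)
    completed by polyadenylation of the transcript; the trailing 1-2 nt
    remainder after the last full codon is reported as an incomplete stop.
    A CDS whose length is a codon multiple must end on a stop codon of the
    given code to count as complete.
    """
    code = code or genetic_code()
    rows = []
    for gene, cds in pcg_sequences.items():
        seq = cds.upper()
        if len(seq) < 6:
            raise ValueError(f"{gene}: CDS shorter than 6 nt")
        start = seq[:3]
        remainder = len(seq) % 3
        if remainder:
            stop, complete = seq[-remainder:], False
        else:
            tail = seq[-3:]
            if code.is_stop(tail):
                stop, complete = tail, True
            else:
                # no in-frame stop at all: report the trailing codon, flagged
                stop, complete = tail, False
        rows.append((gene, start, stop, complete))
    return pd.DataFrame(rows, columns=["gene", "start_codon", "stop_codon", "stop_complete"])


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    with Path(path).open("w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
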