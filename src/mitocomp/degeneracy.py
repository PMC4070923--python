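"""Degenerate-site classification and per-class composition.

A codon position is 4-fold degenerate if all four nucleotides there keep
the encoded amino acid, 0-fold if any change alters it, and 2-fold
otherwise (positions where 2 or 3 nucleotides are synonymous share the
2-fold bin: the three-way 0/2/4 scheme has no 3-fold class, and 3-fold
positions do not occur under the invertebrate mitochondrial code anyway).
Stop-codon alternatives never count as preserving the amino acid.

Classification of an aligned ortholog set can follow two rules:

``concordant``
    a site keeps a class only if every species agrees on its fold at that
    aligned position; discordant sites are dropped from class statistics.
    This is the conservative choice for descriptive composition tables.
``reference``
    every site takes the fold computed from one reference species (by
    default the first). This is the right mode for substitution-rate
    estimation, because the concordance filter preferentially removes
    exactly the sites that substituted, biasing rates downward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np

from .codes import GeneticCode, genetic_code

logger = logging.getLogger(__name__)

FOLD_CLASSES = (0, 2, 4)
Assignment = Literal["concordant", "reference"]


def site_fold(codon: str, position: int, code: GeneticCode | None = None) -> int:
    """Degeneracy fold (0, 2 or 4) of one position of a sense codon.

    Counts how many of the four nucleotides at ``position`` (1-based,
    including the observed one) preserve the amino acid: 4 -> 4-fold,
    1 -> 0-fold, 2 or 3 -> 2-fold.
    """
    code = code or genetic_code()
    codon = codon.upper()
    if position not in (1, 2, 3):
        raise ValueError(f"position must be 1..3, got {position}")
    if set(codon) - set("ACGT") or len(codon) != 3:
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no degeneracy class")
    aa = code.translate_codon(codon)
    i = position - 1
    n = sum(
        1
        for base in "ACGT"
        if code.translate_codon(codon[:i] + base + codon[i + 1 :]) == aa
    )
    if n == 4:
        return 4
    if n == 1:
        return 0
    return 2


@lru_cache(maxsize=None)
def fold_table(code_id: int) -> dict[str, tuple[int, int, int]]:
    """Fold class of all three positions for every sense codon of a code."""
    code = genetic_code(code_id)
    return {
        codon: tuple(site_fold(codon, p, code) for p in (1, 2, 3))
        for codon in code.sense_codons()
    }


@dataclass(frozen=True)
class ClassifiedCodonSite:
    """One codon position of a gene with its degeneracy fold."""

    gene: str
    codon_index: int  # 0-based codon number
    position: int  # 1..3 within the codon
    fold: int

    @property
    def site_index(self) -> int:
        """0-based position in the CDS."""
        return 3 * self.codon_index + self.position - 1


def trim_cds(cds: str, code: GeneticCode | None = None) -> str:
    """Drop an incomplete trailing codon and a terminal stop codon."""
    code = code or genetic_code()
    seq = cds.upper()
    seq = seq[: len(seq) - len(seq) % 3]
    if len(seq) >= 3 and code.is_stop(seq[-3:]):
        seq = seq[:-3]
    return seq


def classify_gene(
    cds: str, code: GeneticCode | None = None, gene: str = ""
) -> list[ClassifiedCodonSite]:
    """Classify every position of every codon of a (trimmed) CDS.

    Codons containing ambiguous characters are skipped with a log line;
    an internal stop codon is an error naming the codon index.
    """
    code = code or genetic_code()
    seq = cds.upper()
    if len(seq) % 3:
        raise ValueError(f"{gene or 'CDS'}: length {len(seq)} is not a codon multiple")
    folds = fold_table(code.table_id)
    sites: list[ClassifiedCodonSite] = []
    for idx in range(len(seq) // 3):
        codon = seq[3 * idx : 3 * idx + 3]
        if set(codon) - set("ACGT"):
            logger.info("%s: skipping ambiguous codon %s at index %d", gene, codon, idx)
            continue
        if code.is_stop(codon):
            raise ValueError(f"{gene or 'CDS'}: internal stop codon {codon} at codon index {idx}")
        for pos in (1, 2, 3):
            sites.append(ClassifiedCodonSite(gene, idx, pos, folds[codon][pos - 1]))
    return sites


def class_site_map(
    ortholog_cds: Mapping[str, str],
    code: GeneticCode | None = None,
    assignment: Assignment = "concordant",
    reference: str | None = None,
) -> dict[int, list[int]]:
    """Assign each aligned CDS site to a fold class across species.

    Returns ``{fold: [0-based site indices]}``. Sites inside codons with
    ambiguous characters (in any species, for concordant assignment; in the
    reference, for reference assignment) are left unassigned.
    """
    code = code or genetic_code()
    if not ortholog_cds:
        raise ValueError("empty ortholog set")
    lengths = {len(s) for s in ortholog_cds.values()}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
    (length,) = lengths
    if length % 3:
        raise ValueError(f"aligned length {length} is not a codon multiple")
    folds = fold_table(code.table_id)
    species = list(ortholog_cds)

    def codon_folds(seq: str, idx: int) -> tuple[int, int, int] | None:
        codon = seq[3 * idx : 3 * idx + 3]
        if set(codon) - set("ACGT") or code.is_stop(codon):
            return None
        return folds[codon]

    sites: dict[int, list[int]] = {f: [] for f in FOLD_CLASSES}
    if assignment == "reference":
        ref = reference or species[0]
        if ref not in ortholog_cds:
            raise KeyError(f"reference species {ref!r} not in ortholog set")
        seq = ortholog_cds[ref].upper()
        for idx in range(length // 3):
            cf = codon_folds(seq, idx)
            if cf is None:
                continue
            for pos in (1, 2, 3):
                sites[cf[pos - 1]].append(3 * idx + pos - 1)
    elif assignment == "concordant":
        seqs = [ortholog_cds[s].upper() for s in species]
        for idx in range(length // 3):
            per_species = [codon_folds(s, idx) for s in seqs]
            if any(cf is None for cf in per_species):
                continue
            for pos in (1, 2, 3):
                classes = {cf[pos - 1] for cf in per_species}  # type: ignore[index]
                if len(classes) == 1:
                    sites[classes.pop()].append(3 * idx + pos - 1)
    else:
        raise ValueError(f"unknown assignment rule {assignment!r}")
    return sites


@dataclass(frozen=True)
class ClassComposition:
    """A+T content at the sites of one fold class, per species and averaged."""

    gene: str
    fold: int
    per_species: dict[str, float]  # species -> A+T fraction
    n_sites: int

    @property
    def defined(self) -> bool:
        return self.n_sites > 0

    @property
    def mean_at_percent(self) -> float:
        if not self.defined:
            raise ValueError(f"{self.gene}: no sites in the {self.fold}-fold class")
        return 100.0 * float(np.mean(list(self.per_species.values())))

    @property
    def sd_at_percent(self) -> float:
        """Sample SD (n-1) across species, as comparative tables report it."""
        if not self.defined:
            raise ValueError(f"{self.gene}: no sites in the {self.fold}-fold class")
        values = list(self.per_species.values())
        if len(values) < 2:
            return 0.0
        return 100.0 * float(np.std(values, ddof=1))


def class_composition(
    ortholog_cds: Mapping[str, str],
    code: GeneticCode | None = None,
    assignment: Assignment = "concordant",
    reference: str | None = None,
    gene: str = "",
) -> dict[int, ClassComposition]:
    """Per-class A+T fraction for each species, over codon-aligned orthologs.

    The per-species A+T fraction is computed over the sites assigned to the
    class; the mean and SD across species are what comparative tables print
    as ``mean ± SD``. A class with zero assigned sites is returned with
    ``defined == False`` rather than a zero value.
    """
    code = code or genetic_code()
    sites = class_site_map(ortholog_cds, code, assignment=assignment, reference=reference)
    out: dict[int, ClassComposition] = {}
    for fold, idxs in sites.items():
        per_species: dict[str, float] = {}
        if idxs:
            for species, seq in ortholog_cds.items():
                s = seq.upper()
                bases = [s[i] for i in idxs if s[i] in "ACGT"]
                if not bases:
                    continue
                per_species[species] = sum(b in "AT" for b in bases) / len(bases)
        out[fold] = ClassComposition(
            gene=gene, fold=fold, per_species=per_species, n_sites=len(idxs)
        )
    return out
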