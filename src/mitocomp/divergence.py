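"""Substitution-frequency and amino-acid-distance estimation.

The per-class "nucleotide substitution frequency" of a gene is the mean
pairwise Jukes-Cantor-corrected distance over all unordered species pairs,
restricted to the sites of one degeneracy class. JC is the minimal
multiple-hit correction consistent with class frequencies above 1
substitution per site, which raw p-distances cannot reach. Class ratios
(R_0F/all, R_4F/all) are built from raw pairwise difference counts instead:
counts stay well defined near saturation and make the three ratios sum to
one exactly. Amino-acid divergence uses the Poisson correction
``d = -ln(1 - p)`` and is summarised as ASD, the mean over all pairs.
Gap/ambiguous positions are excluded pairwise throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .codes import GeneticCode, genetic_code
from .degeneracy import Assignment, class_site_map

logger = logging.getLogger(__name__)

#: p at or above which the JC transform is undefined/saturated.
JC_SATURATION = 0.75

VALID_NT = frozenset("ACGT")


class SaturationError(ValueError):
    """All pairwise comparisons are saturated; no distance can be estimated."""


def pairwise_class_p_distance(
    a: str, b: str, sites: Sequence[int]
) -> tuple[float, int, int]:
    """Proportion of differing sites between two aligned CDS, over ``sites``.

    Positions where either sequence has a gap or ambiguous character are
    excluded pairwise. Returns ``(p, n_compared, n_differences)``.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences are not aligned: {len(a)} vs {len(b)}")
    if not sites:
        raise ValueError("empty site set")
    sa, sb = a.upper(), b.upper()
    compared = diffs = 0
    for i in sites:
        x, y = sa[i], sb[i]
        if x in VALID_NT and y in VALID_NT:
            compared += 1
            diffs += x != y
    if compared == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return diffs / compared, compared, diffs


def jukes_cantor(p: float) -> float:
    """JC69 corrected distance ``d = -(3/4) ln(1 - 4p/3)``; saturates at p >= 0.75."""
    if p < 0:
        raise ValueError(f"p must be non-negative, got {p}")
    if p >= JC_SATURATION:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class ClassSubstitutionStats:
    """Per-pair corrected distances at the sites of one fold class."""

    gene: str
    fold: int
    pair_distances: dict[tuple[str, str], float]
    raw_substitutions: int  # summed pairwise difference counts
    n_sites: int
    n_saturated_pairs: int = 0

    @property
    def frequency(self) -> float:
        """Mean corrected distance over non-saturated pairs: substitutions/site."""
        finite = [d for d in self.pair_distances.values() if math.isfinite(d)]
        if not finite:
            raise SaturationError(
                f"{self.gene} {self.fold}-fold: every species pair is saturated"
            )
        return float(np.mean(finite))


def class_substitution_frequency(
    ortholog_cds: Mapping[str, str],
    fold: int,
    code: GeneticCode | None = None,
    assignment: Assignment = "concordant",
    reference: str | None = None,
    correction: str = "JC",
    gene: str = "",
    sites: Sequence[int] | None = None,
) -> ClassSubstitutionStats:
    """Mean pairwise distance at the sites of one degeneracy class.

    ``correction`` is "JC" (default) or "none" (raw p-distance). Pairs with
    p at or beyond the JC saturation bound are flagged and excluded from
    the mean with a warning. ``sites`` overrides the class-site assignment
    (used when the caller has already computed the site map).
    """
    code = code or genetic_code()
    if len(ortholog_cds) < 2:
        raise ValueError("need at least two species")
    if correction not in ("JC", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if sites is None:
        site_map = class_site_map(
            ortholog_cds, code, assignment=assignment, reference=reference
        )
        sites = site_map[fold]
    if not sites:
        raise ValueError(f"{gene or 'gene'}: no sites in the {fold}-fold class")

    distances: dict[tuple[str, str], float] = {}
    total_diffs = 0
    saturated = 0
    for sp1, sp2 in combinations(ortholog_cds, 2):
        p, _, diffs = pairwise_class_p_distance(ortholog_cds[sp1], ortholog_cds[sp2], sites)
        total_diffs += diffs
        if correction == "none":
            distances[(sp1, sp2)] = p
        else:
            d = jukes_cantor(p)
            if math.isinf(d):
                saturated += 1
                logger.warning(
                    "%s %d-fold: pair (%s, %s) saturated (p=%.3f), excluded",
                    gene, fold, sp1, sp2, p,
                )
            distances[(sp1, sp2)] = d
    return ClassSubstitutionStats(
        gene=gene,
        fold=fold,
        pair_distances=distances,
        raw_substitutions=total_diffs,
        n_sites=len(sites),
        n_saturated_pairs=saturated,
    )


def gene_class_profile(
    ortholog_cds: Mapping[str, str],
    code: GeneticCode | None = None,
    assignment: Assignment = "concordant",
    reference: str | None = None,
    correction: str = "JC",
    gene: str = "",
) -> dict[int, ClassSubstitutionStats]:
    """Substitution statistics for all three fold classes of one gene.

    The class-site assignment is computed once and shared, so the three
    results partition the same site universe (which is what makes the
    downstream ratios meaningful).
    """
    code = code or genetic_code()
    site_map = class_site_map(ortholog_cds, code, assignment=assignment, reference=reference)
    return {
        fold: class_substitution_frequency(
            ortholog_cds, fold, code,
            correction=correction, gene=gene, sites=site_map[fold],
        )
        for fold in (0, 2, 4)
    }


@dataclass(frozen=True)
class ClassSubstitutionRatio:
    """Share of raw substitutions in each class, out of all degenerate classes."""

    gene: str
    ratios: dict[int, float]  # fold -> share, summing to 1

    @property
    def r0f_all(self) -> float:
        return self.ratios[0]

    @property
    def r4f_all(self) -> float:
        return self.ratios[4]


def class_ratios(stats: Mapping[int, ClassSubstitutionStats]) -> ClassSubstitutionRatio:
    """R_xF/all from summed raw pairwise difference counts of each class."""
    missing = {0, 2, 4} - set(stats)
    if missing:
        raise ValueError(f"missing fold classes: {sorted(missing)}")
    counts = {fold: stats[fold].raw_substitutions for fold in (0, 2, 4)}
    total = sum(counts.values())
    if total == 0:
        raise ZeroDivisionError("no substitutions in any degeneracy class")
    gene = stats[0].gene
    return ClassSubstitutionRatio(gene=gene, ratios={f: c / total for f, c in counts.items()})


VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def poisson_aa_distance(protein_a: str, protein_b: str) -> float:
    """Poisson-corrected distance between aligned proteins: ``-ln(1 - p)``.

    p is the proportion of differing residues after pairwise exclusion of
    gaps/ambiguities; p = 1 (no shared residue) has infinite distance and
    raises.
    """
    if len(protein_a) != len(protein_b):
        raise ValueError(f"proteins are not aligned: {len(protein_a)} vs {len(protein_b)}")
    a, b = protein_a.upper(), protein_b.upper()
    compared = diffs = 0
    for x, y in zip(a, b):
        if x in VALID_AA and y in VALID_AA:
            compared += 1
            diffs += x != y
    if compared == 0:
        raise ValueError("no comparable residues after pairwise deletion")
    p = diffs / compared
    if p >= 1.0:
        raise SaturationError("proteins share no residue: Poisson distance is infinite")
    return -math.log1p(-p)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with its overall mean (ASD)."""

    species: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.species)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match species list")

    def distance(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        return float(self.matrix[i, j])

    @property
    def asd(self) -> float:
        """Mean of the upper triangle: the overall average sequence distance."""
        iu = np.triu_indices(len(self.species), k=1)
        return float(np.mean(self.matrix[iu]))


def overall_asd(ortholog_proteins: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise Poisson distances for >= 2 aligned proteins, plus their mean."""
    if len(ortholog_proteins) < 2:
        raise ValueError("need at least two species")
    species = tuple(ortholog_proteins)
    n = len(species)
    matrix = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = poisson_aa_distance(ortholog_proteins[species[i]], ortholog_proteins[species[j]])
        matrix[i, j] = matrix[j, i] = d
    return DistanceMatrix(species=species, matrix=matrix)
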