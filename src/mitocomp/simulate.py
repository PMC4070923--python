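"""Synthetic mitogenomes and ortholog sets with known ground truth.

Two generators make every pipeline stage testable without downloads:

``simulate_genome``
    a circular genome whose annotation table reproduces planted overlap
    and spacer totals, with a control region carrying a planted poly(T)
    run, tandem repeat and spacer counterpart at recorded coordinates.

``simulate_ortholog_set``
    codon sequences for several species evolved independently from a
    common root (a star phylogeny) with separately controlled substitution
    rates at 0-, 2- and 4-fold degenerate sites and controlled A+T bias
    per site class. On a star the expected pairwise distance at a class is
    analytic: twice the per-branch class rate, which is what makes
    parameter-recovery checks sharp. Substitution events are Poisson per
    site with uniform replacement; an event that would create a stop codon
    is redrawn, keeping every sequence translatable.

All randomness flows from one integer seed; per-gene and per-species
streams are derived deterministically, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .codes import GeneticCode, genetic_code
from .degeneracy import fold_table
from .genome import GeneFeature, GenomeRecord

BASES = "ACGT"


@dataclass(frozen=True)
class GeneSpec:
    """One simulated feature: PCG sizes are given in codons, others in bp."""

    name: str
    n_codons: int = 0
    length_bp: int = 0  # used for non-PCG features
    strand: str = "J"
    kind: str = "PCG"

    @property
    def length(self) -> int:
        return 3 * self.n_codons if self.kind == "PCG" else self.length_bp


@dataclass(frozen=True)
class CRSpec:
    """Planted control-region features (offsets are 0-based within the CR)."""

    length: int = 1141
    polyt_offset: int = 1071
    polyt_run: int = 24
    taa_stretch: str = "TATATAATAA"  # planted just downstream of the poly(T)
    tandem_unit: str = "CCTTTTAAATTTTCC"
    tandem_copies: int = 3
    tandem_offset: int = 955
    counterpart_offset: int = 760
    counterpart_length: int = 15


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generators.

    Defaults mirror a tephritid-like comparison: 10 species, 500-codon
    genes, per-branch substitution rates 0.02 / 0.2 / 0.8 at 0-, 2- and
    4-fold degenerate sites, and A+T bias rising with degeneracy
    (0.65 / 0.78 / 0.85), echoing the strong third-position A+T bias of
    insect mitochondrial protein-coding genes.
    """

    seed: int = 0
    n_species: int = 10
    genes: tuple[GeneSpec, ...] = (GeneSpec("gene1", n_codons=500),)
    rates: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.02, 2: 0.2, 4: 0.8}
    )
    at_bias: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.65, 2: 0.78, 4: 0.85}
    )
    code_id: int = 5
    genome_at: float = 0.70
    # signed gap after each feature (the last entry closes the circle to
    # the first feature); length must equal number of features incl. CR
    gene_gaps: tuple[int, ...] | None = None
    cr: CRSpec = field(default_factory=CRSpec)

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("substitution rates must be >= 0")
        if any(not 0 <= b <= 1 for b in self.at_bias.values()):
            raise ValueError("A+T bias must lie in [0, 1]")


def _gene_rng(cfg: SimulationConfig, gene: str, stream: str = "") -> np.random.Generator:
    key = zlib.crc32(f"{gene}/{stream}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, key]))


def _random_dna(rng: np.random.Generator, length: int, at_fraction: float) -> str:
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    return "".join(rng.choice(list(BASES), size=length, p=[p_at, p_gc, p_gc, p_at]))


@dataclass(frozen=True)
class SimulatedGenome:
    genome: GenomeRecord
    features: list[GeneFeature]
    ground_truth: dict

    def ground_truth_json(self) -> str:
        return json.dumps(self.ground_truth, indent=2, sort_keys=True)


def simulate_genome(cfg: SimulationConfig) -> SimulatedGenome:
    """Build a circular genome realising the planted gene-table layout.

    Features are laid head to tail with the configured signed gaps
    (negative = planted overlap, positive = planted spacer); the CR is
    appended as the final feature and carries the planted motifs. With zero
    genes the genome is a single CR covering the whole circle.
    """
    rng = _gene_rng(cfg, "__genome__")
    specs = list(cfg.genes)
    n_features = len(specs) + 1  # + CR
    gaps = cfg.gene_gaps
    if gaps is None:
        gaps = tuple([0] * n_features)
    if len(gaps) != n_features:
        raise ValueError(
            f"gene_gaps must have one entry per feature incl. CR "
            f"({n_features}), got {len(gaps)}"
        )

    features: list[GeneFeature] = []
    pos = 1
    for spec, gap in zip(specs, gaps[:-1]):
        if spec.length <= 0:
            raise ValueError(f"{spec.name}: non-positive length")
        end = pos + spec.length - 1
        features.append(GeneFeature(spec.name, pos, end, spec.strand, spec.kind))
        pos = end + gap + 1
    cr_start = pos
    cr_end = cr_start + cfg.cr.length - 1
    features.append(GeneFeature("CR", cr_start, cr_end, "J", "CR"))
    genome_length = cr_end + gaps[-1]
    for f in features:
        if f.end > genome_length:
            raise ValueError(f"feature {f.name} exceeds genome length {genome_length}")

    sequence = list(_random_dna(rng, genome_length, cfg.genome_at))

    def plant(start0: int, motif: str) -> None:
        if start0 < 0 or start0 + len(motif) > cfg.cr.length:
            raise ValueError("planted feature does not fit within the CR")
        for i, c in enumerate(motif):
            sequence[cr_start - 1 + start0 + i] = c

    cr = cfg.cr
    plant(cr.polyt_offset, "T" * cr.polyt_run)
    # break up accidental extension of the planted run
    if cr.polyt_offset > 0:
        plant(cr.polyt_offset - 1, "A")
    end_off = cr.polyt_offset + cr.polyt_run
    if end_off < cr.length:
        plant(end_off, "A")
    taa = None
    if cr.taa_stretch and end_off + 1 + len(cr.taa_stretch) <= cr.length:
        plant(end_off + 1, cr.taa_stretch)
        taa = {
            "start": cr_start + end_off + 1,
            "end": cr_start + end_off + len(cr.taa_stretch),
        }
    tandem = cr.tandem_unit * cr.tandem_copies
    plant(cr.tandem_offset, tandem)
    # breaker bases so the array cannot extend (or phase-shift) into the
    # random flanks: the base one unit before/after must mismatch the period
    u = len(cr.tandem_unit)
    if cr.tandem_offset > 0:
        bad = cr.tandem_unit[u - 1]
        plant(cr.tandem_offset - 1, next(b for b in BASES if b != bad))
    tail = cr.tandem_offset + len(tandem)
    if tail < cr.length:
        bad = tandem[len(tandem) - u]
        plant(tail, next(b for b in BASES if b != bad))

    # plant a spacer counterpart: copy a slice of the first planted spacer into the CR
    counterpart = None
    spacer_regions = [
        (features[i].end + 1, features[i + 1].start - 1)
        for i in range(len(features) - 1)
        if features[i + 1].start - features[i].end - 1 > 0
    ]
    if spacer_regions and cr.counterpart_length > 0:
        s0, s1 = spacer_regions[0]
        take = min(cr.counterpart_length, s1 - s0 + 1)
        motif = "".join(sequence[s0 - 1 : s0 - 1 + take])
        plant(cr.counterpart_offset, motif)
        counterpart = {
            "spacer_start": s0,
            "spacer_end": s0 + take - 1,
            "cr_start": cr_start + cr.counterpart_offset,
            "cr_end": cr_start + cr.counterpart_offset + take - 1,
            "length": take,
        }

    planted_overlaps = [-g for g in gaps if g < 0]
    planted_spacers = [g for g in gaps if g > 0]
    ground_truth = {
        "genome_length": genome_length,
        "total_overlap_bp": sum(planted_overlaps),
        "overlap_count": len(planted_overlaps),
        "total_spacer_bp": sum(planted_spacers),
        "spacer_count": len(planted_spacers),
        "cr": {
            "start": cr_start,
            "end": cr_end,
            "polyt_start": cr_start + cr.polyt_offset,
            "polyt_end": cr_start + cr.polyt_offset + cr.polyt_run - 1,
            "taa": taa,
            "tandem_start": cr_start + cr.tandem_offset,
            "tandem_end": cr_start + cr.tandem_offset + len(tandem) - 1,
            "tandem_unit": cr.tandem_unit,
            "tandem_copies": cr.tandem_copies,
            "counterpart": counterpart,
        },
    }
    genome = GenomeRecord(id=f"sim-{cfg.seed}", sequence="".join(sequence))
    return SimulatedGenome(genome=genome, features=features, ground_truth=ground_truth)


@dataclass(frozen=True)
class OrthologSet:
    gene: str
    root: str
    sequences: dict[str, str]
    site_classes: dict[int, list[int]]  # root-truth fold -> 0-based site indices
    rates: dict[int, float]


def _root_codon_weights(code: GeneticCode, at_bias: Mapping[int, float]) -> tuple[list[str], np.ndarray]:
    """Sampling weights over sense codons matching the per-class A+T bias."""
    folds = fold_table(code.table_id)
    codons = list(code.sense_codons())
    weights = []
    for codon in codons:
        w = 1.0
        for pos in (1, 2, 3):
            bias = at_bias[folds[codon][pos - 1]]
            base = codon[pos - 1]
            w *= (bias / 2) if base in "AT" else ((1 - bias) / 2)
        weights.append(w)
    arr = np.array(weights)
    return codons, arr / arr.sum()


def simulate_ortholog_set(cfg: SimulationConfig, gene: str) -> OrthologSet:
    """Evolve one gene's ortholog set on a star phylogeny.

    The root CDS is drawn codon by codon with per-class A+T bias; each
    species then accumulates Poisson(rate) substitution events per site,
    with the rate set by the site's fold class *in the root*. Replacement
    is uniform over the three alternative bases, redrawn when the codon
    would become a stop.
    """
    spec = next((g for g in cfg.genes if g.name == gene), None)
    if spec is None:
        raise KeyError(f"gene {gene!r} not in config")
    if spec.kind != "PCG" or spec.n_codons <= 0:
        raise ValueError(f"{gene}: ortholog simulation needs a PCG with n_codons > 0")
    code = genetic_code(cfg.code_id)
    folds = fold_table(code.table_id)
    rng = _gene_rng(cfg, gene, "root")

    codons, weights = _root_codon_weights(code, cfg.at_bias)
    root_codons = list(rng.choice(codons, size=spec.n_codons, p=weights))
    root = "".join(root_codons)

    site_classes: dict[int, list[int]] = {0: [], 2: [], 4: []}
    site_rate = np.empty(3 * spec.n_codons)
    for idx, codon in enumerate(root_codons):
        for pos in (1, 2, 3):
            fold = folds[codon][pos - 1]
            site_classes[fold].append(3 * idx + pos - 1)
            site_rate[3 * idx + pos - 1] = cfg.rates[fold]

    stops = code.stop_codons
    sequences: dict[str, str] = {}
    for s in range(cfg.n_species):
        sp_rng = _gene_rng(cfg, gene, f"species{s}")
        seq = list(root)
        events = sp_rng.poisson(site_rate)
        for site in np.flatnonzero(events):
            codon_start = 3 * (site // 3)
            for _ in range(int(events[site])):
                current = seq[site]
                for _attempt in range(16):
                    new = BASES[sp_rng.integers(4)]
                    if new == current:
                        continue
                    trial = seq[codon_start:codon_start + 3]
                    trial[site - codon_start] = new
                    if "".join(trial) not in stops:
                        seq[site] = new
                        break
        sequences[f"sp{s:02d}"] = "".join(seq)
    return OrthologSet(
        gene=gene, root=root, sequences=sequences,
        site_classes=site_classes, rates=dict(cfg.rates),
    )
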