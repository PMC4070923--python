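# mitocomp

Comparative analysis of circular mitochondrial genomes, built around the
kind of question asked in insect mitogenomics: how is the strong A+T
mutational bias of a mitogenome distributed across genes, strands, codon
positions and degeneracy classes — and how does that distribution relate
to how fast each protein-coding gene evolves?

The package is a library first (everything is importable; `examples/`
walks through each capability) with a thin `mitocomp` command-line
wrapper for pipeline use.

## What it computes

* **Annotation arithmetic on the circle.** Features carry 1-based
  inclusive coordinates on a circular molecule (origin-wrapping
  supported). The gap between consecutive features f, g is
  `start(g) − end(f) − 1`: positive gaps are intergenic spacers, negative
  gaps overlaps. On a fully annotated circle, feature lengths plus signed
  gaps sum exactly to the genome length.
* **Composition and codon usage.** Exact base counts by region, strand
  and codon position; relative synonymous codon usage
  `RSCU(c) = n_c · k / Σ n_c'` within each k-codon synonymous family; the
  G+C-rich/A+T-rich codon ratio (Pro+Ala+Arg+Gly over
  Phe+Ile+Met+Tyr+Asn+Lys).
* **Degenerate-site classes.** Each codon position is 0-, 2- or 4-fold
  degenerate under a genetic code (NCBI table 5, invertebrate
  mitochondrial, by default); per-gene, per-class A+T content is
  summarised as mean ± SD across species.
* **Substitution statistics.** Per-class substitution frequency as the
  mean pairwise Jukes–Cantor distance `d = −(3/4)·ln(1 − 4p/3)` over
  class sites; class substitution shares R_0F/all and R_4F/all from raw
  difference counts; amino-acid divergence as Poisson distances
  `d = −ln(1 − p)` summarised by their mean over pairs (ASD).
* **Correlation battery.** Pearson r with two-tailed P from
  `t = r·√((n−2)/(1−r²))` over named column pairs of a per-gene table.
* **Control-region scanning.** Poly(T) runs, [TA(A)]n stretches, G+A-rich
  blocks, exact tandem repeats, spacer→CR counterpart search and perfect
  stem-loop (hairpin) scanning, all in J-strand genome coordinates.
* **Synthetic data.** A simulator that plants known overlaps, spacers and
  CR motifs in a circular genome, and evolves ortholog sets on a star
  phylogeny with independently controlled substitution rates and A+T bias
  per degeneracy class — so every estimator above can be checked against
  ground truth.

## Worked example

Boundary accounting over the bundled annotation table of the
*Bactrocera minax* mitogenome (GenBank HM776033):

```
$ python examples/01_boundary_accounting.py
genome: 16043 bp, 38 annotated features
overlaps: 43 bp in 12 segments (1-17 bp)
spacers:  178 bp in 16 spacers (2-42 bp)
largest spacer: 42 bp between trnC and trnY
closure check: lengths + signed gaps = 16043 (genome length 16043)
```

Reading: the 38 annotated features overlap at 12 boundaries for 43 bp in
total, and leave 178 bp of intergenic sequence in 16 spacers; the closure
check confirms the circular bookkeeping is exact.

The correlation battery over the bundled 13-gene class-statistics table
of the ten-species tephritid comparison:

```
$ python examples/04_correlation_battery.py
AT_0F ~ subst_0F: r = 0.735, P = 0.004 (n = 13)
AT_2F ~ subst_2F: r = -0.217, P = 0.477 (n = 13)
AT_4F ~ subst_4F: r = 0.864, P = 0.000 (n = 13)
AT_0F ~ R_0F_all: r = 0.760, P = 0.003 (n = 13)
AT_0F ~ ASD: r = 0.752, P = 0.003 (n = 13)
R_0F_all ~ ASD: r = 0.983, P = 0.000 (n = 13)
AT_4F ~ R_4F_all: r = 0.809, P = 0.001 (n = 13)
AT_4F ~ ASD: r = -0.828, P = 0.000 (n = 13)
R_4F_all ~ ASD: r = -0.970, P = 0.000 (n = 13)
```

Reading: genes whose 0-fold (amino-acid-changing) sites are A+T-rich put
a larger share of their substitutions at those sites and diverge more at
the protein level (r = 0.98 between R_0F/all and ASD); conserved genes
concentrate change at synonymous 4-fold sites.

Estimator checks on simulated data (`examples/03_degeneracy_and_divergence.py`)
recover per-class rates within a few percent of the star-phylogeny
expectation 2 × rate, and the scanners recover planted CR motifs at their
recorded coordinates (`examples/05_control_region_scan.py`).

The same operations are available as subcommands:
`mitocomp boundaries | composition | rscu | degeneracy | divergence |
correlate | cr-scan | simulate | pipeline`.

## Layout

```
src/mitocomp/      library (genome, composition, degeneracy, divergence,
                   stats, cr_scan, simulate, datasets, cli)
src/mitocomp/data/ bundled annotation + class-statistics tables (TSV)
examples/          one narrative script per capability
tests/             pytest suite incl. brute-force oracles
docs/methods.md    models, conventions, design choices, limitations
```
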