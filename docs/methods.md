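# Methods

`mitocomp` analyses circular mitochondrial genomes the way comparative
mitogenomics studies of insects do: annotation arithmetic on the circle,
composition and codon-usage statistics, degenerate-site substitution
statistics across an ortholog panel, and control-region motif scanning.
This note records the models, conventions and design choices behind each
stage, and what the synthetic-data generator does and does not emulate.

## Coordinate and strand conventions

All coordinates are 1-based inclusive, the convention of published
mitogenome annotation tables; every TSV report carries this in a header
comment. A feature with `end < start` wraps the origin of the circle
(length `end + L - start + 1`). Strands are J (majority) and N (minority);
input tables using F/R are normalised on read. The gap between consecutive
features f and g is `start(g) - end(f) - 1` — positive values are
intergenic spacers, negative values overlaps, zero abutting — and the pair
that wraps the origin is included, so on a fully annotated circle feature
lengths plus signed gaps sum exactly to the genome length (the package
asserts this identity on the bundled *Bactrocera minax* table: 16,043 bp).
Feature containment is rejected rather than merged: real mitogenome tables
contain overlaps but not containment, which almost always signals a bad
row. A declared size column that contradicts the coordinates is likewise a
hard error; the bundled *B. minax* table ships the coordinate-derived
length where the published row for trnL(UUR) misprints its size.

## Composition and codon usage

Base composition is exact counting; N characters leave the percentage
denominator and are tallied separately. Printed percentages round half-up
to one decimal, matching how composition tables are published. Codon-position
composition is tallied on the coding strand after trimming each CDS to a
codon multiple.

RSCU(c) = count(c) × family size / family total, with synonymous families
defined by the genetic code (NCBI table 5, invertebrate mitochondrial, by
default; configurable). A family never observed yields undefined (NaN)
RSCU rather than zero — zero is a statement about usage, NaN about data.
Stop codons are excluded from counting by default, CodonW-style; a flag
re-includes them as one family to reproduce the layout of published codon
usage tables that print UAA/UAG rows. The G+C-rich/A+T-rich codon ratio
counts codons by amino-acid family membership — numerator Pro, Ala, Arg,
Gly; denominator Phe, Ile, Met, Tyr, Asn, Lys — because the statistic
measures how amino-acid composition responds to A+T mutational bias, not
the base content of individual codons.

## Degenerate-site classification

A codon position's fold is the number of nucleotides (of four, including
the observed one) that preserve the amino acid: 4 → 4-fold, 1 → 0-fold,
2 or 3 → 2-fold. Stop-codon alternatives never count as preserving.
Three-fold positions (which exist under the standard code) share the
2-fold bin; under table 5 they do not occur, and every second codon
position is 0-fold — both facts are asserted by exhaustive enumeration in
the test suite against a brute-force translate-all-alternatives oracle.
Codons containing ambiguous characters are skipped and logged; internal
stop codons are an error naming the codon index.

Across an aligned ortholog set, sites get a class by one of two rules:

* **concordant** (default): a site keeps a class only when every species
  agrees on its fold at that aligned position; discordant sites are
  excluded. Conservative, and right for descriptive per-class A+T tables.
* **reference**: every site takes the fold of one reference species.
  This is the mode for substitution-rate estimation: concordance filtering
  preferentially discards exactly the sites that substituted (a 0-fold
  site whose amino acid changed often changes fold class in that species),
  deflating rate estimates, whereas a fixed reference assignment leaves
  the difference counts unbiased apart from a small misassignment
  contamination (measured at under ~8% relative on the default synthetic
  conditions).

Per-class A+T is computed per species over the class's sites, then
summarised as mean ± sample SD (n−1) across species, which is what
comparative tables print.

## Substitution frequencies, ratios and amino-acid distances

The per-class substitution frequency of a gene is the mean pairwise
Jukes–Cantor distance, `d = -(3/4) ln(1 - 4p/3)`, over all unordered
species pairs, restricted to the class's sites, with gap/ambiguous
positions excluded pairwise (pairwise deletion). JC is the minimal
multiple-hit correction consistent with published per-class frequencies
exceeding one substitution per site, which a raw p-distance cannot reach;
pairs at or beyond p = 0.75 are saturated, flagged, and excluded from the
mean with a warning (an error only if every pair saturates).

The class ratios R_0F/all and R_4F/all divide summed raw pairwise
difference counts, not corrected distances: counts remain well defined
near saturation and force the three ratios to sum to one exactly.

Amino-acid divergence is the Poisson-corrected distance
`d = -ln(1 - p)` per pair, assembled into a symmetric matrix whose
upper-triangle mean is the overall average sequence distance (ASD).
Codon alignments are taken as given; the package deliberately contains no
aligner (back-translate a protein alignment upstream if needed).

## Correlation analysis

Pearson r with two-tailed P from `t = r sqrt((n-2)/(1-r^2))` on n−2
degrees of freedom (delegated to `scipy.stats.pearsonr`, which implements
exactly this test). P values print at three decimals, so strong effects
appear as "0.000". No multiple-testing correction is applied to a
battery. Rows with undefined values are dropped pairwise with a log line.
The bundled 13-gene class-statistics table reproduces all nine published
coefficients of the ten-species tephritid comparison to the printed
precision (r = 0.735, −0.217, 0.864, 0.760, 0.752, 0.983, 0.809, −0.828,
−0.970).

## Control-region scanners

All scanners are exact, pure and combinatorial; coordinates are reported
on the J strand, lifted into genome coordinates via an `origin` argument.

* **poly(T)**: maximal T runs of at least `min_run` (default 5) on either
  strand (an N-strand run appears as a poly-A on the J slice).
* **[TA(A)]n**: within a window (default 50 bp) downstream of a J-strand
  poly(T) run, the longest stretch decomposable greedily left-to-right
  into TA/TAA units (ties prefer the longer TAA unit), requiring at least
  3 units.
* **G+A-rich block**: windows (default 10 bp) upstream of the poly(T)
  start with purine fraction ≥ `min_frac` (default 0.8), merged into
  maximal blocks scored by purine fraction.
* **tandem repeats**: exact-match arrays only — the published repeats in
  tephritid control regions are exact, and mismatch-tolerant detection
  (TRF-style scoring) is a different published algorithm, out of scope.
  An array with unit length u is a maximal stretch where
  `seq[i] == seq[i-u]`; copy number span/u may be fractional. Overlapping
  candidates collapse to the highest-copy-number representative (ties:
  shorter unit, then leftmost), greedily.
* **counterpart search**: ungapped scan of a spacer against both strands
  of the CR; per alignment diagonal, the longest window of length
  ≥ `min_len` with identity ≥ 70% (the default threshold sits inside the
  71.4–100% conservation range reported for tephritid spacer
  counterparts), ties toward more identities then leftmost; matches are
  returned best-first.
* **hairpin scan**: perfect stems only, Watson–Crick pairs only (no G·U),
  loop lengths 3–12; for each candidate loop the stem grows outward
  maximally and is reported when it reaches `min_stem`.

Each of the tandem, counterpart and hairpin scanners is tested for exact
agreement with an independent brute-force implementation on random
sequences.

## Synthetic data

`simulate_genome` lays features head-to-tail with configured signed gaps
(negative = planted overlap), appends a control region carrying a planted
poly(T) run, tandem array and spacer counterpart at recorded coordinates,
and serialises the ground truth. `simulate_ortholog_set` draws a root CDS
codon-by-codon with per-class A+T bias (codon weights multiply per-position
base weights set by each position's fold), then evolves each species
independently from the root — a star phylogeny — placing Poisson(rate)
substitution events per site at the rate of the site's *root* fold class,
replacing uniformly over the three alternative bases and redrawing any
event that would create a stop codon. The star keeps expectations
analytic: the expected pairwise distance at a class is twice the
per-branch rate, so JC estimates can be checked against 2 × rate without
simulation-side bookkeeping. All randomness derives from one seed through
per-gene, per-species streams; identical configs are byte-identical.

Default conditions: 10 species, 500-codon genes, per-branch rates
0.02/0.2/0.8 at 0-/2-/4-fold sites, A+T biases 0.65/0.78/0.85 — a
tephritid-like regime where 4-fold sites approach (but mostly stay below)
JC saturation, mirroring published 4-fold frequencies above 1. Parameter
recovery over 100 replicates at these conditions recovers the rate
ordering in ≥95 runs and mean JC frequencies within 15% of 2 × rate
(reference-species assignment; see above for why concordance is the wrong
estimator here).

What the generator does **not** emulate: a real phylogeny (no shared
internal branches, so among-pair covariance is understated), indels,
selection beyond the sense-codon constraint, strand-asymmetric mutation,
and within-gene rate heterogeneity. Passing recovery tests therefore show
estimator correctness under the stated model, not robustness to tree
shape or alignment error.

## What needs the real genomes

Genome-wide composition tables, RSCU values, the 0.44 G+C-rich/A+T-rich
codon ratio, and the control-region motif coordinates (e.g. the poly(T)
stretch at 15,974–15,997) can only be recomputed from the GenBank records
themselves, which are not bundled; `scripts/fetch_genomes.py` downloads
the ten accessions for users with network access, producing flat files
readable by `mitocomp.genome.read_genbank`. The bundled inputs — the
annotation table and the 13-gene class-statistics table — cover everything
the offline pipeline and its tests assert.

## Numerical choices

* Sample SD uses n−1 throughout (species are a sample).
* JC saturation bound p ≥ 0.75 → +inf, excluded from means with a warning.
* Poisson distance at p = 1 is an error, not a sentinel.
* Undefined statistics (empty site class, unobserved codon family)
  propagate as flagged/NaN values, never as zeros.
* Reported percentages round half-up (1 d.p.); r prints at 3 d.p.; full
  precision is always available from the Python objects and JSON outputs.
* Problem sizes in the recovery analyses (100 replicates × 10 species ×
  500 codons) were chosen so the Monte-Carlo error on mean frequencies is
  a few percent — comfortably inside the 15% recovery band — while the
  whole analysis stays interactive on a laptop.
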