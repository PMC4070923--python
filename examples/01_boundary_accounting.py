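"""Overlap and spacer accounting on the bundled B. minax annotation table.

Loads the 38-feature annotation of the 16,043 bp circular mitogenome and
tallies the signed gaps between adjacent features around the circle.
"""

from mitocomp import compute_boundaries
from mitocomp.datasets import load_bminax_gene_table

features, genome_length = load_bminax_gene_table()
report = compute_boundaries(features, genome_length)

print(f"genome: {genome_length} bp, {len(features)} annotated features")
print(
    f"overlaps: {report.total_overlap_bp} bp in {report.overlap_count} segments "
    f"({report.min_overlap}-{report.max_overlap} bp)"
)
print(
    f"spacers:  {report.total_spacer_bp} bp in {report.spacer_count} spacers "
    f"({report.min_spacer}-{report.max_spacer} bp)"
)
largest = max(report.spacers, key=lambda g: g.gap)
print(f"largest spacer: {largest.gap} bp between {largest.upstream} and {largest.downstream}")

# On a fully annotated circle, feature lengths plus signed gaps close exactly.
total = sum(f.length(genome_length) for f in features) + sum(g.gap for g in report.gaps)
print(f"closure check: lengths + signed gaps = {total} (genome length {genome_length})")
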