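"""Control-region motif scanning on a simulated genome with planted features.

The simulator plants a poly(T) run, a tandem repeat and a spacer
counterpart in the control region and records their coordinates; the
scanners recover them blind.
"""

from mitocomp import (
    compute_boundaries,
    counterpart_search,
    extract_feature_sequence,
    find_polyt,
    find_taa_stretch,
    simulate_genome,
    tandem_repeats,
)
from mitocomp.simulate import GeneSpec, SimulationConfig

cfg = SimulationConfig(
    seed=23,
    genes=(GeneSpec("g1", n_codons=120), GeneSpec("t1", length_bp=65, kind="tRNA")),
    gene_gaps=(-7, 42, 0),
)
sim = simulate_genome(cfg)
truth = sim.ground_truth["cr"]
cr = sim.features[-1]
cr_seq = extract_feature_sequence(sim.genome, cr)

report = compute_boundaries(sim.features, sim.genome.length)
print(f"simulated circle: {sim.genome.length} bp; overlaps {report.total_overlap_bp} bp, "
      f"spacers {report.total_spacer_bp} bp (as planted)")

polyt = [h for h in find_polyt(cr_seq, min_run=10, origin=cr.start) if h.strand == "J"]
print(f"poly(T): found {polyt[0].start}-{polyt[0].end} "
      f"(planted {truth['polyt_start']}-{truth['polyt_end']})")

taa = find_taa_stretch(cr_seq, polyt_hits=polyt, origin=cr.start)
print(f"[TA(A)]n stretch after poly(T): {taa[0].score:.0f} units at {taa[0].start}-{taa[0].end} "
      f"(planted at {truth['taa']['start']}-{truth['taa']['end']})")

repeats = tandem_repeats(cr_seq, min_unit=4, min_copies=3, origin=cr.start)
planted = next(t for t in repeats if t.unit == truth["tandem_unit"])
print(f"tandem repeat: unit {planted.unit} x {planted.copies:.0f} at "
      f"{planted.start}-{planted.end} (planted {truth['tandem_start']}-{truth['tandem_end']})")

cp = truth["counterpart"]
spacer = sim.genome.sequence[cp["spacer_start"] - 1 : cp["spacer_end"]]
best = counterpart_search(spacer, cr_seq, min_len=cp["length"], subject_origin=cr.start)[0]
print(f"spacer counterpart in CR: {best.percent_identity:.0f}% identity at "
      f"{best.subject_start}-{best.subject_end} (planted {cp['cr_start']}-{cp['cr_end']})")
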