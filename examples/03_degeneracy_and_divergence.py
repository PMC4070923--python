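"""Degenerate-site classes and substitution statistics on simulated orthologs.

Simulates a ten-species, 500-codon gene with known per-class substitution
rates (0.02 / 0.2 / 0.8 per branch at 0-, 2- and 4-fold sites), then runs
the estimation pipeline and compares against the star-phylogeny
expectation of 2 x rate per species pair.
"""

from mitocomp import (
    class_composition,
    class_ratios,
    gene_class_profile,
    overall_asd,
    simulate_ortholog_set,
    trim_cds,
)
from mitocomp.codes import genetic_code
from mitocomp.simulate import SimulationConfig

code = genetic_code(5)
cfg = SimulationConfig(seed=11)
ortho = simulate_ortholog_set(cfg, "gene1")

comps = class_composition(ortho.sequences, code, assignment="reference")
profile = gene_class_profile(ortho.sequences, code, assignment="reference")
print("fold  sites  A+T% (mean+/-SD)   subst/site   expected 2xrate")
for fold in (0, 2, 4):
    c, s = comps[fold], profile[fold]
    print(
        f"{fold:>4}  {s.n_sites:>5}  {c.mean_at_percent:6.2f} +/- {c.sd_at_percent:4.2f}"
        f"     {s.frequency:6.3f}       {2 * cfg.rates[fold]:.2f}"
    )

ratios = class_ratios(profile)
print(f"R_0F/all = {ratios.r0f_all:.3f}, R_4F/all = {ratios.r4f_all:.3f} (shares sum to 1)")

proteins = {sp: code.translate(trim_cds(s, code)) for sp, s in ortho.sequences.items()}
print(f"ASD (mean Poisson amino-acid distance): {overall_asd(proteins).asd:.4f}")
print("-> low ASD despite fast 4-fold evolution: 4-fold changes are synonymous")
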