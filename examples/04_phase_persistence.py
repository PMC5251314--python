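"""Persistence of gametic phase between diverging populations.

One ancestral population is split into pairs that evolve independently
for 0, 20 and 100 generations.  Within each distance bin we correlate
the signed phase, sign(D) * sqrt(r2), of the same SNP pairs in the two
populations: shared ancestry keeps marker phases aligned, drift after
the split erodes the correlation — fastest at long distances.
"""

import numpy as np

from pigpop import SimConfig, ld_scan, phase_persistence, simulate_population, split_populations

base = simulate_population(
    SimConfig(chromosomes=2, chrom_length_cm=50, n_markers=800, ne=100,
              burn_in_generations=120, seed=7)
)

for gens in (0, 20, 100):
    a, b = split_populations(base, gens, names=(f"A{gens}", f"B{gens}"),
                             seeds=(1000 + gens, 2000 + gens))
    pp = phase_persistence(
        ld_scan(a.panel, max_distance_mbp=0.15),
        ld_scan(b.panel, max_distance_mbp=0.15),
        bin_width_mbp=0.05,
    )
    row = pp[np.isclose(pp.bin_lo, 0.05)].iloc[0]
    print(f"{gens:3d} generations after split: "
          f"phase correlation at 0.05-0.10 Mbp = {row.pearson_r:.3f} "
          f"({row.n_pairs} shared pairs)")
# r = 1 at zero divergence by construction; the decline with divergence
# time is what limits multi-population genomic prediction
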