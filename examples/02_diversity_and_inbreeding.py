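"""Heterozygosity, IBS distance, ROH and the four inbreeding coefficients.

A small inbred line (Ne = 40) is simulated; we then compute the
diversity summary, detect runs of homozygosity, and compare the
genomic inbreeding coefficients (F_EH, F_VR, F_ROH) with the
pedigree-based F_PED over the recorded generations.
"""

from pigpop import (
    SimConfig,
    detect_roh,
    diversity_summary,
    f_roh,
    inbreeding_correlations,
    inbreeding_table,
    simulate_population,
)

out = simulate_population(
    SimConfig(chromosomes=2, chrom_length_cm=50, n_markers=400, ne=40,
              burn_in_generations=100, seed=3)
)
panel = out.panel

div = diversity_summary(panel)
print(div.round(3).to_string())
# H_O close to H_E says genotype frequencies sit near Hardy-Weinberg;
# mean D is the average IBS genetic distance between animals

segments = detect_roh(panel)
froh = f_roh(segments, panel.map, panel.animal_ids)
print(f"\n{len(segments)} ROH segments; mean F_ROH = {froh.mean():.3f}")

tab = inbreeding_table(panel, f_roh=froh, pedigree=out.pedigree)
print("\nper-population inbreeding means:")
print(tab.groupby("population")[["F_EH", "F_VR", "F_ROH", "F_PED"]]
      .mean().round(3).to_string())

corr = inbreeding_correlations(tab)
print("\ncross-estimator Pearson correlations:")
print(corr.round(2).to_string(index=False))
# F_PED only sees the recorded 5 generations, so it sits well below the
# genomic coefficients, which absorb the whole drift history
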