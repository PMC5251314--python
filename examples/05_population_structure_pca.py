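"""Population structure from the genomic relationship matrix.

Two lines diverged for 100 generations plus their F1 cross are stacked
into one panel; the top principal components of the VanRaden GRM
separate the lines, and the F1 cohort sits between them.
"""

import numpy as np
import pandas as pd

from pigpop import (
    SimConfig,
    build_grm,
    make_f1,
    principal_components,
    simulate_population,
    split_populations,
)
from pigpop.io import GenotypePanel

base = simulate_population(
    SimConfig(chromosomes=2, chrom_length_cm=50, n_markers=500, ne=80,
              burn_in_generations=100, seed=11)
)
line_a, line_b = split_populations(base, 100, names=("LINE_A", "LINE_B"))
f1 = make_f1(line_a, line_b, n_offspring=40, seed=12)

panels = [line_a.panel, line_b.panel, f1.panel]
panel = GenotypePanel(
    animals=pd.concat([p.animals for p in panels], ignore_index=True),
    dosages=np.vstack([p.dosages for p in panels]),
    map=panels[0].map,
    counted_allele=panels[0].counted_allele,
    other_allele=panels[0].other_allele,
)

pcs = principal_components(build_grm(panel), k=2)
print("variance explained: PC1 {:.1%}, PC2 {:.1%}".format(
    *pcs.variance_fractions))
scores = pcs.to_frame(populations=panel.populations)
print(scores.groupby("population")[["PC1", "PC2"]].mean().round(2).to_string())
# the two lines take opposite ends of PC1 and the F1 centroid lies
# between them — the geometry of admixture in GRM space
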