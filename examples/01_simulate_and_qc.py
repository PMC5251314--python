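"""Simulate a SNP panel, write it as PLINK text, and run quality control.

The simulator produces a drifted Wright-Fisher population; QC then
applies the four standard panel filters (animal call rate, MAF, SNP
call rate, Hardy-Weinberg) and reports how many markers each criterion
removed.
"""

import tempfile
from pathlib import Path

import numpy as np

from pigpop import SimConfig, apply_qc, read_plink_text, simulate_population, write_plink_text

out = simulate_population(
    SimConfig(chromosomes=2, chrom_length_cm=50, n_markers=300, ne=60,
              burn_in_generations=80, seed=1)
)
panel = out.panel
print(f"simulated {panel.n_animals} animals x {panel.n_markers} SNPs")

# knock a little realism into the data: 2% missing calls
rng = np.random.default_rng(2)
panel.dosages[rng.random(panel.dosages.shape) < 0.02] = np.nan

ped, mp = write_plink_text(panel, Path(tempfile.mkdtemp()) / "example_panel")
panel = read_plink_text(ped, mp)

clean, report = apply_qc(panel)
print(f"QC: {report.n_excluded_maf} markers failed MAF < 0.05, "
      f"{report.n_excluded_snp_call_rate} failed call rate < 0.90, "
      f"{report.n_excluded_hwe} failed HWE p < 1e-6; "
      f"{clean.n_markers} SNPs survive")
# drifted populations lose rare alleles, so the MAF filter dominates;
# the survivors feed every downstream statistic
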