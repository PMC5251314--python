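from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pigpop import SimConfig, simulate_population, split_populations
from pigpop.io import GenotypePanel, MarkerMap


def make_panel(dosages, positions_bp=None, chromosomes=None, populations=None):
    """Hand-build a GenotypePanel from a dosage matrix (NaN = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions_bp = positions_bp or [1000 * (j + 1) for j in range(m)]
    chromosomes = chromosomes or [1] * m
    populations = populations or ["P"] * n
    mm = MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [f"m{j}" for j in range(m)],
                "chromosome": chromosomes,
                "position_bp": positions_bp,
            }
        )
    )
    animals = pd.DataFrame(
        {
            "animal_id": [f"ind{i}" for i in range(n)],
            "population": populations,
            "herd": populations,
        }
    )
    return GenotypePanel(
        animals=animals,
        dosages=dosages,
        map=mm,
        counted_allele=np.full(m, "A", dtype=object),
    )


def random_panel(rng, n=20, m=50, maf_range=(0.1, 0.5), missing_rate=0.0):
    p = rng.uniform(*maf_range, size=m)
    dos = (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)
    if missing_rate:
        dos[rng.random((n, m)) < missing_rate] = np.nan
    return make_panel(dos)


@pytest.fixture(scope="session")
def wf_constant_ne100():
    """Constant-size Wright-Fisher population for Ne parameter recovery:
    10 chromosomes x 100 cM, 300 markers each, Ne = 100, 200 burn-in
    generations."""
    cfg = SimConfig(
        chromosomes=10,
        chrom_length_cm=100.0,
        n_markers=300,
        ne=100,
        burn_in_generations=200,
        seed=42,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def split_series():
    """One ancestral population split into pairs that diverged for 0, 20
    and 100 generations (dense map so the 0.05-0.10 Mbp bin is populated)."""
    base = simulate_population(
        SimConfig(
            chromosomes=2,
            chrom_length_cm=50.0,
            n_markers=800,
            ne=100,
            burn_in_generations=120,
            seed=7,
        )
    )
    out = {}
    for gens in (0, 20, 100):
        out[gens] = split_populations(
            base, gens, names=(f"A{gens}", f"B{gens}"), seeds=(1000 + gens, 2000 + gens)
        )
    return out


def build_qc_fixture():
    """30 animals x 12 markers: 3 fail MAF, 2 fail call rate, 1 fails HWE."""
    rng = np.random.default_rng(0)
    n = 30
    cols = []
    kinds = []
    # 3 monomorphic -> MAF 0 < 0.05
    for _ in range(3):
        cols.append(np.zeros(n))
        kinds.append("maf")
    # 2 with 4/30 missing -> call rate 0.867 < 0.9, MAF fine among called
    for _ in range(2):
        c = np.array([0.0, 1, 2] * 10)
        c[rng.choice(n, 4, replace=False)] = np.nan
        cols.append(c)
        kinds.append("cr")
    # 1 failing HWE: 15 AA + 15 aa, chi2 = 30, p = 4.3e-8 < 1e-6
    cols.append(np.array([2.0] * 15 + [0.0] * 15))
    kinds.append("hwe")
    # 6 clean: near-HWE at p = 0.5 (8 / 14 / 8)
    for _ in range(6):
        c = np.array([2.0] * 8 + [1.0] * 14 + [0.0] * 8)
        cols.append(rng.permutation(c))
        kinds.append("clean")
    order = rng.permutation(len(cols))
    dosages = np.column_stack([cols[j] for j in order])
    return make_panel(dosages), [kinds[j] for j in order]
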