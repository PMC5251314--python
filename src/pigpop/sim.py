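"""Forward Wright-Fisher diploid simulator with recombination.

Discrete non-overlapping generations of a monoecious randomly mating
population (selfing excluded), no mutation or selection, so the census
size is the effective size — the regime Sved's LD expectation assumes.
Founders start at linkage equilibrium with counted-allele frequencies
drawn uniformly per marker; LD then builds up by drift over a burn-in.

Markers sit at equally spaced genetic positions; gametes are sampled at
the marker loci under the Haldane (no-interference) crossover model:
the source haplotype switches between adjacent markers with probability
theta = (1 - exp(-2 d_Morgans)) / 2, the recombination fraction implied
by Poisson crossovers, which reproduces the crossover process exactly
at the marker positions.  Physical positions are genetic positions
scaled by ``cm_per_mbp`` (1 cM = 1 Mbp by default).

The simulator records pedigree for the trailing generations and can
split a population into independently evolving copies (shared map and
allele coding) or cross two populations into an F1 cohort, which is
what the phase-persistence and crossbred analyses feed on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenotypePanel, MarkerMap, Pedigree

PEDIGREE_DEPTH = 5  # generations of matings kept in the exported pedigree


@dataclass
class SimConfig:
    chromosomes: int = 2
    chrom_length_cm: float = 100.0
    n_markers: int = 250  # per chromosome
    ne: int = 100
    ne_trajectory: list[tuple[int, int]] | None = None  # (generation, size)
    burn_in_generations: int = 100
    n_sampled: int | None = None  # default: whole final generation
    init_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    cm_per_mbp: float = 1.0
    population: str = "SIM"

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError("population size must be >= 2")
        if self.chrom_length_cm < 0:
            raise ValueError("chromosome length must be >= 0")
        if self.n_markers < 2:
            raise ValueError("need >= 2 markers per chromosome")
        lo, hi = self.init_maf_range
        if not 0 < lo <= hi < 1:
            raise ValueError("init_maf_range must satisfy 0 < lo <= hi < 1")
        if self.ne_trajectory:
            for g, size in self.ne_trajectory:
                if not 0 <= g <= self.burn_in_generations:
                    raise ValueError(
                        f"trajectory generation {g} outside 0..{self.burn_in_generations}"
                    )
                if size < 2:
                    raise ValueError("trajectory sizes must be >= 2")

    def size_at(self, generation: int) -> int:
        size = self.ne
        if self.ne_trajectory:
            for g, s in sorted(self.ne_trajectory):
                if generation >= g:
                    size = s
        return size


@dataclass
class _State:
    """Evolving population state: haplotypes per chromosome + pedigree tail."""

    haplotypes: list[np.ndarray]  # each (2N, M) int8
    generation: int
    matings: list[pd.DataFrame]  # trailing generations, newest last
    pop: str

    @property
    def n(self) -> int:
        return self.haplotypes[0].shape[0] // 2

    def ids(self) -> list[str]:
        return [f"{self.pop}_G{self.generation}_{i}" for i in range(self.n)]


@dataclass
class SimOutput:
    panel: GenotypePanel
    pedigree: Pedigree
    config: SimConfig
    state: _State = field(repr=False, default=None)  # type: ignore[assignment]


def _marker_map(config: SimConfig) -> tuple[MarkerMap, np.ndarray]:
    """Equally spaced map plus per-interval switch probabilities."""
    m = config.n_markers
    cm = np.linspace(0.0, config.chrom_length_cm, m)
    d_morgans = np.diff(cm) / 100.0
    theta = 0.5 * (1.0 - np.exp(-2.0 * d_morgans))
    bp = np.round(cm / config.cm_per_mbp * 1e6).astype(int) + 1
    bp = np.maximum.accumulate(bp)  # guard against rounding ties
    bp = bp + np.arange(m)  # strictly increasing even at zero length
    rows = []
    for c in range(1, config.chromosomes + 1):
        for j in range(m):
            rows.append((f"chr{c}_snp{j}", c, int(bp[j])))
    table = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])
    return MarkerMap(table), theta


def _gametes(
    H: np.ndarray, parents: np.ndarray, theta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per listed parent, Haldane switches between markers."""
    G = len(parents)
    M = H.shape[1]
    u = rng.random((G, M))
    switch = np.empty((G, M), dtype=np.int8)
    switch[:, 0] = u[:, 0] < 0.5  # random starting haplotype
    switch[:, 1:] = u[:, 1:] < theta
    src = np.cumsum(switch, axis=1, dtype=np.int32) & 1
    A = H[2 * parents]
    B = H[2 * parents + 1]
    return np.where(src == 0, A, B).astype(np.int8)


def _advance(
    state: _State,
    config: SimConfig,
    theta: np.ndarray,
    rng: np.random.Generator,
    n_generations: int,
) -> None:
    """Evolve the state in place for ``n_generations``."""
    for _ in range(n_generations):
        n_parents = state.n
        next_gen = state.generation + 1
        n_off = config.size_at(next_gen)
        sires = rng.integers(0, n_parents, size=n_off)
        # distinct second parent (no selfing)
        shift = rng.integers(1, n_parents, size=n_off)
        dams = (sires + shift) % n_parents
        parent_ids = state.ids()
        new_haps = []
        for H in state.haplotypes:
            g1 = _gametes(H, sires, theta, rng)
            g2 = _gametes(H, dams, theta, rng)
            Hn = np.empty((2 * n_off, H.shape[1]), dtype=np.int8)
            Hn[0::2] = g1
            Hn[1::2] = g2
            new_haps.append(Hn)
        state.haplotypes = new_haps
        state.generation = next_gen
        mat = pd.DataFrame(
            {
                "animal": [f"{state.pop}_G{next_gen}_{i}" for i in range(n_off)],
                "sire": [parent_ids[s] for s in sires],
                "dam": [parent_ids[d] for d in dams],
                "population": state.pop,
            }
        )
        state.matings.append(mat)
        if len(state.matings) > PEDIGREE_DEPTH:
            state.matings.pop(0)


def _export(state: _State, config: SimConfig, marker_map: MarkerMap,
            rng: np.random.Generator) -> SimOutput:
    n = state.n
    take = np.arange(n)
    if config.n_sampled is not None and config.n_sampled < n:
        take = np.sort(rng.choice(n, size=config.n_sampled, replace=False))
    dosages = np.hstack(
        [(H[2 * take] + H[2 * take + 1]).astype(float) for H in state.haplotypes]
    )
    ids = state.ids()
    animals = pd.DataFrame(
        {
            "animal_id": [ids[i] for i in take],
            "population": state.pop,
            "herd": state.pop,
        }
    )
    panel = GenotypePanel(
        animals=animals,
        dosages=dosages,
        map=MarkerMap(marker_map.table.copy()),
        counted_allele=np.full(len(marker_map), "A", dtype=object),
        other_allele=np.full(len(marker_map), "B", dtype=object),
    )
    pedigree = _pedigree_from_matings(state.matings)
    return SimOutput(panel=panel, pedigree=pedigree, config=config, state=state)


def _pedigree_from_matings(matings: list[pd.DataFrame]) -> Pedigree:
    if not matings:
        return Pedigree(pd.DataFrame(columns=["animal", "sire", "dam", "population"]))
    tab = pd.concat(matings, ignore_index=True)
    known = set(tab["animal"])
    # parents beyond the recorded window become founders
    founders = sorted(
        (set(tab["sire"]) | set(tab["dam"])) - known - {"0"}
    )
    if founders:
        pops = {}
        for r in tab.itertuples():
            pops.setdefault(r.sire, r.population)
            pops.setdefault(r.dam, r.population)
        head = pd.DataFrame(
            {
                "animal": founders,
                "sire": "0",
                "dam": "0",
                "population": [pops[f] for f in founders],
            }
        )
        tab = pd.concat([head, tab], ignore_index=True)
    return Pedigree(tab)


def simulate_population(config: SimConfig) -> SimOutput:
    """Run founders -> burn-in -> exported sample, reproducibly from seed."""
    rng = np.random.default_rng(config.seed)
    marker_map, theta = _marker_map(config)
    n0 = config.size_at(0)
    lo, hi = config.init_maf_range
    haps = []
    for _ in range(config.chromosomes):
        p = rng.uniform(lo, hi, size=config.n_markers)
        haps.append(
            (rng.random((2 * n0, config.n_markers)) < p).astype(np.int8)
        )
    state = _State(haplotypes=haps, generation=0, matings=[], pop=config.population)
    _advance(state, config, theta, rng, config.burn_in_generations)
    return _export(state, config, marker_map, rng)


def split_populations(
    parent: SimOutput,
    generations_after_split: int,
    names: tuple[str, str] = ("POP_A", "POP_B"),
    seeds: tuple[int, int] | None = None,
) -> tuple[SimOutput, SimOutput]:
    """Evolve two independent copies of a saved state.

    The copies share the marker map and allele coding; with 0
    generations after the split they are identical.  Seeds default to
    (config.seed + 1, config.seed + 2).
    """
    config = parent.config
    marker_map, theta = _marker_map(config)
    if seeds is None:
        seeds = (config.seed + 1, config.seed + 2)
    outs = []
    for name, seed in zip(names, seeds):
        # pedigree restarts at the split: pre-split animals of the two
        # copies are the same individuals under different labels, so
        # carrying old matings across would alias them
        st = _State(
            haplotypes=[H.copy() for H in parent.state.haplotypes],
            generation=parent.state.generation,
            matings=[],
            pop=name,
        )
        rng = np.random.default_rng(seed)
        cfg = replace(config, population=name)
        _advance(st, cfg, theta, rng, generations_after_split)
        outs.append(_export(st, cfg, marker_map, rng))
    return outs[0], outs[1]


def make_f1(
    pop_a: SimOutput, pop_b: SimOutput, n_offspring: int, seed: int | None = None,
    population: str = "F1",
) -> SimOutput:
    """Cross two populations: each offspring takes one random parent from
    each.  Maps must be identical (same marker ids and positions)."""
    if not pop_a.panel.map.table.equals(pop_b.panel.map.table):
        raise ValueError("parent populations have incompatible marker maps")
    config = replace(pop_a.config, population=population)
    marker_map, theta = _marker_map(config)
    rng = np.random.default_rng(pop_a.config.seed + 101 if seed is None else seed)
    sa = pop_a.state
    sb = pop_b.state
    sires = rng.integers(0, sa.n, size=n_offspring)
    dams = rng.integers(0, sb.n, size=n_offspring)
    haps = []
    for Ha, Hb in zip(sa.haplotypes, sb.haplotypes):
        g1 = _gametes(Ha, sires, theta, rng)
        g2 = _gametes(Hb, dams, theta, rng)
        Hn = np.empty((2 * n_offspring, Ha.shape[1]), dtype=np.int8)
        Hn[0::2] = g1
        Hn[1::2] = g2
        haps.append(Hn)
    ids_a, ids_b = sa.ids(), sb.ids()
    gen = max(sa.generation, sb.generation) + 1
    st = _State(haplotypes=haps, generation=gen, matings=[], pop=population)
    mat = pd.DataFrame(
        {
            "animal": [f"{population}_G{gen}_{i}" for i in range(n_offspring)],
            "sire": [ids_a[s] for s in sires],
            "dam": [ids_b[d] for d in dams],
            "population": population,
        }
    )
    st.matings = [*(m.copy() for m in sa.matings), *(m.copy() for m in sb.matings), mat]
    out = _export(st, replace(config, n_sampled=None), marker_map, rng)
    return out
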