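import numpy as np
import pytest
from scipy import stats

from pigpop import (
    allele_stats,
    f_pedigree,
    make_f1,
    simulate_population,
    split_populations,
)
from pigpop.sim import SimConfig


class TestDeterminismAndConfig:
    def test_same_seed_identical_panels(self):
        cfg = SimConfig(chromosomes=2, n_markers=60, ne=30, burn_in_generations=15, seed=5)
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        np.testing.assert_array_equal(a.panel.dosages, b.panel.dosages)
        assert a.pedigree.table.equals(b.pedigree.table)

    def test_different_seed_differs(self):
        cfg = SimConfig(chromosomes=1, n_markers=60, ne=30, burn_in_generations=15, seed=5)
        a = simulate_population(cfg)
        b = simulate_population(SimConfig(**{**cfg.__dict__, "seed": 6}))
        assert not np.array_equal(a.panel.dosages, b.panel.dosages)

    def test_trajectory_validation(self):
        with pytest.raises(ValueError, match="outside"):
            SimConfig(burn_in_generations=10, ne_trajectory=[(50, 100)])

    def test_trajectory_changes_census_size(self):
        cfg = SimConfig(
            chromosomes=1,
            n_markers=20,
            ne=40,
            ne_trajectory=[(0, 40), (5, 10)],
            burn_in_generations=10,
            seed=2,
        )
        out = simulate_population(cfg)
        assert out.panel.n_animals == 10


class TestMendelianTransmission:
    def test_zero_length_chromosome_transmits_whole_haplotypes(self):
        # with no recombination each gamete is an exact parental haplotype,
        # so single-locus transmission must follow Mendelian ratios
        cfg = SimConfig(
            chromosomes=1,
            chrom_length_cm=0.0,
            n_markers=10,
            ne=1000,
            burn_in_generations=1,
            seed=3,
        )
        out = simulate_population(cfg)
        # founders drawn at He ~ 2p(1-p); offspring genotype frequencies at
        # each locus should match HWE at the parental allele frequency
        st = allele_stats(out.panel)
        for j in range(10):
            p = st.p[j]
            counts = [
                int((out.panel.dosages[:, j] == k).sum()) for k in (2, 1, 0)
            ]
            exp = 1000 * np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
            chi2 = ((np.array(counts) - exp) ** 2 / np.maximum(exp, 1e-12)).sum()
            assert stats.chi2.sf(chi2, df=2) > 0.01

    def test_f1_genotypes_compatible_with_parents(self):
        base = simulate_population(
            SimConfig(chromosomes=1, n_markers=50, ne=20, burn_in_generations=10, seed=8)
        )
        pa, pb = split_populations(base, 5, names=("A", "B"))
        f1 = make_f1(pa, pb, n_offspring=30, seed=9)
        parents = f1.pedigree.parents_of()
        dos_a = {aid: pa.panel.dosages[i] for i, aid in enumerate(pa.panel.animal_ids)}
        dos_b = {aid: pb.panel.dosages[i] for i, aid in enumerate(pb.panel.animal_ids)}
        for i, animal in enumerate(f1.panel.animal_ids):
            sire, dam = parents[animal]
            child = f1.panel.dosages[i]
            s, d = dos_a[sire], dos_b[dam]
            # a parent homozygous for one allele forces that allele in the gamete
            lo = (s == 2).astype(int) + (d == 2).astype(int)
            hi = 2 - ((s == 0).astype(int) + (d == 0).astype(int))
            assert np.all(child >= lo) and np.all(child <= hi)


class TestDrift:
    def test_allele_frequency_drift_variance(self):
        # one generation of drift: var(p' - p) ~ p(1-p)/(2N)
        cfg = SimConfig(
            chromosomes=1,
            chrom_length_cm=100.0,
            n_markers=500,
            ne=50,
            burn_in_generations=1,
            init_maf_range=(0.5, 0.5),
            seed=10,
        )
        out = simulate_population(cfg)
        p1 = allele_stats(out.panel).p
        # founders were Bernoulli(0.5); one generation of sampling plus
        # founder sampling noise: total variance ~ 2 * p(1-p)/(2N)
        var = np.var(p1 - 0.5)
        expected = 2 * 0.5 * 0.5 / (2 * 50)
        assert var == pytest.approx(expected, rel=0.2)


class TestSplitAndF1:
    def test_zero_generation_split_identical(self):
        base = simulate_population(
            SimConfig(chromosomes=1, n_markers=40, ne=25, burn_in_generations=10, seed=4)
        )
        a, b = split_populations(base, 0)
        np.testing.assert_array_equal(a.panel.dosages, b.panel.dosages)

    def test_f1_pedigree_inbreeding_zero(self):
        base = simulate_population(
            SimConfig(chromosomes=1, n_markers=40, ne=25, burn_in_generations=10, seed=4)
        )
        a, b = split_populations(base, 10)
        f1 = make_f1(a, b, n_offspring=20)
        f = f_pedigree(f1.pedigree)
        f1_ids = [x for x in f.index if x.startswith("F1_")]
        assert len(f1_ids) == 20
        assert (f[f1_ids] == 0.0).all()

    def test_f1_heterozygosity_exceeds_diverged_parents(self, split_series):
        pa, pb = split_series[100]
        f1 = make_f1(pa, pb, n_offspring=50, seed=12)
        ho = lambda p: np.nanmean(allele_stats(p.panel).h_obs)
        assert ho(f1) >= max(ho(pa), ho(pb))

    def test_incompatible_maps_rejected(self):
        a = simulate_population(
            SimConfig(chromosomes=1, n_markers=30, ne=10, burn_in_generations=3, seed=1)
        )
        b = simulate_population(
            SimConfig(chromosomes=1, n_markers=31, ne=10, burn_in_generations=3, seed=1)
        )
        with pytest.raises(ValueError, match="incompatible"):
            make_f1(a, b, n_offspring=5)
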