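import numpy as np
import pandas as pd
import pytest

from pigpop import (
    build_grm,
    f_excess_homozygosity,
    f_pedigree,
    f_vanraden,
    inbreeding_correlations,
    inbreeding_table,
)
from pigpop.io import Pedigree

from conftest import make_panel, random_panel
from oracles import f_pedigree_oracle


def pedigree_of(rows):
    return Pedigree(
        pd.DataFrame(rows, columns=["animal", "sire", "dam"]).assign(population="ALL")
    )


class TestFExcessHomozygosity:
    def test_all_heterozygous_at_half_frequency(self):
        # c=1 everywhere, p=0.5: each term 1 - 1/0.5 = -1
        panel = make_panel([[1.0, 1], [1, 1], [0, 0], [2, 2]])
        f = f_excess_homozygosity(panel)
        assert f.iloc[0] == pytest.approx(-1.0)

    def test_all_homozygous_at_half_frequency(self):
        panel = make_panel([[2.0, 0], [0, 2], [1, 1], [1, 1]])
        f = f_excess_homozygosity(panel)
        assert f.iloc[0] == pytest.approx(1.0)

    def test_two_marker_hand_case(self):
        # p = (0.5, 0.25), animal calls c = (1, 2): terms (-1, +1), mean 0
        from pigpop.diversity import AlleleStats

        freqs = AlleleStats(
            marker_ids=np.array(["m0", "m1"]),
            p=np.array([0.5, 0.25]),
            maf=np.array([0.5, 0.25]),
            h_obs=np.zeros(2),
            h_exp=np.zeros(2),
        )
        panel = make_panel([[1.0, 2.0]])
        f = f_excess_homozygosity(panel, freqs=freqs)
        assert f.iloc[0] == pytest.approx(0.0)

    def test_near_zero_mean_under_random_mating(self):
        panel = random_panel(np.random.default_rng(1), n=500, m=200)
        assert abs(f_excess_homozygosity(panel).mean()) < 0.02


class TestFVanRaden:
    def test_single_marker_closed_form(self):
        from pigpop.diversity import AlleleStats

        freqs = AlleleStats(
            marker_ids=np.array(["m0"]),
            p=np.array([0.5]),
            maf=np.array([0.5]),
            h_obs=np.zeros(1),
            h_exp=np.zeros(1),
        )
        panel = make_panel([[2.0]])
        assert f_vanraden(panel, freqs=freqs).iloc[0] == pytest.approx(1.0)

    def test_heterozygote_at_half_frequency_is_minus_one(self):
        panel = make_panel([[1.0, 1], [0, 2], [2, 0]])
        f = f_vanraden(panel)
        assert f.iloc[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("missing_rate", [0.0, 0.15])
    def test_equals_grm_diagonal(self, missing_rate):
        panel = random_panel(
            np.random.default_rng(6), n=50, m=200, missing_rate=missing_rate
        )
        f = f_vanraden(panel)
        g = build_grm(panel)
        np.testing.assert_allclose(f.to_numpy(), np.diag(g.values) - 1, atol=1e-10)

    def test_near_zero_mean_under_random_mating(self):
        panel = random_panel(np.random.default_rng(21), n=500, m=200)
        assert abs(f_vanraden(panel).mean()) < 0.02


class TestFPedigree:
    def test_outbred_offspring(self):
        ped = pedigree_of([("A", "0", "0"), ("B", "0", "0"), ("X", "A", "B")])
        assert f_pedigree(ped)["X"] == 0.0

    def test_full_sib_mating(self):
        ped = pedigree_of(
            [
                ("A", "0", "0"),
                ("B", "0", "0"),
                ("S1", "A", "B"),
                ("S2", "A", "B"),
                ("X", "S1", "S2"),
            ]
        )
        assert f_pedigree(ped)["X"] == pytest.approx(0.25)

    def test_parent_offspring_mating(self):
        ped = pedigree_of(
            [("A", "0", "0"), ("B", "0", "0"), ("C", "A", "B"), ("X", "A", "C")]
        )
        f = f_pedigree(ped)
        assert f["X"] == pytest.approx(0.25)
        # cross-check by explicit common-ancestor path counting
        parents = {r.animal: (r.sire, r.dam) for r in ped.table.itertuples()}
        assert f["X"] == pytest.approx(f_pedigree_oracle("X", parents))

    def test_matches_path_counting_on_random_small_pedigrees(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            rows = []
            for i in range(n):
                if i < 2 or rng.random() < 0.3:
                    rows.append((f"a{i}", "0", "0"))
                else:
                    s, d = rng.choice(i, size=2, replace=False)
                    rows.append((f"a{i}", f"a{s}", f"a{d}"))
            ped = pedigree_of(rows)
            f = f_pedigree(ped)
            parents = {r.animal: (r.sire, r.dam) for r in ped.table.itertuples()}
            for animal in f.index:
                assert f[animal] == pytest.approx(
                    f_pedigree_oracle(animal, parents), abs=1e-12
                )


class TestCorrelations:
    def _table(self, f_eh, f_vr, f_roh, f_ped, pop="P"):
        n = len(f_eh)
        return pd.DataFrame(
            {
                "population": [pop] * n,
                "F_EH": f_eh,
                "F_VR": f_vr,
                "F_ROH": f_roh,
                "F_PED": f_ped,
            },
            index=[f"i{k}" for k in range(n)],
        )

    def test_duplicated_coefficient_correlates_perfectly(self):
        x = [0.1, 0.2, 0.3, 0.15]
        tab = self._table(x, x, [0.0, 0.1, 0.2, 0.05], [0.0, 0.05, 0.1, 0.02])
        out = inbreeding_correlations(tab)
        row = out[(out.coef_a == "F_EH") & (out.coef_b == "F_VR")].iloc[0]
        assert row.pearson_r == pytest.approx(1.0)
        assert not row.degenerate

    def test_zero_variance_f_ped_reported_as_zero_with_flag(self):
        tab = self._table(
            [0.1, 0.2, 0.3], [0.1, 0.25, 0.28], [0.0, 0.1, 0.2], [0.0, 0.0, 0.0]
        )
        out = inbreeding_correlations(tab)
        ped_rows = out[(out.coef_a == "F_PED") | (out.coef_b == "F_PED")]
        assert (ped_rows.pearson_r == 0.0).all()
        assert ped_rows.degenerate.all()

    def test_froh_fped_positively_correlated_in_inbred_simulation(
        self, wf_constant_ne100
    ):
        from pigpop import detect_roh, f_roh

        panel = wf_constant_ne100.panel
        segments = detect_roh(panel)
        froh = f_roh(segments, panel.map, panel.animal_ids)
        tab = inbreeding_table(panel, f_roh=froh, pedigree=wf_constant_ne100.pedigree)
        out = inbreeding_correlations(tab)
        row = out[(out.coef_a == "F_ROH") & (out.coef_b == "F_PED")].iloc[0]
        assert row.pearson_r > 0
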