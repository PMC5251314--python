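import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigpop import composite_ld_pair, ld_scan, summarize_ld
from pigpop.ld import DEFAULT_DISTANCE_CLASSES, pairwise_r2_matrix

from conftest import make_panel, random_panel
from oracles import ld_oracle


class TestCompositeLDPair:
    def test_hand_evaluated_example(self):
        # f(A)=0.5, f(B)=0.75, joint term 7/8, D = (4/3)(7/8 - 3/4) = 1/6,
        # r2 = (1/36)/(0.5*0.5*0.75*0.25) = 0.5926
        D, r2, sr = composite_ld_pair([2, 1, 1, 0], [2, 2, 1, 1])
        assert D == pytest.approx(1 / 6)
        assert r2 == pytest.approx(16 / 27)
        assert sr == pytest.approx(np.sqrt(16 / 27))
        oD, or2, osr = ld_oracle([2, 1, 1, 0], [2, 2, 1, 1])
        assert D == pytest.approx(oD, abs=1e-15)
        assert r2 == pytest.approx(or2, abs=1e-15)

    def test_identical_vectors_clamp_r2_to_one(self):
        # uncorrected D = 0.25 already gives r2 = 1; the N/(N-1) factor
        # pushes the raw ratio above 1 and the clamp holds it at 1
        D, r2, sr = composite_ld_pair([2, 1, 1, 0], [2, 1, 1, 0])
        assert D == pytest.approx(0.25 * 4 / 3)
        assert r2 == 1.0 and sr == 1.0

    def test_monomorphic_pair_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            composite_ld_pair([2, 2, 2], [0, 1, 2])

    def test_missing_handled_as_complete_pairs(self):
        D, r2, _ = composite_ld_pair(
            [2, 1, np.nan, 1, 0], [2, 2, 0, 1, 1]
        )
        D2, r22, _ = composite_ld_pair([2, 1, 1, 0], [2, 2, 1, 1])
        assert (D, r2) == (D2, r22)

    def test_independent_markers_decorrelate_in_large_samples(self):
        rng = np.random.default_rng(14)
        n = 1000
        r2s = []
        for _ in range(50):
            a = rng.binomial(2, 0.4, size=n).astype(float)
            b = rng.binomial(2, 0.3, size=n).astype(float)
            r2s.append(composite_ld_pair(a, b)[1])
        assert np.mean(r2s) < 0.02

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.integers(4, 30),
        st.integers(0, 2**31 - 1),
    )
    def test_symmetry_and_bounds(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, size=n).astype(float)
        b = rng.integers(0, 3, size=n).astype(float)
        if len(set(a)) == 1 or len(set(b)) == 1:
            return
        try:
            D1, r21, sr1 = composite_ld_pair(a, b)
            D2, r22, sr2 = composite_ld_pair(b, a)
        except ValueError:
            return  # monomorphic among complete pairs
        assert D1 == pytest.approx(D2, abs=1e-14)
        assert r21 == pytest.approx(r22, abs=1e-14)
        assert 0 <= r21 <= 1
        assert sr1 * sr1 == pytest.approx(r21, abs=1e-12)
        if sr1 != 0:
            assert np.sign(sr1) == (1.0 if D1 > 0 else -1.0)

    def test_matrix_path_agrees_with_pair_path(self):
        panel = random_panel(np.random.default_rng(2), n=30, m=12, missing_rate=0.1)
        r2m = pairwise_r2_matrix(panel.dosages)
        for i in range(12):
            for j in range(i + 1, 12):
                try:
                    _, r2, _ = composite_ld_pair(
                        panel.dosages[:, i], panel.dosages[:, j]
                    )
                except ValueError:
                    assert np.isnan(r2m[i, j])
                    continue
                assert r2m[i, j] == pytest.approx(r2, abs=1e-12)


class TestLDScan:
    def test_all_pairs_combinatorics(self):
        panel = make_panel(
            [[0.0, 1, 2], [1, 2, 0], [2, 0, 1], [1, 1, 1]],
            positions_bp=[10_000, 20_000, 30_000],
        )
        rec = ld_scan(panel, max_distance_mbp=5)
        assert len(rec) == 3
        assert list(rec["id_a"]) == ["m0", "m0", "m1"]

    def test_adjacent_only(self):
        rng = np.random.default_rng(1)
        panel = random_panel(rng, n=30, m=5, maf_range=(0.4, 0.5))
        rec = ld_scan(panel, adjacent_only=True)
        assert len(rec) == 4

    def test_max_distance_excludes_far_pairs(self):
        panel = make_panel(
            [[0.0, 1], [1, 2], [2, 0], [1, 1]],
            positions_bp=[10_000, 60_000],
        )
        assert ld_scan(panel, max_distance_mbp=0.02).empty

    def test_deterministic_order_and_positive_distance(self):
        panel = random_panel(np.random.default_rng(3), n=15, m=20)
        rec = ld_scan(panel)
        assert (rec["distance_mbp"] > 0).all()
        assert (rec["bp_a"] < rec["bp_b"]).all()


class TestSummarizeLD:
    def _records(self, dists, r2s):
        import pandas as pd

        return pd.DataFrame(
            {
                "distance_mbp": dists,
                "r2": r2s,
                "signed_r": np.sqrt(r2s),
                "n_animals": 10,
            }
        )

    def test_constant_records(self):
        rec = self._records([0.005, 0.02, 0.3, 2.5], np.full(4, 0.5))
        s = summarize_ld(rec)
        assert (s.bins["mean_r2"] == 0.5).all()
        assert s.useful_fractions[0.2] == 1.0
        assert s.useful_fractions[0.3] == 1.0

    def test_class_mean_and_threshold_fraction(self):
        rec = self._records([0.2, 0.3], np.array([0.1, 0.3]))
        s = summarize_ld(rec)
        row = s.class_means[s.class_means["class_lo"] == 0.10].iloc[0]
        assert row["mean_r2"] == pytest.approx(0.2)
        assert s.useful_fractions[0.3] == 0.5

    def test_half_open_boundary_convention(self):
        rec = self._records([5.0], np.array([0.4]))
        s = summarize_ld(rec, distance_classes=DEFAULT_DISTANCE_CLASSES)
        assert s.class_means.empty  # exactly 5.0 falls outside the 4-5 class

    def test_decay_monotone_in_simulated_population(self, wf_constant_ne100):
        rec = ld_scan(wf_constant_ne100.panel, max_distance_mbp=5.0)
        s = summarize_ld(rec)
        means = s.class_means["mean_r2"].to_numpy()
        inversions = int((np.diff(means) > 0).sum())
        assert inversions <= 1
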