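"""Normalization stages: MA transform, GC-grouped loess, A-quantile,
windowed median smoothing."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profile
from medipchip import simulate_hybridizations
from medipchip.normalization import (AlignmentError, StageError,
                                     aquantile_across_arrays, compute_ma,
                                     gc_group_loess, ma_from_hybridizations,
                                     window_median_smooth)
from medipchip.simulate import SyntheticTruth

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


class TestComputeMA:
    def test_printed_formula(self):
        assert compute_ma(10, 4) == (6, 7)

    def test_equal_channels(self):
        m, a = compute_ma(8.5, 8.5)
        assert m == 0 and a == 8.5

    @settings(derandomize=True, max_examples=100)
    @given(finite, finite)
    def test_algebraic_inversion(self, m, a):
        cy5, cy3 = a + m / 2, a - m / 2
        m2, a2 = compute_ma(cy5, cy3)
        assert m2 == pytest.approx(m, abs=1e-9)
        assert a2 == pytest.approx(a, abs=1e-9)

    def test_nonfinite_propagates_to_invalid_flag(self, small_annotation):
        truth = SyntheticTruth.empty(0)
        hybs = simulate_hybridizations(small_annotation, truth, seed=1,
                                       n_pairs=1)
        hybs.signals.iloc[0, 0] = np.nan
        prof = ma_from_hybridizations(hybs)[0]
        assert not prof.data["valid"].iloc[0]
        assert prof.data["valid"].iloc[1:].all()


class TestGCGroupLoess:
    def test_requires_raw_stage(self):
        prof = make_profile([100, 200, 300], [1, 2, 3], stage="loess")
        with pytest.raises(StageError):
            gc_group_loess(prof)

    def test_removes_gc_dependent_bias(self, small_annotation):
        hybs = simulate_hybridizations(small_annotation,
                                       SyntheticTruth.empty(0), noise_sd=0.3,
                                       dye_bias_amplitude=1.0, n_pairs=1,
                                       seed=3)
        raw = ma_from_hybridizations(hybs)[0]
        out = gc_group_loess(raw)
        # bias of amplitude ~1 reduced by an order of magnitude
        assert abs(raw.data["M"].mean()) > 5 * abs(out.data["M"].mean()) or \
            abs(out.data["M"].mean()) < 0.02
        groups = pd.qcut(out.data["gc_fraction"], 10, labels=False)
        for _, grp in out.data.groupby(groups):
            assert abs(grp["M"].mean()) < 0.05

    def test_a_and_coordinates_unchanged(self, small_annotation):
        hybs = simulate_hybridizations(small_annotation,
                                       SyntheticTruth.empty(0), seed=3,
                                       n_pairs=1)
        raw = ma_from_hybridizations(hybs)[0]
        out = gc_group_loess(raw)
        np.testing.assert_array_equal(raw.data["A"], out.data["A"])
        assert out.data.index.equals(raw.data.index)

    def test_small_group_falls_back_to_pooled_curve(self):
        rng = np.random.default_rng(0)
        n = 400
        mids = np.arange(100, 100 + 100 * n, 100)
        a = rng.normal(10, 0.5, n)
        m = 0.5 * (a - 10) + rng.normal(0, 0.1, n)
        gc = np.full(n, 0.5)
        gc[0] = 0.95  # lone high-GC probe: its decile is below the floor
        prof = make_profile(mids, m, a, stage="raw", gc=gc)
        out = gc_group_loess(prof, n_groups=10, min_group_size=50)
        pooled = gc_group_loess(make_profile(mids, m, a, stage="raw",
                                             gc=np.full(n, 0.5)), n_groups=1)
        assert out.data["M"].iloc[0] == pytest.approx(
            pooled.data["M"].iloc[0], abs=1e-9)

    def test_degenerate_identical_a_subtracts_median(self):
        n = 120
        mids = np.arange(100, 100 + 100 * n, 100)
        m = np.arange(n, dtype=float)
        prof = make_profile(mids, m, a=np.full(n, 10.0), stage="raw")
        out = gc_group_loess(prof, n_groups=1, min_group_size=10)
        np.testing.assert_allclose(out.data["M"], m - np.median(m))

    def test_idempotent_on_detrended_data(self, small_annotation):
        hybs = simulate_hybridizations(small_annotation,
                                       SyntheticTruth.empty(0), noise_sd=0.3,
                                       dye_bias_amplitude=1.0, n_pairs=1,
                                       seed=4)
        out = gc_group_loess(ma_from_hybridizations(hybs)[0])
        again = out.copy()
        again.stage = "raw"
        out2 = gc_group_loess(again)
        assert np.abs(out2.data["M"] - out.data["M"]).max() < 0.1


class TestAquantile:
    def test_three_probe_rank_mean_oracle(self):
        p1 = make_profile([100, 200, 300], [0.1, 0.2, 0.3], a=[1, 2, 3],
                          stage="loess")
        p2 = make_profile([100, 200, 300], [1.0, 2.0, 3.0], a=[3, 4, 5],
                          stage="loess", hyb=2)
        out = aquantile_across_arrays([p1, p2])
        np.testing.assert_allclose(out[0].data["A"], [2, 3, 4])
        np.testing.assert_allclose(out[1].data["A"], [2, 3, 4])
        np.testing.assert_allclose(out[0].data["M"], [0.1, 0.2, 0.3])
        np.testing.assert_allclose(out[1].data["M"], [1.0, 2.0, 3.0])

    def test_identical_arrays_are_fixed_point(self):
        p1 = make_profile([100, 200, 300], [1, 2, 3], a=[5, 6, 7],
                          stage="loess")
        p2 = make_profile([100, 200, 300], [1, 2, 3], a=[5, 6, 7],
                          stage="loess", hyb=2)
        out = aquantile_across_arrays([p1, p2])
        np.testing.assert_allclose(out[0].data["A"], [5, 6, 7])
        np.testing.assert_allclose(out[1].data["A"], [5, 6, 7])

    def test_sorted_a_vectors_identical_after(self, small_annotation):
        hybs = simulate_hybridizations(small_annotation,
                                       SyntheticTruth.empty(0), n_pairs=3,
                                       seed=5)
        profs = [gc_group_loess(p) for p in ma_from_hybridizations(hybs)]
        out = aquantile_across_arrays(profs)
        ref = np.sort(out[0].data["A"].to_numpy())
        for p in out[1:]:
            np.testing.assert_allclose(np.sort(p.data["A"].to_numpy()), ref,
                                       atol=1e-12)

    def test_matches_limma_aquantile(self, tmp_path):
        """Independent oracle: limma's normalizeBetweenArrays(Aquantile)."""
        import subprocess
        rng = np.random.default_rng(0)
        n, k = 200, 3
        a = rng.normal(10, 1, (n, k))
        m = rng.normal(0, 0.5, (n, k))
        np.savetxt(tmp_path / "A.tsv", a, delimiter="\t")
        np.savetxt(tmp_path / "M.tsv", m, delimiter="\t")
        (tmp_path / "aq.R").write_text(
            'suppressMessages(library(limma))\n'
            'A <- as.matrix(read.table("A.tsv"))\n'
            'M <- as.matrix(read.table("M.tsv"))\n'
            'out <- normalizeBetweenArrays(new("MAList", list(M=M, A=A)), '
            'method="Aquantile")\n'
            'write.table(out$A, "A_out.tsv", sep="\\t", row.names=FALSE, '
            'col.names=FALSE)\n')
        subprocess.run(["Rscript", "aq.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        a_limma = np.loadtxt(tmp_path / "A_out.tsv")
        mids = np.arange(100, 100 + n * 100, 100)
        profs = [make_profile(mids, m[:, j], a[:, j], stage="loess",
                              hyb=j + 1) for j in range(k)]
        out = aquantile_across_arrays(profs)
        for j in range(k):
            np.testing.assert_allclose(out[j].data["A"].to_numpy(),
                                       a_limma[:, j], atol=1e-10)

    def test_mismatched_probe_sets_rejected(self):
        p1 = make_profile([100, 200, 300], [1, 2, 3], stage="loess")
        p2 = make_profile([100, 200], [1, 2], stage="loess", hyb=2)
        with pytest.raises(AlignmentError, match="p0002"):
            aquantile_across_arrays([p1, p2])


def brute_force_smooth(profiles, window_bp=600, min_probes=3,
                       pool_arrays=True):
    """Independent nested-loop re-computation of the windowed median."""
    k = len(profiles)
    df0 = profiles[0].data
    mids = ((df0["start"] + df0["end"]) // 2).to_numpy()
    chrom = df0["chrom"].to_numpy()
    out_m = [np.full(len(df0), np.nan) for _ in range(k)]
    out_a = [np.full(len(df0), np.nan) for _ in range(k)]
    out_v = [np.zeros(len(df0), dtype=bool) for _ in range(k)]
    for i in range(len(df0)):
        members = [j for j in range(len(df0))
                   if chrom[j] == chrom[i]
                   and abs(mids[j] - mids[i]) <= window_bp / 2]
        if len({mids[j] for j in members}) < min_probes:
            continue
        for arr in range(k):
            if pool_arrays:
                vals_m, vals_a = [], []
                for j in members:
                    for a2 in range(k):
                        if profiles[a2].data["valid"].iloc[j]:
                            vals_m.append(profiles[a2].data["M"].iloc[j])
                            vals_a.append(profiles[a2].data["A"].iloc[j])
            else:
                vals_m = [profiles[arr].data["M"].iloc[j] for j in members
                          if profiles[arr].data["valid"].iloc[j]]
                vals_a = [profiles[arr].data["A"].iloc[j] for j in members
                          if profiles[arr].data["valid"].iloc[j]]
            if vals_m:
                out_m[arr][i] = np.median(vals_m)
                out_a[arr][i] = np.median(vals_a)
                out_v[arr][i] = True
    return out_m, out_a, out_v


class TestWindowMedianSmooth:
    def test_three_probe_median_example(self):
        p = make_profile([100, 200, 300], [1, 5, 9])
        out = window_median_smooth([p])[0]
        assert out.data["M"].iloc[1] == 5

    def test_median_of_constants(self):
        p = make_profile(np.arange(100, 1100, 100), np.full(10, 2.5))
        out = window_median_smooth([p])[0]
        valid = out.data["valid"]
        assert valid.any()
        np.testing.assert_allclose(out.data.loc[valid, "M"], 2.5)

    def test_isolated_probe_gets_no_value(self):
        p = make_profile([100, 200, 300, 10_000, 10_100], [1, 2, 3, 4, 5])
        out = window_median_smooth([p], min_probes=3)[0]
        assert not out.data["valid"].iloc[3]
        assert not out.data["valid"].iloc[4]
        assert np.isnan(out.data["M"].iloc[3])
        assert out.data["valid"].iloc[:3].all()

    @pytest.mark.parametrize("pool_arrays", [True, False])
    def test_matches_brute_force(self, pool_arrays):
        rng = np.random.default_rng(2)
        mids = np.sort(rng.choice(np.arange(100, 60_000, 25), size=300,
                                  replace=False))
        profs = [make_profile(mids, rng.normal(size=300),
                              rng.normal(10, 1, size=300), hyb=h + 1)
                 for h in range(2)]
        out = window_median_smooth([p.copy() for p in profs],
                                   pool_arrays=pool_arrays)
        bm, ba, bv = brute_force_smooth(profs, pool_arrays=pool_arrays)
        for j in range(2):
            np.testing.assert_array_equal(out[j].data["valid"], bv[j])
            np.testing.assert_allclose(out[j].data["M"].to_numpy(), bm[j])
            np.testing.assert_allclose(out[j].data["A"].to_numpy(), ba[j])

    def test_unsorted_input_rejected(self):
        p = make_profile([300, 100, 200], [1, 2, 3])
        with pytest.raises(ValueError, match="sorted"):
            window_median_smooth([p])

    def test_idempotent_on_piecewise_constant(self):
        p = make_profile(np.arange(100, 2100, 100), np.full(20, 1.5))
        out = window_median_smooth([p])[0]
        again = out.copy()
        again.stage = "aquantile"
        out2 = window_median_smooth([again])[0]
        valid = out2.data["valid"]
        np.testing.assert_allclose(out2.data.loc[valid, "M"],
                                   out.data.loc[valid, "M"])

    def test_probe_count_order_coordinates_unchanged(self, small_annotation):
        hybs = simulate_hybridizations(small_annotation,
                                       SyntheticTruth.empty(0), n_pairs=2,
                                       seed=6)
        profs = aquantile_across_arrays(
            [gc_group_loess(p) for p in ma_from_hybridizations(hybs)])
        out = window_median_smooth(profs)
        for before, after in zip(profs, out):
            assert after.data.index.equals(before.data.index)
            np.testing.assert_array_equal(after.data["start"],
                                          before.data["start"])
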