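"""Loop calling, insulation domains, loop domains, pixel counts, APA."""

import numpy as np
import pandas as pd
import pytest

from loopshift import loops as lp
from loopshift.counts import CountMatrix
from loopshift.hic import ContactMatrix, ice_balance

from conftest import planted_loop_matrix, poisson_symmetric


class TestCallLoops:
    def test_planted_focal_peaks_recovered(self):
        m, centers = planted_loop_matrix(400, 25, background=30.0,
                                         strength=5.0, seed=21)
        ice_balance(m)
        calls = lp.call_loops(m)
        hits = sum(((abs(calls["bin1"] - i) <= 2)
                    & (abs(calls["bin2"] - j) <= 2)).any() for i, j in centers)
        assert hits / len(centers) >= 0.8

    def test_near_diagonal_pixels_never_candidates(self):
        m, _ = planted_loop_matrix(100, 3, background=50.0, strength=8.0,
                                   seed=22, gap_lo=10, gap_hi=30)
        # plant an extreme enrichment just off the diagonal
        m.counts[40, 44] = m.counts[44, 40] = 5_000.0
        ice_balance(m)
        calls = lp.call_loops(m, peak_width=1, donut_width=5)
        assert not ((calls["bin2"] - calls["bin1"]) <= 6).any()

    def test_max_dist_below_span_errors(self):
        m, _ = planted_loop_matrix(60, 2, background=30.0, strength=5.0, seed=23)
        ice_balance(m)
        with pytest.raises(ValueError):
            lp.call_loops(m, max_dist=5 * m.resolution, donut_width=5)


class TestInsulation:
    def test_uniform_matrix_scores_near_zero(self):
        m = poisson_symmetric(100, 200.0, seed=24)
        ice_balance(m)
        ins = lp.insulation_scores(m, window=5)
        assert np.nanstd(ins) < 0.2
        assert np.abs(np.nanmean(ins)) < 0.05

    def test_two_block_minimum_at_junction(self):
        n = 60
        lam = np.full((n, n), 5.0)
        lam[:30, :30] = 80.0
        lam[30:, 30:] = 80.0
        m = poisson_symmetric(n, lam, seed=25)
        ice_balance(m)
        ins = lp.insulation_scores(m, window=5)
        # bins 29 and 30 both see a fully cross-block diamond
        assert np.nanargmin(ins) in (29, 30)

    def test_deterministic(self):
        m = poisson_symmetric(80, 50.0, seed=26)
        ice_balance(m)
        a = lp.insulation_scores(m, window=4)
        b = lp.insulation_scores(m, window=4)
        np.testing.assert_array_equal(a, b)

    def test_oversized_window_errors(self):
        m = poisson_symmetric(20, 5.0, seed=27)
        ice_balance(m)
        with pytest.raises(ValueError):
            lp.insulation_scores(m, window=10)


class TestDomains:
    def test_flat_scores_single_domain(self):
        ins = np.zeros(50)
        d = lp.call_domains(ins, min_depth=0.3)
        assert len(d) == 1
        assert (d.loc[0, "start_bin"], d.loc[0, "end_bin"]) == (0, 50)

    def test_two_block_fixture_two_domains(self):
        n = 60
        lam = np.full((n, n), 5.0)
        lam[:30, :30] = 80.0
        lam[30:, 30:] = 80.0
        m = poisson_symmetric(n, lam, seed=28)
        ice_balance(m)
        ins = lp.insulation_scores(m, window=5)
        d = lp.call_domains(ins, min_depth=0.5)
        assert len(d) == 2
        assert d.loc[0, "end_bin"] == 30 and d.loc[1, "start_bin"] == 30

    def test_domains_tile_without_overlap(self):
        rng = np.random.default_rng(29)
        ins = rng.normal(0, 1, 200)
        d = lp.call_domains(ins, min_depth=0.5)
        assert d.loc[0, "start_bin"] == 0
        assert (d["start_bin"].to_numpy()[1:] == d["end_bin"].to_numpy()[:-1]).all()


class TestLoopDomains:
    def domains(self):
        return pd.DataFrame({"start_bin": [10, 40], "end_bin": [25, 60]})

    def loops(self, rows):
        return pd.DataFrame(rows, columns=["bin1", "bin2"])

    def test_exact_boundary_match_included(self):
        ld = lp.identify_loop_domains(self.domains(), self.loops([(10, 25)]),
                                      slack=0)
        assert len(ld) == 1 and ld.loc[0, "start_bin"] == 10

    def test_no_matching_loop_excluded(self):
        ld = lp.identify_loop_domains(self.domains(), self.loops([(12, 30)]),
                                      slack=1)
        assert len(ld) == 0

    def test_slack_zero_requires_exact_bins(self):
        ld = lp.identify_loop_domains(self.domains(), self.loops([(11, 25)]),
                                      slack=0)
        assert len(ld) == 0

    def test_monotone_in_slack(self):
        rng = np.random.default_rng(30)
        doms = pd.DataFrame({"start_bin": np.arange(0, 100, 10),
                             "end_bin": np.arange(10, 110, 10)})
        loops = self.loops([(int(a), int(b))
                            for a, b in rng.integers(0, 110, (40, 2)) if a < b])
        sizes = [len(lp.identify_loop_domains(doms, loops, slack=s))
                 for s in (0, 1, 2, 3)]
        assert sizes == sorted(sizes)


class TestMergeLoopDomains:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["start_bin", "end_bin"])

    def test_identical_sets_collapse(self):
        a = self.frame([(10, 25), (40, 60)])
        merged = lp.merge_loop_domains(a, a)
        assert len(merged) == 2
        assert set(merged["provenance"]) == {"A,B"}

    def test_disjoint_sets_concatenate(self):
        a = self.frame([(10, 25)])
        b = self.frame([(100, 130)])
        assert len(lp.merge_loop_domains(a, b)) == 2

    def test_merge_is_idempotent(self):
        a = self.frame([(10, 25), (40, 60), (41, 61)])
        m1 = lp.merge_loop_domains(a, a.iloc[0:0])
        m2 = lp.merge_loop_domains(m1[["start_bin", "end_bin"]], a.iloc[0:0])
        pd.testing.assert_frame_equal(m1[["start_bin", "end_bin"]],
                                      m2[["start_bin", "end_bin"]])

    def test_size_bounded_by_sum(self):
        rng = np.random.default_rng(31)
        a = self.frame([(int(s), int(s + w)) for s, w in
                        zip(rng.integers(0, 200, 15), rng.integers(5, 30, 15))])
        b = self.frame([(int(s), int(s + w)) for s, w in
                        zip(rng.integers(0, 200, 15), rng.integers(5, 30, 15))])
        assert len(lp.merge_loop_domains(a, b)) <= len(a) + len(b)


class TestLoopPixelCounts:
    def matrices(self, seed=32):
        return {s: poisson_symmetric(50, 20.0, seed=seed + k)
                for k, s in enumerate(["WT_1", "WT_2", "MUT_1", "MUT_2"])}

    def conditions(self):
        return pd.Series(["WT", "WT", "MUT", "MUT"],
                         index=["WT_1", "WT_2", "MUT_1", "MUT_2"])

    def test_matches_block_sum_oracle(self):
        mats = self.matrices()
        loops = pd.DataFrame({"bin1": [10, 20], "bin2": [30, 44]})
        cm = lp.loop_pixel_counts(mats, loops, self.conditions(), pad=1)
        for k, s in enumerate(mats):
            for li, (b1, b2) in enumerate(zip(loops["bin1"], loops["bin2"])):
                oracle = mats[s].counts[b1 - 1:b1 + 2, b2 - 1:b2 + 2].sum()
                assert cm.counts.iloc[li, k] == oracle

    def test_pad_zero_single_pixel(self):
        mats = self.matrices(seed=40)
        loops = pd.DataFrame({"bin1": [10], "bin2": [30]})
        cm = lp.loop_pixel_counts(mats, loops, self.conditions(), pad=0)
        assert cm.counts.iloc[0, 0] == mats["WT_1"].counts[10, 30]

    def test_empty_loop_set(self):
        cm = lp.loop_pixel_counts(self.matrices(seed=44),
                                  pd.DataFrame({"bin1": [], "bin2": []}),
                                  self.conditions())
        assert cm.counts.shape[0] == 0

    def test_out_of_bounds_errors(self):
        with pytest.raises(ValueError):
            lp.loop_pixel_counts(self.matrices(seed=48),
                                 pd.DataFrame({"bin1": [0], "bin2": [30]}),
                                 self.conditions(), pad=1)


class TestDifferentialLoops:
    def test_identical_replicates_nothing_significant(self):
        rng = np.random.default_rng(33)
        base = rng.poisson(200, 60)
        counts = pd.DataFrame({s: base for s in ["WT_1", "WT_2", "MUT_1", "MUT_2"]})
        cm = CountMatrix(counts=counts,
                         conditions=pd.Series(["WT", "WT", "MUT", "MUT"],
                                              index=counts.columns))
        t = lp.differential_loops(cm)
        assert (t["label"] == "ns").all()

    def test_planted_strengthened_recovered(self):
        rng = np.random.default_rng(34)
        alpha = 0.05
        lam = rng.gamma(1 / alpha, alpha * 300.0, size=(100, 1))
        lam = np.broadcast_to(lam, (100, 4)).copy()
        lam[:20, 2:] *= 2.0
        counts = pd.DataFrame(rng.poisson(lam),
                              columns=["WT_1", "WT_2", "MUT_1", "MUT_2"])
        cm = CountMatrix(counts=counts,
                         conditions=pd.Series(["WT", "WT", "MUT", "MUT"],
                                              index=counts.columns))
        t = lp.differential_loops(cm)
        assert (t["label"][:20] == "strengthened").mean() >= 0.7
        assert t["label"].isin(["strengthened", "weakened", "ns"]).all()


class TestApa:
    def test_close_loops_dropped(self):
        m = poisson_symmetric(200, 30.0, seed=35)
        ice_balance(m)
        loops = pd.DataFrame({"bin1": [50, 20], "bin2": [60, 120]})
        res = lp.apa(m, loops, window=10)
        assert res["n_used"] == 1 and res["n_dropped"] == 1

    def test_no_eligible_loops_errors(self):
        m = poisson_symmetric(100, 30.0, seed=36)
        ice_balance(m)
        with pytest.raises(ValueError):
            lp.apa(m, pd.DataFrame({"bin1": [10], "bin2": [20]}), window=10)

    def test_aggregate_equals_mean_per_loop_on_uniform_background(self):
        n = 400
        base = np.full((n, n), 40.0)
        rng = np.random.default_rng(37)
        centers = [(int(i), int(i + g)) for i, g in
                   zip(rng.integers(15, 300, 10), rng.integers(30, 80, 10))]
        for i, j in centers:
            base[i, j] *= 4
            base[j, i] *= 4
        m = ContactMatrix(chrom="c", resolution=50_000, counts=base)
        ice_balance(m, mad_cutoff=None)
        res = lp.apa(m, pd.DataFrame(centers, columns=["bin1", "bin2"]),
                     window=10)
        assert res["score"] == pytest.approx(res["per_loop_scores"].mean(),
                                             rel=0.05)


class TestCompareApa:
    def test_identical_scores(self):
        out = lp.compare_apa([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert out["t"] == 0.0 and out["pvalue"] == 1.0

    def test_shift_detected(self):
        rng = np.random.default_rng(38)
        a = rng.normal(2.0, 0.2, 100)
        out = lp.compare_apa(a, a + 0.3 + rng.normal(0, 0.05, 100))
        assert out["pvalue"] < 0.01

    def test_antisymmetric(self):
        rng = np.random.default_rng(39)
        a = rng.normal(2.0, 0.3, 30)
        b = rng.normal(2.4, 0.3, 30)
        assert lp.compare_apa(a, b)["t"] == pytest.approx(-lp.compare_apa(b, a)["t"])

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            lp.compare_apa([1.0, 2], [2.0, 3])
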