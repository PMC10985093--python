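"""Interval model, BED/BEDPE I/O, and interval arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from loopshift import intervals as iv


def write(tmp_path, text, name="f.bed"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestBedIO:
    def test_basic_record(self, tmp_path):
        df = iv.read_bed(write(tmp_path, "chr1\t100\t200\n"))
        assert len(df) == 1
        assert (df.loc[0, "chrom"], df.loc[0, "start"], df.loc[0, "end"]) == \
            ("chr1", 100, 200)
        assert df.loc[0, "strand"] == "."

    def test_empty_file(self, tmp_path):
        assert len(iv.read_bed(write(tmp_path, ""))) == 0

    def test_inverted_interval_errors_with_line_number(self, tmp_path):
        with pytest.raises(iv.BedFormatError, match="line 2"):
            iv.read_bed(write(tmp_path, "chr1\t1\t2\nchr1\t300\t200\n"))

    def test_unknown_chrom_errors_only_with_genome(self, tmp_path, genome_small):
        p = write(tmp_path, "chrZ\t10\t20\n")
        assert len(iv.read_bed(p)) == 1
        with pytest.raises(iv.BedFormatError, match="chrZ"):
            iv.read_bed(p, genome=genome_small)

    def test_bed6_roundtrip(self, tmp_path):
        a = iv.make_intervals(["chr1", "chr2"], [5, 0], [50, 7],
                              names=["a", "b"], strands=["+", "-"])
        path = tmp_path / "rt.bed"
        iv.write_bed(a, path)
        b = iv.read_bed(path)
        pd.testing.assert_frame_equal(a[iv.INTERVAL_COLUMNS], b[iv.INTERVAL_COLUMNS])


class TestBedpeIO:
    def test_canonical_anchor_order(self, tmp_path):
        txt = "chr1\t5000\t6000\tchr1\t1000\t2000\n"
        df = iv.read_bedpe(write(tmp_path, txt, "f.bedpe"))
        assert df.loc[0, "start1"] == 1000 and df.loc[0, "start2"] == 5000
        assert bool(df.loc[0, "intra"])

    def test_roundtrip_preserves_records(self, tmp_path):
        txt = "chr1\t1000\t2000\tchr1\t5000\t6000\tx\t0.5\n" \
              "chr2\t0\t100\tchr1\t0\t100\n"
        p = write(tmp_path, txt, "f.bedpe")
        df = iv.read_bedpe(p)
        out = tmp_path / "g.bedpe"
        iv.write_bedpe(df, out)
        df2 = iv.read_bedpe(out)
        pd.testing.assert_frame_equal(df, df2)

    def test_malformed_errors(self, tmp_path):
        with pytest.raises(iv.BedFormatError, match="line 1"):
            iv.read_bedpe(write(tmp_path, "chr1\t1\t2\tchr1\t3\n", "f.bedpe"))


class TestIntersect:
    @pytest.mark.parametrize("a,b,expect_len", [
        ((100, 200), (150, 250), 50),   # partial overlap
        ((100, 200), (200, 300), None),  # half-open: touching is no overlap
        ((100, 200), (100, 200), 100),
    ])
    def test_half_open_semantics(self, a, b, expect_len):
        A = iv.make_intervals(["chr1"], [a[0]], [a[1]])
        B = iv.make_intervals(["chr1"], [b[0]], [b[1]])
        hits = iv.intersect(A, B)
        if expect_len is None:
            assert len(hits) == 0
        else:
            assert len(hits) == 1 and hits.loc[0, "overlap"] == expect_len

    def test_different_chroms_never_overlap(self):
        A = iv.make_intervals(["chr1"], [0], [100])
        B = iv.make_intervals(["chr2"], [0], [100])
        assert len(iv.intersect(A, B)) == 0


class TestMerge:
    def test_overlapping_pair_merges(self):
        a = iv.make_intervals(["chr1", "chr1"], [100, 150], [200, 250])
        m = iv.merge_overlapping(a)
        assert len(m) == 1 and m.loc[0, "start"] == 100 and m.loc[0, "end"] == 250

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_merge_is_idempotent_and_disjoint(self, raw):
        starts = [s for s, _ in raw]
        ends = [s + w for s, w in raw]
        a = iv.make_intervals(["chr1"] * len(raw), starts, ends)
        m = iv.merge_overlapping(a)
        # disjoint & sorted
        assert (m["start"].to_numpy()[1:] >= m["end"].to_numpy()[:-1]).all()
        pd.testing.assert_frame_equal(iv.merge_overlapping(m), m)
        # coverage preserved
        cov = np.zeros(600, dtype=bool)
        for s, e in zip(starts, ends):
            cov[s:e] = True
        cov2 = np.zeros(600, dtype=bool)
        for s, e in zip(m["start"], m["end"]):
            cov2[s:e] = True
        assert (cov == cov2).all()


class TestShuffle:
    def test_preserves_lengths_and_chroms(self, genome_small):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 400_000, 50)
        a = iv.make_intervals(["chr1"] * 30 + ["chr2"] * 20, starts,
                              starts + rng.integers(100, 5000, 50))
        b = iv.shuffle_intervals(a, genome_small, seed=3)
        assert sorted(b["end"] - b["start"]) == sorted(a["end"] - a["start"])
        assert (a["chrom"] == b["chrom"]).all()
        assert (b["start"] >= 0).all()
        for chrom, length in genome_small.chroms:
            assert (b.loc[b["chrom"] == chrom, "end"] <= length).all()

    def test_same_seed_is_deterministic(self, genome_small):
        a = iv.make_intervals(["chr1"] * 5, [0, 10, 20, 30, 40],
                              [5, 15, 25, 35, 45])
        pd.testing.assert_frame_equal(
            iv.shuffle_intervals(a, genome_small, seed=7),
            iv.shuffle_intervals(a, genome_small, seed=7))

    def test_oversized_interval_errors(self, genome_small):
        a = iv.make_intervals(["chr2"], [0], [600_000])
        with pytest.raises(ValueError):
            iv.shuffle_intervals(a, genome_small, seed=0)

    def test_midpoints_uniform_over_chromosome(self, genome_small):
        # mean midpoint of 1000 shuffles of one peak ~ chrom center
        a = iv.make_intervals(["chr1"], [0], [10_000])
        rng = np.random.default_rng(5)
        mids = [float(iv.shuffle_intervals(a, genome_small, rng).loc[0, "start"])
                + 5_000 for _ in range(1000)]
        L = 1_000_000
        se = (L - 10_000) / np.sqrt(12) / np.sqrt(1000)
        assert abs(np.mean(mids) - L / 2) < 3 * se


class TestPromoters:
    def test_plus_strand_window(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [15_000],
                              "strand": ["+"], "gene_id": ["g"]})
        p = iv.promoters_from_genes(genes)
        assert (p.loc[0, "start"], p.loc[0, "end"]) == (7_000, 10_000)

    def test_minus_strand_window(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [5_000], "end": [8_000],
                              "strand": ["-"], "gene_id": ["g"]})
        p = iv.promoters_from_genes(genes)
        assert (p.loc[0, "start"], p.loc[0, "end"]) == (8_000, 11_000)

    def test_clipped_at_chromosome_start(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [1_000], "end": [2_000],
                              "strand": ["+"], "gene_id": ["g"]})
        p = iv.promoters_from_genes(genes)
        assert (p.loc[0, "start"], p.loc[0, "end"]) == (0, 1_000)

    def test_widths_equal_upstream_except_clipped(self):
        rng = np.random.default_rng(2)
        starts = rng.integers(0, 900_000, 100)
        genes = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + 5_000,
                              "strand": rng.choice(["+", "-"], 100),
                              "gene_id": [f"g{i}" for i in range(100)]})
        p = iv.promoters_from_genes(genes, upstream=3000)
        widths = (p["end"] - p["start"]).to_numpy()
        clipped = (genes["strand"] == "+") & (genes["start"] < 3000)
        assert (widths[~clipped.to_numpy()] == 3000).all()


class TestRegulatoryRegions:
    def test_enhancers_exclude_promoter_overlaps(self):
        k27 = iv.make_intervals(["chr1", "chr1"], [100, 5_000], [500, 5_400])
        prom = iv.make_intervals(["chr1"], [400], [1_000])
        e = iv.define_enhancers(k27, prom)
        assert list(e["start"]) == [5_000]
        assert len(iv.define_enhancers(k27, prom.iloc[0:0])) == 2

    def test_insulators_require_cohesin_overlap(self):
        ctcf = iv.make_intervals(["chr1", "chr1"], [100, 5_000], [500, 5_400])
        coh = iv.make_intervals(["chr1"], [450], [600])
        ins = iv.define_insulators(ctcf, coh)
        assert list(ins["start"]) == [100]
        assert len(iv.define_insulators(ctcf, coh.iloc[0:0])) == 0


class TestCountOverlaps:
    def test_positions_counted_per_target(self):
        q = iv.make_intervals(["chr1", "chr1"], [150, 160], [151, 161])
        t = iv.make_intervals(["chr1"], [100], [200])
        assert iv.count_overlaps(q, t).tolist() == [2]
        assert iv.count_overlaps(q.iloc[0:0], t).tolist() == [0]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n_q, n_t = rng.integers(5, 40, 2)
            qs = rng.integers(0, 10_000, n_q)
            ts = rng.integers(0, 10_000, n_t)
            q = iv.make_intervals(["chr1"] * n_q, qs, qs + rng.integers(1, 500, n_q))
            t = iv.make_intervals(["chr1"] * n_t, ts, ts + rng.integers(1, 500, n_t))
            oracle = [sum(max(a, c) < min(b, d)
                          for a, b in zip(q["start"], q["end"]))
                      for c, d in zip(t["start"], t["end"])]
            assert iv.count_overlaps(q, t).tolist() == oracle


class TestSignalProfile:
    def make_track(self, genome_small, values):
        tr = iv.SignalTrack(genome=genome_small, bin_size=1000)
        tr.values["chr1"][:] = values
        return tr

    def test_constant_track_gives_flat_profile(self, genome_small):
        tr = self.make_track(genome_small, 2.5)
        regions = iv.make_intervals(["chr1"] * 3, [100_000, 200_000, 300_000],
                                    [101_000, 201_000, 301_000])
        prof = iv.aggregate_signal_profile(tr, regions, flank=5_000)
        assert prof.shape == (11,)
        assert np.allclose(prof, 2.5)

    def test_impulse_at_centers(self, genome_small):
        tr = self.make_track(genome_small, 0.0)
        centers = [100_500, 200_500]
        for c in centers:
            tr.values["chr1"][c // 1000] = 1.0
        regions = iv.make_intervals(["chr1"] * 2, [c - 500 for c in centers],
                                    [c + 500 for c in centers])
        prof = iv.aggregate_signal_profile(tr, regions, flank=3_000)
        assert prof[3] == 1.0 and prof.sum() == 1.0

    def test_matches_naive_window_mean(self, genome_small):
        rng = np.random.default_rng(1)
        tr = self.make_track(genome_small, rng.random(1000))
        starts = rng.integers(20_000, 900_000, 40)
        regions = iv.make_intervals(["chr1"] * 40, starts, starts + 2_000)
        flank = 10_000
        prof = iv.aggregate_signal_profile(tr, regions, flank=flank)
        f = flank // 1000
        naive = np.mean([tr.values["chr1"][(s + 1000) // 1000 - f:
                                           (s + 1000) // 1000 + f + 1]
                         for s in starts], axis=0)
        assert np.allclose(prof, naive)

    def test_empty_regions_error(self, genome_small):
        tr = self.make_track(genome_small, 1.0)
        with pytest.raises(ValueError):
            iv.aggregate_signal_profile(tr, tr.values and
                                        iv.make_intervals([], [], []), 2_000)

    def test_bedgraph_roundtrip(self, genome_small, tmp_path):
        rng = np.random.default_rng(3)
        tr = self.make_track(genome_small, np.round(rng.random(1000), 4))
        tr.to_bedgraph(tmp_path / "t.bg")
        tr2 = iv.SignalTrack.from_bedgraph(tmp_path / "t.bg", genome_small, 1000)
        assert np.allclose(tr.values["chr1"], tr2.values["chr1"])


class TestPeakAnnotation:
    def test_one_peak_per_category(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [50_000],
                              "end": [60_000], "strand": ["+"], "gene_id": ["g"]})
        promoters = iv.promoters_from_genes(genes)
        insulators = iv.make_intervals(["chr1"], [80_000], [81_000])
        peaks = iv.make_intervals(
            ["chr1"] * 4,
            [48_000, 80_200, 55_000, 200_000],
            [48_400, 80_600, 55_400, 200_400])
        labels, fractions = iv.annotate_peak_location(peaks, genes, promoters,
                                                      insulators)
        assert labels.tolist() == ["promoter", "insulator", "gene_body",
                                   "intergenic"]
        assert fractions == {c: 0.25 for c in iv.PEAK_CATEGORIES}

    def test_promoter_precedence_over_gene_body(self):
        # a promoter inside another gene's body is still "promoter"
        genes = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [10_000, 0],
                              "end": [15_000, 50_000], "strand": ["+", "+"],
                              "gene_id": ["a", "b"]})
        promoters = iv.promoters_from_genes(genes)
        peaks = iv.make_intervals(["chr1"], [8_000], [8_400])
        labels, _ = iv.annotate_peak_location(peaks, genes, promoters,
                                              iv.make_intervals([], [], []))
        assert labels.tolist() == ["promoter"]

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 900_000, 200)
        peaks = iv.make_intervals(["chr1"] * 200, starts, starts + 400)
        genes = pd.DataFrame({"chrom": "chr1",
                              "start": rng.integers(0, 900_000, 30),
                              "end": 0, "strand": "+",
                              "gene_id": [f"g{i}" for i in range(30)]})
        genes["end"] = genes["start"] + 20_000
        promoters = iv.promoters_from_genes(genes)
        labels, fr = iv.annotate_peak_location(
            peaks, genes, promoters, iv.make_intervals([], [], []))
        assert abs(sum(fr.values()) - 1.0) < 1e-12
        assert len(labels) == 200
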