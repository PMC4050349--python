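"""Window binning, RPKM, subtraction, correlation, islands, Hilbert curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromodyn import medip, synthdata

SIZES = {"chr1": 10_000}


def reads(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestBinCounts:
    def test_midpoint_rule_window_index(self):
        # 1 kb interval with midpoint 2,500 lands in window 1 of 2,000 bp grid
        track = medip.bin_counts(
            reads([("chr1", 2000, 3000)]), SIZES, window=2000
        )
        counts = track.windows["count"].to_numpy()
        assert counts[1] == 1 and counts.sum() == 1

    def test_empty_input_zero_counts_correct_window_count(self):
        track = medip.bin_counts(reads([]), {"chr1": 10_500}, window=2000)
        assert len(track.windows) == 6  # ceil(10500/2000)
        assert (track.windows["count"] == 0).all()
        assert track.windows["end"].iloc[-1] == 10_500  # truncated last window

    def test_exact_window_arithmetic(self):
        track = medip.bin_counts(reads([]), SIZES, window=2000)
        assert len(track.windows) == 5

    def test_count_conservation(self, rng):
        rows = []
        for _ in range(500):
            s = int(rng.integers(0, 9_800))
            rows.append(("chr1", s, s + 200))
        track = medip.bin_counts(reads(rows), SIZES, window=700)
        assert track.windows["count"].sum() == 500
        assert track.total_mapped == 500

    def test_out_of_bounds_interval_named_in_error(self):
        with pytest.raises(ValueError, match="chr1:9900-10100"):
            medip.bin_counts(reads([("chr1", 9900, 10_100)]), SIZES, 1000)

    def test_coverage_apportioned_by_overlap(self):
        cov = pd.DataFrame(
            [("chr1", 900, 1100, 2.0)], columns=["chrom", "start", "end", "value"]
        )
        track = medip.bin_counts(cov, SIZES, window=1000)
        counts = track.windows["count"].to_numpy()
        assert counts[0] == pytest.approx(200.0)  # 100 bp * 2.0
        assert counts[1] == pytest.approx(200.0)


class TestRpkm:
    def test_formula(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [2000], "count": [10]}
        )
        track = medip.rpkm(medip.GenomicTrack(df, 2000, 1_000_000))
        assert track.windows["rpkm"].iloc[0] == pytest.approx(5.0)

    def test_zero_counts_zero_rpkm(self):
        track = medip.rpkm(medip.bin_counts(reads([("chr1", 0, 100)]), SIZES, 1000))
        assert (track.windows["rpkm"].iloc[1:] == 0).all()

    def test_depth_invariance(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [0, 1000], "end": [1000, 2000],
             "count": [10, 30]}
        )
        a = medip.rpkm(medip.GenomicTrack(df, 1000, 1_000_000))
        doubled = df.copy()
        doubled["count"] *= 2
        b = medip.rpkm(medip.GenomicTrack(doubled, 1000, 2_000_000))
        assert np.allclose(a.windows["rpkm"], b.windows["rpkm"])

    def test_zero_total_rejected(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "count": [0]}
        )
        with pytest.raises(ValueError):
            medip.rpkm(medip.GenomicTrack(df, 1000, 0))


class TestSubtractInput:
    def make(self, counts, total=1_000_000):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(counts)) * 1000,
                "end": (np.arange(len(counts)) + 1) * 1000,
                "count": counts,
            }
        )
        return medip.GenomicTrack(df, 1000, total)

    def test_signal_equals_input_gives_zeros(self):
        t = self.make([5, 10, 15])
        diff = medip.subtract_input(t, t)
        assert np.allclose(diff["value"], 0.0)

    def test_zero_input_gives_signal_rpkm(self):
        sig = self.make([5, 10, 15])
        zero = self.make([0, 0, 0], total=1_000_000)
        diff = medip.subtract_input(sig, zero)
        assert np.allclose(diff["value"], medip.rpkm(sig).windows["rpkm"])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            medip.subtract_input(self.make([1, 2]), self.make([1, 2, 3]))

    def test_planted_enrichment_positive_inside(self, medip_sim):
        params, sim = medip_sim
        diff = medip.subtract_input(sim.tracks["chanA"], sim.tracks["input"])
        latent = sim.ground_truth.true_methylation["level"].to_numpy()
        hot = latent >= 0.9
        cold = latent <= 0.1
        assert diff["value"][hot].mean() > 0
        assert diff["value"][hot].mean() > diff["value"][cold].mean()


class TestWindowCorrelation:
    def test_identical_channels_r_one(self, medip_sim):
        params, sim = medip_sim
        corr = medip.window_correlation(
            sim.reads["chanA"], sim.reads["chanA"], params.chrom_sizes
        )
        assert np.allclose(corr["pearson_r"], 1.0)

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(8)
        rows_a, rows_b = [], []
        for _ in range(20_000):
            s = int(rng.integers(0, 999_800))
            rows_a.append(("chr1", s, s + 200))
            s = int(rng.integers(0, 999_800))
            rows_b.append(("chr1", s, s + 200))
        corr = medip.window_correlation(
            reads(rows_a), reads(rows_b), {"chr1": 1_000_000}, windows=[2000]
        )
        assert abs(corr["pearson_r"].iloc[0]) < 0.1

    def test_shared_signal_r_increases_with_window(self, medip_sim):
        params, sim = medip_sim
        corr = medip.window_correlation(
            sim.reads["chanA"], sim.reads["chanB"], params.chrom_sizes
        )
        r = corr.sort_values("window_bp")["pearson_r"].to_numpy()
        assert (r > 0).all()
        assert r[0] < r[-1]

    def test_matches_brute_force_oracle(self, rng):
        # brute-force: recompute per-window RPKM by looping over reads
        rows = []
        for _ in range(300):
            s = int(rng.integers(0, 9_700))
            rows.append(("chr1", s, s + 200))
        a = reads(rows)
        b = reads(rows[::-1])
        for w in (1000, 2500):
            corr = medip.window_correlation(a, b, SIZES, windows=[w])
            n_win = -(-10_000 // w)

            def brute(df):
                counts = np.zeros(n_win)
                for _, r in df.iterrows():
                    counts[((r.start + r.end) // 2) // w] += 1
                lens = np.minimum((np.arange(n_win) + 1) * w, 10_000) - np.arange(n_win) * w
                return counts / (lens / 1000.0 * len(df) / 1e6)

            expected = np.corrcoef(brute(a), brute(b))[0, 1]
            assert corr["pearson_r"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestIslandEnrichment:
    def islands(self, levels):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(levels)) * 2000,
                "end": np.arange(len(levels)) * 2000 + 1000,
                "level": levels,
            }
        )

    def test_threshold_boundary(self):
        rng = np.random.default_rng(9)
        rows = [("chr1", int(s), int(s) + 200)
                for s in rng.integers(0, 9_800, size=50)]
        enr = medip.island_enrichment(
            {"ch": reads(rows)}, self.islands([0.80, 0.79])
        )
        assert list(enr.records["group"]) == ["heavy", "light"]

    def test_single_group_refused_with_flag(self):
        rows = [("chr1", 100, 300)]
        enr = medip.island_enrichment(
            {"ch": reads(rows)}, self.islands([0.9, 0.95])
        )
        assert enr.tests["ch"] is None
        assert "refused" in enr.note

    def test_empty_islands_rejected(self):
        with pytest.raises(ValueError):
            medip.island_enrichment({"ch": reads([])}, pd.DataFrame())

    def test_any_overlap_counts(self):
        # read straddling the island start must count (full-overlap rule)
        rows = [("chr1", 1900, 2100), ("chr1", 5000, 5200)]
        enr = medip.island_enrichment(
            {"ch": reads(rows)}, self.islands([0.9, 0.1, 0.1])
        )
        counts = enr.records["rpkm_ch"].to_numpy()
        assert counts[1] > 0  # island [2000,3000) caught the straddler


class TestHilbert:
    def test_order_one_visits_four_cells(self):
        df = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(4) * 1000,
             "end": (np.arange(4) + 1) * 1000, "value": [1.0, 2.0, 3.0, 4.0]}
        )
        img = medip.hilbert_render(df)
        assert img.order == 1
        assert img.assigned.all()
        assert sorted(img.matrix.ravel()) == [1.0, 2.0, 3.0, 4.0]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 6))
    def test_bijective_and_adjacent(self, order):
        n = 4**order
        seen = set()
        prev = None
        for d in range(n):
            x, y = medip.hilbert_d2xy(order, d)
            assert medip.hilbert_xy2d(order, x, y) == d
            seen.add((x, y))
            if prev is not None:
                assert abs(x - prev[0]) + abs(y - prev[1]) == 1
            prev = (x, y)
        assert len(seen) == n

    def test_constant_track_constant_image(self):
        df = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(10) * 1000,
             "end": (np.arange(10) + 1) * 1000, "value": 2.5}
        )
        img = medip.hilbert_render(df)
        assert np.all(img.matrix[img.assigned] == 2.5)
        assert np.all(np.isnan(img.matrix[~img.assigned]))

    def test_empty_track_rejected(self):
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        with pytest.raises(ValueError):
            medip.hilbert_render(df, chrom="chr1")


class TestTextIO:
    def test_bedgraph_chrom_sizes_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 1000], "end": [1000, 2000],
             "value": [1.5, -0.5]}
        )
        p = tmp_path / "x.bedGraph"
        medip.write_bedgraph(df, p)
        back = medip.read_bedgraph(p)
        pd.testing.assert_frame_equal(back, df)
        sizes_path = tmp_path / "c.sizes"
        sizes_path.write_text("chr1\t10000\nchr2\t5000\n")
        assert medip.read_chrom_sizes(sizes_path) == {"chr1": 10000, "chr2": 5000}
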