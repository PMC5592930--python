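import numpy as np
import pytest

from genomesurvey.depthmodel import (
    CalibrationError,
    DepthWindow,
    fit_gaussian,
    gc_correct,
    make_windows,
    read_depth_table,
    window_depth,
    write_depth_table,
)
from genomesurvey.seqio import GenomeSequence
from tests.conftest import make_depth_windows


class TestMakeWindows:
    def test_tiling_with_partial_tail(self):
        wins = make_windows([GenomeSequence("s", "A" * 1250)], width=500)
        assert [(w.start, w.end) for w in wins] == [(0, 500), (500, 1000), (1000, 1250)]
        assert [w.partial for w in wins] == [False, False, True]

    def test_all_gc_window(self):
        wins = make_windows([GenomeSequence("s", "GC" * 250)], width=500)
        assert wins[0].gc_fraction == 1.0

    def test_half_n_window_composition(self):
        seq = "N" * 250 + "G" * 125 + "A" * 125
        (w,) = make_windows([GenomeSequence("s", seq)], width=500)
        assert w.n_fraction == 0.5
        assert w.gc_fraction == 0.5
        # exclusion threshold is strictly above one half
        assert w.usable()
        w.n_fraction = 0.6
        assert not w.usable()

    def test_width_floor(self):
        with pytest.raises(ValueError):
            make_windows([GenomeSequence("s", "ACGT")], width=10)


class TestWindowDepth:
    def test_depth_table_roundtrip(self, tmp_path):
        wins = make_depth_windows([1.5, 2.5, 0.0])
        p = tmp_path / "d.tsv"
        write_depth_table(wins, p)
        wins2 = make_depth_windows([0, 0, 0])
        window_depth(wins2, p)
        assert [w.raw_depth for w in wins2] == [1.5, 2.5, 0.0]
        df = read_depth_table(p)
        assert list(df.columns) == ["scaffold", "start", "end", "depth"]

    def test_unknown_scaffold_in_table(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("#scaffold\tstart\tend\tdepth\nother\t0\t500\t3\n")
        with pytest.raises(ValueError, match="other"):
            window_depth(make_depth_windows([0.0]), p)

    def test_sam_read_fully_inside_window(self, tmp_path):
        # one 100 bp read inside a 500 bp window -> depth 0.2
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:s1\tLN:1000\n"
            "r1\t0\ts1\t101\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
        )
        import pysam

        bam = tmp_path / "a.bam"
        with pysam.AlignmentFile(str(sam)) as inf, pysam.AlignmentFile(
            str(bam), "wb", template=inf
        ) as outf:
            for r in inf:
                outf.write(r)
        wins = [
            DepthWindow("s1", 0, 500, 0.4, 0.0),
            DepthWindow("s1", 500, 1000, 0.4, 0.0),
        ]
        window_depth(wins, bam)
        assert wins[0].raw_depth == pytest.approx(0.2)
        assert wins[1].raw_depth == 0.0

    def test_sam_read_split_across_boundary(self, tmp_path):
        # read spanning the window boundary contributes only overlapping bp
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:s1\tLN:1000\n"
            "r1\t0\ts1\t451\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
        )
        import pysam

        bam = tmp_path / "a.bam"
        with pysam.AlignmentFile(str(sam)) as inf, pysam.AlignmentFile(
            str(bam), "wb", template=inf
        ) as outf:
            for r in inf:
                outf.write(r)
        wins = [
            DepthWindow("s1", 0, 500, 0.4, 0.0),
            DepthWindow("s1", 500, 1000, 0.4, 0.0),
        ]
        window_depth(wins, bam)
        assert wins[0].raw_depth == pytest.approx(50 / 500)
        assert wins[1].raw_depth == pytest.approx(50 / 500)

    def test_poisson_window_counts_concentrate(self, rng):
        # 2000 windows at 50 reads of 100 bp per 500 bp window -> depth ~10
        depths = rng.poisson(50, size=2000) * 100 / 500
        wins = make_depth_windows(depths)
        mean = np.mean([w.raw_depth for w in wins])
        assert abs(mean - 10.0) / 10.0 < 0.02


class TestGcCorrect:
    def test_identity_under_uniform_depth(self):
        wins = make_depth_windows([100.0] * 200)
        gc_correct(wins)
        assert all(w.corrected_depth == pytest.approx(100.0) for w in wins)

    def test_two_bin_arithmetic(self):
        wins_a = make_depth_windows([80.0] * 100, gc=0.305)
        wins_b = make_depth_windows([120.0] * 100, gc=0.705)
        wins = wins_a + wins_b
        gc_correct(wins, min_bin_windows=10)
        assert wins_a[0].corrected_depth == pytest.approx(100.0)
        assert wins_b[0].corrected_depth == pytest.approx(100.0)

    def test_linear_bias_removed(self, rng):
        wins = []
        for i in range(10_000):
            gc = float(rng.uniform(0.25, 0.65))
            d = rng.poisson(100 * 500 * (0.5 + gc)) / 500
            wins.append(
                DepthWindow("s", i * 500, (i + 1) * 500, gc, 0.0, raw_depth=float(d))
            )
        gc_correct(wins)
        corr = np.array([w.corrected_depth for w in wins])
        gcs = np.array([w.gc_fraction for w in wins])
        gm = corr.mean()
        for b in np.arange(0.25, 0.65, 0.01):
            sel = (gcs >= b) & (gcs < b + 0.01)
            if sel.sum() >= 50:
                assert abs(corr[sel].mean() - gm) / gm < 0.03

    def test_mean_preserved_within_one_percent(self, rng):
        wins = []
        for i in range(2000):
            gc = float(rng.uniform(0.3, 0.6))
            d = rng.poisson(80 * 500 * (0.6 + 0.8 * gc)) / 500
            wins.append(
                DepthWindow("s", i * 500, (i + 1) * 500, gc, 0.0, raw_depth=float(d))
            )
        gc_correct(wins)
        raw = np.mean([w.raw_depth for w in wins])
        corr = np.mean([w.corrected_depth for w in wins])
        assert abs(corr - raw) / raw < 0.01

    def test_flagged_windows_excluded_from_bins(self):
        good = make_depth_windows([100.0] * 100)
        gappy = [
            DepthWindow("s", 10**6 + i * 500, 10**6 + (i + 1) * 500, 0.4, 0.9, raw_depth=0.0)
            for i in range(50)
        ]
        calib = gc_correct(good + gappy, min_bin_windows=10)
        # bin means computed from usable windows only -> no zero-dragged bin
        assert all(m == pytest.approx(100.0) for m in calib.gc_bin_means.values())

    def test_all_windows_flagged_is_error(self):
        wins = [DepthWindow("s", 0, 500, 0.4, 1.0, raw_depth=0.0)]
        with pytest.raises(CalibrationError):
            gc_correct(wins)


class TestFitGaussian:
    def test_normal_recovery(self, rng):
        d = rng.normal(100, 10, 10_000)
        calib = fit_gaussian(d)
        assert 99 <= calib.mean <= 101
        assert 9 <= calib.sd <= 11
        assert calib.dup_cutoff == pytest.approx(calib.mean + 3 * calib.sd)
        assert calib.del_cutoff == pytest.approx(calib.mean - 2 * calib.sd)

    def test_degenerate_constant_depths(self, caplog):
        with caplog.at_level("WARNING", logger="genomesurvey.depthmodel"):
            calib = fit_gaussian(np.full(100, 42.0))
        assert (calib.mean, calib.sd) == (42.0, 0.0)
        assert any("degenerate" in m or "sd = 0" in m for m in caplog.messages)

    def test_contaminating_cnv_mode_ignored(self, rng):
        d = np.concatenate([rng.normal(100, 10, 9500), rng.normal(300, 10, 500)])
        calib = fit_gaussian(d)
        assert 99 <= calib.mean <= 102

    def test_scale_equivariance(self, rng):
        d = rng.normal(100, 10, 5000)
        c1 = fit_gaussian(d)
        c2 = fit_gaussian(3.0 * d)
        assert c2.mean == pytest.approx(3 * c1.mean, rel=0.02)
        assert c2.sd == pytest.approx(3 * c1.sd, rel=0.05)

    def test_too_few_windows(self):
        with pytest.raises(CalibrationError):
            fit_gaussian(np.arange(5, dtype=float))
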