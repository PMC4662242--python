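"""Coverage evidence chain: fragments, window medians, GC normalisation,
robust normal fit, classification, multimapper windows."""

import numpy as np
import pytest

from asmqc.coverage_gc import (RobustNormal, WindowCoverage, classify_coverage,
                               extract_fragments, fit_gc_model,
                               fit_robust_normal, gc_percent, lc_attribution,
                               multimap_windows, window_median_coverage)
from asmqc.intervals import GenomeLayout, IntervalSet, make_windows
from conftest import make_sam


def _pair(qname, chrom, p1, p2, mapq=60, proper=True, length=50):
    tlen = p2 + length - p1
    return [
        dict(qname=qname, chrom=chrom, pos=p1, mapq=mapq, proper=proper,
             tlen=tlen, length=length, read1=True, mate_pos=p2),
        dict(qname=qname, chrom=chrom, pos=p2, mapq=mapq, proper=proper,
             tlen=-tlen, length=length, read1=False, reverse=True, mate_pos=p1),
    ]


class TestExtractFragments:
    def test_span_and_filters(self, tmp_path):
        reads = (_pair("a", "chr1", 100, 300)          # kept: [100, 350)
                 + _pair("b", "chr1", 500, 700, mapq=0)   # mapq < 2: dropped
                 + _pair("c", "chr1", 900, 1100, proper=False))  # improper
        sam = make_sam(tmp_path / "r.sam", {"chr1": 2000}, reads)
        frags = extract_fragments(sam, min_mapq=2)
        assert [tuple(x) for x in frags.by_chrom("chr1")] == [(100, 350)]
        # improper pairs kept when the filter is relaxed
        assert extract_fragments(sam, min_mapq=2, require_proper=False).n_features == 2

    def test_one_low_mapq_mate_drops_pair(self, tmp_path):
        reads = _pair("a", "chr1", 100, 300)
        reads[1]["mapq"] = 0
        sam = make_sam(tmp_path / "r.sam", {"chr1": 2000}, reads)
        assert extract_fragments(sam).n_features == 0

    def test_unsorted_rejected(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:2000\n"
            "b\t99\tchr1\t501\t60\t50M\t=\t700\t249\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
            "a\t99\tchr1\t101\t60\t50M\t=\t300\t249\t" + "A" * 50 + "\t" + "I" * 50 + "\n")
        with pytest.raises(ValueError, match="sorted"):
            extract_fragments(sam)

    def test_matches_enumeration_oracle(self, tmp_path):
        rng = np.random.default_rng(17)
        reads, expected = [], []
        for i in range(50):
            p1 = int(rng.integers(0, 4000))
            gap = int(rng.integers(0, 400))
            p2 = p1 + 50 + gap
            reads += _pair(f"q{i}", "chr1", p1, p2)
            expected.append((p1, p2 + 50))
        sam = make_sam(tmp_path / "r.sam", {"chr1": 5000}, reads)
        got = [tuple(x) for x in extract_fragments(sam).by_chrom("chr1")]
        assert sorted(got) == sorted(expected)


class TestWindowMedian:
    def test_examples(self):
        depth = {"chr1": np.array([1, 2, 3, 4, 0, 0, 0, 0])}
        wins = IntervalSet({"chr1": [(0, 4), (4, 8)]})
        out = window_median_coverage(depth, wins)
        assert [w.median_cov for w in out] == [2.5, 0.0]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(9)
        depth = {"chr1": rng.integers(0, 60, 20_000)}
        wins = make_windows(GenomeLayout({"chr1": 20_000}), 1000, 1000)
        out = window_median_coverage(depth, wins)
        for w in out:
            vals = sorted(depth["chr1"][w.start:w.end])
            n = len(vals)
            oracle = (vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2)
            assert w.median_cov == oracle


class TestGcPercent:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", 50), ("AAAA", 0), ("GCGC", 100),
        ("ACGN", 67),  # 2 GC of 3 unambiguous; N excluded from the denominator
        ("ATGN", 33),  # 1 GC of 3 unambiguous
        ("acgt", 50), ("NNNN", None),
    ])
    def test_examples(self, seq, expected):
        assert gc_percent(seq) == expected


class TestGcModel:
    def test_single_bin_identity(self):
        wins = [WindowCoverage("chr1", i * 1000, (i + 1) * 1000, m, gc_pct=40)
                for i, m in enumerate([10, 20, 30] * 20)]
        model = fit_gc_model(wins, min_bin_windows=50)
        assert model.global_median == 20
        assert model.f(40) == 1.0
        assert all(w.norm_cov == w.median_cov for w in wins)

    def test_factor_is_median_ratio(self):
        # one bin at half the global median gets factor 2
        wins = ([WindowCoverage("chr1", i, i + 1, 41.0, gc_pct=40) for i in range(60)]
                + [WindowCoverage("chr1", i, i + 1, 20.5, gc_pct=70) for i in range(60)])
        model = fit_gc_model(wins, min_bin_windows=50)
        assert model.global_median == pytest.approx(30.75)
        assert model.factor[70] == pytest.approx(30.75 / 20.5)

    def test_small_bins_uncorrected(self):
        wins = ([WindowCoverage("chr1", i, i + 1, 40.0, gc_pct=40) for i in range(100)]
                + [WindowCoverage("chr1", i, i + 1, 5.0, gc_pct=90) for i in range(3)])
        model = fit_gc_model(wins, min_bin_windows=50)
        assert model.f(90) == 1.0

    def test_normalization_fixed_point(self):
        # GC-biased coverage: per-bin medians equalise to the global median
        rng = np.random.default_rng(23)
        wins = []
        for gc, scale in ((25, 0.5), (45, 1.0), (65, 0.7)):
            wins += [WindowCoverage("chr1", i, i + 1,
                                    float(rng.poisson(40 * scale)), gc_pct=gc)
                     for i in range(200)]
        model = fit_gc_model(wins, min_bin_windows=50)
        for gc in (25, 45, 65):
            norm = [w.norm_cov for w in wins if w.gc_pct == gc]
            assert np.median(norm) == pytest.approx(model.global_median, rel=1e-12)

    def test_degenerate_library_rejected(self):
        wins = [WindowCoverage("chr1", i, i + 1, 0.0, gc_pct=40) for i in range(10)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_gc_model(wins)


class TestRobustNormal:
    def test_cutoffs_from_moments(self):
        m = RobustNormal(41.0, 7.0, k=2.0)
        assert m.low_cut == 27.0 and m.high_cut == 55.0

    def test_clean_recovery(self):
        rng = np.random.default_rng(42)
        fit = fit_robust_normal(rng.normal(41, 7, 100_000))
        assert fit.mean == pytest.approx(41, abs=0.2)
        assert fit.sd == pytest.approx(7, abs=0.2)

    def test_contamination_robustness(self):
        rng = np.random.default_rng(42)
        vals = np.concatenate([rng.normal(41, 7, 98_000),
                               rng.uniform(200, 400, 2_000)])
        fit = fit_robust_normal(vals)
        assert fit.mean == pytest.approx(41, abs=0.5)
        assert fit.sd == pytest.approx(7, abs=0.5)
        assert np.std(vals) > 7 * 1.5  # the plain moment is badly inflated

    @pytest.mark.parametrize("mu", [20.0, 41.0, 80.0])
    @pytest.mark.parametrize("sigma", [3.0, 7.0, 15.0])
    def test_parameter_recovery_grid(self, mu, sigma):
        rng = np.random.default_rng(int(mu * 100 + sigma))
        vals = np.concatenate([rng.normal(mu, sigma, 95_000),
                               rng.uniform(mu + 10 * sigma, mu + 30 * sigma, 5_000)])
        fit = fit_robust_normal(vals)
        assert fit.mean == pytest.approx(mu, rel=0.05)
        assert fit.sd == pytest.approx(sigma, rel=0.05)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fit_robust_normal(np.ones(10))


class TestClassify:
    @pytest.mark.parametrize("value,label", [
        (56, "HIGH"), (55, "NORMAL"), (41, "NORMAL"),
        (27, "NORMAL"), (26, "LOW"),
    ])
    def test_strict_boundaries(self, value, label):
        assert classify_coverage(value, RobustNormal(41, 7, 2)) == label

    def test_partition(self):
        rng = np.random.default_rng(1)
        model = RobustNormal(41, 7, 2)
        labels = [classify_coverage(v, model) for v in rng.uniform(0, 100, 500)]
        assert len(labels) == 500
        assert set(labels) <= {"LOW", "NORMAL", "HIGH"}


class TestMultimap:
    def test_flagging_and_empty_window_rule(self, tmp_path):
        reads = []
        # window [0,1000): 10 reads, 6 multimapped -> 60% -> flagged
        for i in range(10):
            reads.append(dict(qname=f"a{i}", chrom="chr1", pos=100 + i * 10,
                              mapq=0 if i < 6 else 60))
        # window [1000,2000): 10 reads, 3 multimapped -> 30% -> kept
        for i in range(10):
            reads.append(dict(qname=f"b{i}", chrom="chr1", pos=1100 + i * 10,
                              mapq=0 if i < 3 else 60))
        # window [2000,3000): empty -> 0% -> kept
        sam = make_sam(tmp_path / "r.sam", {"chr1": 3000}, reads)
        wins = make_windows(GenomeLayout({"chr1": 3000}), 1000, 1000)
        res = multimap_windows(sam, wins)
        assert res.pct.tolist() == [60.0, 30.0, 0.0]
        assert [tuple(x) for x in res.flagged.by_chrom("chr1")] == [(0, 1000)]

    def test_attribution_containment_and_disjoint(self, tmp_path):
        sam = make_sam(tmp_path / "r.sam", {"chr1": 3000},
                       [dict(qname="a", chrom="chr1", pos=10, mapq=0)])
        wins = make_windows(GenomeLayout({"chr1": 3000}), 1000, 1000)
        res = multimap_windows(sam, wins)
        mm = IntervalSet({"chr1": [(0, 1000)]})
        lc = IntervalSet({"chr1": [(0, 2000)]})
        att = lc_attribution(lc, mm, res)
        assert att.pct_mm_in_lc == 100.0
        disjoint = IntervalSet({"chr1": [(2000, 3000)]})
        att2 = lc_attribution(disjoint, mm, res)
        assert att2.pct_mm_in_lc == 0.0 and att2.pct_lc_in_mm == 0.0
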