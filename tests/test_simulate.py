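"""Simulator: determinism, planted-signature correctness, mass conservation."""

import numpy as np
import pytest

from asmqc import simulate
from asmqc.intervals import IntervalSet
from asmqc.simulate import (Fragments, MisassemblySpec, SimConfig,
                            corrupt_assembly, default_scenario, evaluate,
                            make_sample_genome, project_alignments,
                            simulate_pairs)


def small_config(**kw):
    defaults = dict(seed=1, chrom_lengths={"chr1": 60_000}, depth=40.0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSampleGenome:
    def test_deterministic_under_seed(self):
        g1, _ = make_sample_genome(small_config())
        g2, _ = make_sample_genome(small_config())
        assert (g1["chr1"] == g2["chr1"]).all()
        g3, _ = make_sample_genome(small_config(seed=2))
        assert not (g1["chr1"] == g3["chr1"]).all()

    def test_gc_profile_realized(self):
        cfg = small_config(gc_profile=[("chr1", 10_000, 20_000, 0.60)])
        g, _ = make_sample_genome(cfg)
        region = g["chr1"][10_000:20_000]
        gc = ((region == ord("G")) | (region == ord("C"))).mean()
        assert gc == pytest.approx(0.60, abs=0.03)

    def test_zero_length_chrom_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_lengths={"chr1": 0})


class TestCorruptAssembly:
    def test_no_specs_is_identity(self):
        g, _ = make_sample_genome(small_config())
        c = corrupt_assembly(g, [], seed=1)
        assert (c.assembly["chr1"] == g["chr1"]).all()
        assert all(t.n_features == 0 for t in c.truth.values())

    def test_collapse_shortens_and_diverges(self):
        g, _ = make_sample_genome(small_config())
        spec = MisassemblySpec("collapsed_duplication", "chr1", 10_000, 5_000,
                               divergence=0.01)
        c = corrupt_assembly(g, [spec], seed=1)
        assert len(c.assembly["chr1"]) == 60_000 - 5_000
        # the sample now carries two ~1%-diverged copies
        a = c.sample["chr1"][10_000:15_000]
        b = c.sample["chr1"][15_000:20_000]
        n_div = int((a != b).sum())
        assert 25 <= n_div <= 80  # Binomial(5000, 0.01)
        assert [tuple(x) for x in
                c.truth["collapsed_duplication"].by_chrom("chr1")] == [(10_000, 15_000)]

    def test_inversion_preserves_length(self):
        g, _ = make_sample_genome(small_config())
        c = corrupt_assembly(g, [MisassemblySpec("inversion", "chr1", 10_000, 4_000)],
                             seed=1)
        assert len(c.assembly["chr1"]) == 60_000
        t = c.truth["inversion"].by_chrom("chr1")
        assert (t[0, 1] - t[0, 0]) == 4_000

    def test_false_tandem_lengthens(self):
        g, _ = make_sample_genome(small_config())
        c = corrupt_assembly(
            g, [MisassemblySpec("false_tandem_duplication", "chr1", 10_000, 3_000)],
            seed=1)
        assert len(c.assembly["chr1"]) == 63_000
        assert (c.assembly["chr1"][10_000:13_000]
                == c.assembly["chr1"][13_000:16_000]).all()

    def test_overlapping_specs_rejected(self):
        g, _ = make_sample_genome(small_config())
        specs = [MisassemblySpec("inversion", "chr1", 10_000, 4_000),
                 MisassemblySpec("inversion", "chr1", 12_000, 4_000)]
        with pytest.raises(ValueError, match="overlap"):
            corrupt_assembly(g, specs, seed=1)


class TestSimulatePairs:
    def test_depth_and_determinism(self):
        cfg = small_config(chrom_lengths={"chr1": 100_000})
        g, _ = make_sample_genome(cfg)
        f1 = simulate_pairs(g, cfg)
        f2 = simulate_pairs(g, cfg)
        assert (f1.starts["chr1"] == f2.starts["chr1"]).all()
        total = int(f1.lengths["chr1"].sum())
        assert total / 100_000 == pytest.approx(40, abs=2)

    def test_gc_response_thins_coverage(self):
        cfg = small_config(chrom_lengths={"chr1": 100_000},
                           gc_profile=[("chr1", 0, 50_000, 0.25)],
                           gc_response=[(0.25, 0.5), (0.45, 1.0)])
        g, _ = make_sample_genome(cfg)
        f = simulate_pairs(g, cfg)
        mids = f.starts["chr1"] + f.lengths["chr1"] // 2
        low_gc = (mids < 50_000).sum()
        normal = (mids >= 50_000).sum()
        assert low_gc / normal == pytest.approx(0.5, abs=0.08)


class TestProjection:
    def _project(self, tmp_path, specs, cfg=None):
        cfg = cfg or small_config()
        g, _ = make_sample_genome(cfg)
        c = corrupt_assembly(g, specs, seed=cfg.seed)
        frags = simulate_pairs(c.sample, cfg)
        sam = tmp_path / "r.sam"
        counts = project_alignments(frags, c, cfg, sam)
        return c, frags, sam, counts

    def test_uncorrupted_all_proper_and_error_free(self, tmp_path):
        import pysam
        cfg = small_config(error_rate=0.0)
        c, frags, sam, counts = self._project(tmp_path, [], cfg)
        ref = c.assembly["chr1"]
        n = 0
        with pysam.AlignmentFile(str(sam)) as af:
            for rec in af:
                n += 1
                assert rec.is_proper_pair and rec.mapping_quality == 60
                seq = np.frombuffer(rec.query_sequence.encode(), np.uint8)
                assert (seq == ref[rec.reference_start:rec.reference_end]).all()
        assert n == 2 * counts.n_projected
        assert counts.n_dropped_pairs == 0

    def test_mass_conservation(self, tmp_path):
        specs = [MisassemblySpec("assembly_insertion", "chr1", 30_000, 300)]
        _, frags, _, counts = self._project(tmp_path, specs)
        assert counts.n_pairs == frags.n_pairs
        assert counts.n_projected + counts.n_dropped_pairs == counts.n_pairs
        assert counts.n_dropped_pairs > 0  # reads inside the lost sequence

    def test_collapse_doubles_depth(self, tmp_path):
        from asmqc.coverage_gc import extract_fragments
        from asmqc.intervals import fragment_depth
        specs = [MisassemblySpec("collapsed_duplication", "chr1", 20_000, 5_000,
                                 divergence=0.01)]
        c, _, sam, _ = self._project(tmp_path, specs)
        frags = extract_fragments(sam)
        depth = fragment_depth(frags, c.assembly_layout)["chr1"]
        inside = depth[21_000:24_000].mean()
        outside = np.concatenate([depth[5_000:15_000], depth[30_000:50_000]]).mean()
        assert inside / outside == pytest.approx(2.0, abs=0.25)

    def test_deletion_shifts_template_length(self, tmp_path):
        import pysam
        specs = [MisassemblySpec("assembly_deletion", "chr1", 30_000, 300)]
        c, _, sam, _ = self._project(tmp_path, specs)
        # pairs spanning the inserted assembly segment: tlen ~ insert + 300
        t = c.truth["assembly_deletion"].by_chrom("chr1")[0]
        spanning = []
        with pysam.AlignmentFile(str(sam)) as af:
            for rec in af:
                if (rec.template_length > 0 and rec.reference_end <= t[0]
                        and rec.reference_start + rec.template_length >= t[1]):
                    spanning.append(rec.template_length)
        assert len(spanning) > 10
        assert np.mean(spanning) == pytest.approx(427 + 300, abs=60)
        assert np.mean(spanning) > 588  # beyond the large-insert cutoff

    def test_multimap_reads_split_between_copies(self, tmp_path):
        import pysam
        specs = [MisassemblySpec("false_tandem_duplication", "chr1", 20_000, 3_000)]
        c, _, sam, counts = self._project(tmp_path, specs)
        assert counts.n_multimap_reads > 0
        copy1 = copy2 = 0
        with pysam.AlignmentFile(str(sam)) as af:
            for rec in af:
                if rec.mapping_quality == 0:
                    if rec.reference_start < 23_000:
                        copy1 += 1
                    else:
                        copy2 += 1
        assert copy1 > 0 and copy2 > 0
        assert copy1 / (copy1 + copy2) == pytest.approx(0.5, abs=0.1)

    def test_projection_deterministic(self, tmp_path):
        specs = [MisassemblySpec("inversion", "chr1", 20_000, 2_000)]
        cfg = small_config()
        g, _ = make_sample_genome(cfg)
        c = corrupt_assembly(g, specs, seed=cfg.seed)
        frags = simulate_pairs(c.sample, cfg)
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        project_alignments(frags, c, cfg, p1)
        project_alignments(frags, c, cfg, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestEvaluate:
    def test_perfect_and_empty(self):
        truth = {"inversion": IntervalSet({"chr1": [(100, 200)]})}
        flagged = {"IMPROPER_PAIR": IntervalSet({"chr1": [(100, 200)]})}
        df = evaluate(flagged, truth)
        row = df.iloc[0]
        assert row.precision == 1.0 and row.recall == 1.0
        df2 = evaluate({"IMPROPER_PAIR": IntervalSet({})}, truth)
        assert df2.iloc[0].recall == 0.0 and df2.iloc[0].precision == 1.0
        assert df2.iloc[0].flagged_bases == 0


class TestEndToEndSignatures:
    """Signature correctness on the shared default-scenario run."""

    def test_expected_track_recall(self, default_run):
        recalls = simulate.evaluate_expected(default_run["tracks"],
                                             default_run["truth"])
        assert set(recalls) == set(simulate.EXPECTED_EVIDENCE)
        for kind, r in recalls.items():
            assert r >= 0.8, f"{kind} recall {r:.2f}"

    def test_collapse_divergent_sites_become_variant_calls(self, default_run):
        # paralog sequence variants inside the collapse are called as
        # variants (mixed ~50/50, so het rather than hom) by a permissive
        # re-run of the counting caller
        from asmqc.homozygosity import call_homozygous_sites
        sites = call_homozygous_sites(default_run["cfg"].alignments,
                                      default_run["cfg"].assembly,
                                      min_alt_fraction=0.3)
        t = default_run["truth"]["collapsed_duplication"].by_chrom("chr1")[0]
        inside = [s for s in sites if t[0] <= s.pos < t[1]]
        assert len(inside) > 30  # ~100 divergent sites planted at 2%
        mixed = [s for s in inside if s.alt_fraction < 0.9]
        assert len(mixed) > len(inside) // 2
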