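"""Shared fixtures: synthetic scenario runs and small SAM/FASTA builders."""

from __future__ import annotations

import glob
import os
from pathlib import Path

import numpy as np
import pysam
import pytest

from asmqc import pipeline, read_bed, simulate
from asmqc.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> dict:
    """Default corrupted scenario (500 kb, one event of each kind, seed 42)
    simulated and pushed through the full pipeline once per session."""
    root = tmp_path_factory.mktemp("default_scenario")
    sim_cfg, specs = simulate.default_scenario()
    paths = pipeline.run_simulate(sim_cfg, specs, root / "sim")
    cfg = PipelineConfig(alignments=str(paths["reads"]),
                         assembly=str(paths["assembly"]),
                         gaps=str(paths["gaps"]),
                         outdir=str(root / "out"))
    reports = pipeline.run_all(cfg)
    tracks = pipeline.run_merge(cfg)
    truth = {}
    for p in glob.glob(str(root / "sim" / "truth_*.bed")):
        kind = os.path.basename(p)[6:-4]
        if os.path.getsize(p):
            truth[kind] = read_bed(p)
    return {"sim_cfg": sim_cfg, "specs": specs, "paths": paths, "cfg": cfg,
            "reports": reports, "tracks": tracks, "truth": truth,
            "root": root}


@pytest.fixture(scope="session")
def control_run(tmp_path_factory) -> dict:
    """Same library and genome as the default scenario but with no planted
    misassemblies: the null model for false-positive rates."""
    root = tmp_path_factory.mktemp("control_scenario")
    sim_cfg, _ = simulate.default_scenario()
    paths = pipeline.run_simulate(sim_cfg, [], root / "sim")
    cfg = PipelineConfig(alignments=str(paths["reads"]),
                         assembly=str(paths["assembly"]),
                         gaps=str(paths["gaps"]),
                         outdir=str(root / "out"))
    reports = pipeline.run_all(cfg)
    tracks = pipeline.run_merge(cfg)
    return {"sim_cfg": sim_cfg, "paths": paths, "cfg": cfg,
            "reports": reports, "tracks": tracks, "root": root}


def make_sam(path: Path, chrom_lengths: dict[str, int],
             reads: list[dict]) -> Path:
    """Write a coordinate-sorted SAM from simple read dicts.

    Each dict: qname, chrom, pos, plus optional mapq (60), tlen (0),
    proper (True), paired (True), reverse (False), read1 (True), seq, length
    (100).
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()]}
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    recs = []
    for r in reads:
        a = pysam.AlignedSegment()
        length = r.get("length", 100)
        a.query_name = r["qname"]
        a.reference_id = tid[r["chrom"]]
        a.reference_start = r["pos"]
        a.mapping_quality = r.get("mapq", 60)
        a.cigartuples = [(0, length)]
        a.query_sequence = r.get("seq", "A" * length)
        a.query_qualities = pysam.qualitystring_to_array("I" * length)
        a.template_length = r.get("tlen", 0)
        a.is_paired = r.get("paired", True)
        a.is_proper_pair = r.get("proper", True)
        a.is_reverse = r.get("reverse", False)
        a.is_read1 = r.get("read1", True)
        a.is_read2 = not r.get("read1", True)
        if "mate_pos" in r:
            a.next_reference_id = tid[r["chrom"]]
            a.next_reference_start = r["mate_pos"]
        recs.append((a.reference_id, a.reference_start, a))
    recs.sort(key=lambda x: (x[0], x[1]))
    with pysam.AlignmentFile(str(path), "wh", header=header) as af:
        for _, _, a in recs:
            af.write(a)
    return path


def make_fasta(path: Path, seqs: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return path


def mask_cover(intervals, size: int) -> np.ndarray:
    """Per-base boolean-mask oracle for interval coverage on one chromosome."""
    mask = np.zeros(size, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask
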