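"""Pipeline orchestration: each stage is a pure function of (inputs, config).

The stages mirror the evidence chain — coverage, multimappers, insert sizes,
proper pairing, homozygous variants, merging, reporting — and persist their
per-window tables and region BEDs under ``outdir`` so later stages (and
threshold refits with a different ``k``) never re-read the alignments.
Re-running a stage with the same inputs and config produces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage_gc, homozygosity, pair_metrics, regions, simulate
from ._samio import load_read_table
from .intervals import (GenomeLayout, IntervalSet, make_windows, merge_intervals,
                        read_bed, remove_gap_windows, fragment_depth, write_bed)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_coverage", "run_multimap",
           "run_inserts", "run_pairing", "run_variants", "run_merge",
           "run_report", "run_all"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full QC run.

    Parameter defaults are the method's reference operating point: 1 kb
    windows (non-overlapping for coverage, step 800 for pair metrics), mapq
    floor 2, k = 2 SD cutoffs everywhere, >50 % multimapper windows,
    +/-100 bp homozygous-variant flanks.
    """

    alignments: str = ""
    assembly: str = ""
    outdir: str = "asmqc_out"
    gaps: str | None = None
    vcf: str | None = None
    # annotation name -> (path, mode); mode is feature_count or base_count
    annotations: dict[str, tuple[str, str]] = field(default_factory=dict)

    window_width: int = 1000
    cov_step: int = 1000
    pair_step: int = 800
    min_mapq: int = 2
    k: float = 2.0
    multimap_pct: float = 50.0
    flank: int = 100
    min_bin_windows: int = 50
    min_depth: int = 8
    min_alt_fraction: float = 0.9
    min_baseq: int = 13
    excluded_chroms: tuple[str, ...] = ()
    seed: int = 42

    def validate(self) -> None:
        if self.window_width <= 0 or not (0 < self.cov_step <= self.window_width):
            raise ValueError("invalid coverage windowing parameters")
        if not (0 < self.pair_step <= self.window_width):
            raise ValueError("invalid pair-metric windowing parameters")
        if self.k <= 0 or self.flank < 0 or self.min_mapq < 0:
            raise ValueError("parameter out of range")
        if not (0 <= self.multimap_pct <= 100):
            raise ValueError("multimap_pct must lie in [0, 100]")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["excluded_chroms"] = list(self.excluded_chroms)
        d["annotations"] = {k: list(v) for k, v in self.annotations.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["excluded_chroms"] = tuple(d.get("excluded_chroms", ()))
        d["annotations"] = {k: tuple(v) for k, v in d.get("annotations", {}).items()}
        return cls(**d)


def _require(path: str | Path | None, what: str) -> Path:
    if not path or not Path(path).exists():
        raise FileNotFoundError(f"missing required input for this stage: {what} "
                                f"({path!r})")
    return Path(path)


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _layout(cfg: PipelineConfig) -> GenomeLayout:
    _require(cfg.assembly, "assembly FASTA")
    return GenomeLayout.from_fasta(cfg.assembly).drop(cfg.excluded_chroms)


def _gaps(cfg: PipelineConfig) -> IntervalSet:
    if cfg.gaps and Path(cfg.gaps).exists():
        return read_bed(cfg.gaps)
    return IntervalSet({})


def run_simulate(sim_config: simulate.SimConfig,
                 specs: list[simulate.MisassemblySpec],
                 outdir: str | Path) -> dict[str, Path]:
    """Generate a synthetic scenario: sample + corrupted assembly, projected
    read alignments, truth BEDs and an (empty) gap track."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sample, _ = simulate.make_sample_genome(sim_config)
    corruption = simulate.corrupt_assembly(sample, specs, seed=sim_config.seed)
    frags = simulate.simulate_pairs(corruption.sample, sim_config)
    counts = simulate.project_alignments(frags, corruption, sim_config,
                                         out / "reads.sam")
    simulate.write_fasta(corruption.sample, out / "sample.fa")
    simulate.write_fasta(corruption.assembly, out / "assembly.fa")
    (out / "gaps.bed").write_text("")
    paths = {"sample": out / "sample.fa", "assembly": out / "assembly.fa",
             "reads": out / "reads.sam", "gaps": out / "gaps.bed"}
    for kind, t in corruption.truth.items():
        p = out / f"truth_{kind}.bed"
        write_bed(t, p)
        paths[f"truth_{kind}"] = p
    cfg_dict = dataclasses.asdict(sim_config)
    cfg_dict["planted"] = [dataclasses.asdict(s) for s in specs]
    cfg_dict["projection_counts"] = dataclasses.asdict(counts)
    (out / "sim_config.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    return paths


def run_coverage(cfg: PipelineConfig) -> dict[str, object]:
    """Fragment-coverage stage: GC-normalised window medians, robust normal
    fit, HIGH/LOW window flagging."""
    cfg.validate()
    _require(cfg.alignments, "alignments SAM/BAM")
    out = _outdir(cfg)
    layout = _layout(cfg)
    windows = remove_gap_windows(
        make_windows(layout, cfg.window_width, cfg.cov_step), _gaps(cfg))
    frags = coverage_gc.extract_fragments(cfg.alignments, cfg.min_mapq)
    frags = IntervalSet({c: frags.by_chrom(c) for c in frags.chroms
                         if c in layout}, chrom_order=[c for c in frags.chroms
                                                       if c in layout])
    depth = fragment_depth(frags, layout)
    wins = coverage_gc.window_median_coverage(depth, windows)
    coverage_gc.annotate_gc(wins, cfg.assembly)
    model = coverage_gc.fit_gc_model(wins, cfg.min_bin_windows)
    robust = coverage_gc.fit_robust_normal([w.norm_cov for w in wins], k=cfg.k)
    labels = [coverage_gc.classify_coverage(w.norm_cov, robust) for w in wins]
    table = pd.DataFrame({
        "chrom": [w.chrom for w in wins], "start": [w.start for w in wins],
        "end": [w.end for w in wins],
        "median_cov": [w.median_cov for w in wins],
        "gc_pct": [w.gc_pct for w in wins],
        "norm_cov": [w.norm_cov for w in wins], "label": labels,
    })
    table.to_csv(out / "coverage_windows.tsv", sep="\t", index=False)
    for label, name in (("HIGH", "high_cov.bed"), ("LOW", "low_cov.bed")):
        flagged = merge_intervals(IntervalSet.from_records(
            [(w.chrom, w.start, w.end) for w, l in zip(wins, labels) if l == label]))
        write_bed(flagged, out / name)
    (out / "coverage_model.yaml").write_text(yaml.safe_dump({
        "global_median": model.global_median,
        "robust_mean": robust.mean, "robust_sd": robust.sd, "k": robust.k,
        "low_cut": robust.low_cut, "high_cut": robust.high_cut,
    }, sort_keys=True))
    return {"windows": wins, "model": model, "robust": robust}


def run_multimap(cfg: PipelineConfig) -> coverage_gc.MultimapResult:
    """Flag windows dominated (>50 %) by multimapped reads."""
    cfg.validate()
    _require(cfg.alignments, "alignments SAM/BAM")
    out = _outdir(cfg)
    layout = _layout(cfg)
    windows = remove_gap_windows(
        make_windows(layout, cfg.window_width, cfg.cov_step), _gaps(cfg))
    res = coverage_gc.multimap_windows(cfg.alignments, windows, cfg.multimap_pct)
    write_bed(res.flagged, out / "multimap.bed")
    rows = [(iv.chrom, iv.start, iv.end) for iv in windows]
    pd.DataFrame({
        "chrom": [r[0] for r in rows], "start": [r[1] for r in rows],
        "end": [r[2] for r in rows], "raw_reads": res.raw_counts,
        "mm_reads": res.mm_counts, "pct_mm": res.pct,
    }).to_csv(out / "multimap_windows.tsv", sep="\t", index=False)
    return res


def _pair_windows(cfg: PipelineConfig) -> IntervalSet:
    return remove_gap_windows(
        make_windows(_layout(cfg), cfg.window_width, cfg.pair_step), _gaps(cfg))


def _write_fractions(fracs, path: Path) -> None:
    pd.DataFrame({
        "chrom": [f.chrom for f in fracs], "start": [f.start for f in fracs],
        "end": [f.end for f in fracs],
        "subset_count": [f.subset_count for f in fracs],
        "total_count": [f.total_count for f in fracs],
        "pct": [f.pct for f in fracs],
    }).to_csv(path, sep="\t", index=False)


def run_inserts(cfg: PipelineConfig) -> dict[str, object]:
    """Insert-size stage: fit the template-length model, compute per-window
    small/large-insert percentages and flag beyond 2 SD."""
    cfg.validate()
    _require(cfg.alignments, "alignments SAM/BAM")
    out = _outdir(cfg)
    table = load_read_table(cfg.alignments)
    model = pair_metrics.fit_insert_model(table, k=cfg.k)
    windows = _pair_windows(cfg)
    small, large = pair_metrics.abnormal_insert_fractions(table, model, windows)
    results = {}
    for name, fracs in (("small_insert", small), ("large_insert", large)):
        thr = pair_metrics.fit_fraction_threshold(fracs, "above", k=cfg.k)
        flagged = pair_metrics.flag_windows(fracs, thr)
        write_bed(flagged, out / f"{name}.bed")
        _write_fractions(fracs, out / f"{name}_fractions.tsv")
        results[name] = {"threshold": thr, "flagged": flagged}
    (out / "insert_model.yaml").write_text(yaml.safe_dump({
        "mean": model.mean, "sd": model.sd,
        "small_cut": model.small_cut, "large_cut": model.large_cut,
        "small_pct_mean": results["small_insert"]["threshold"].mean_pct,
        "small_pct_cutoff": results["small_insert"]["threshold"].cutoff,
        "large_pct_mean": results["large_insert"]["threshold"].mean_pct,
        "large_pct_cutoff": results["large_insert"]["threshold"].cutoff,
    }, sort_keys=True))
    results["model"] = model
    return results


def run_pairing(cfg: PipelineConfig) -> dict[str, object]:
    """Proper-pairing stage: per-window percentage of 0x2-flagged reads,
    flagging windows 2 SD below the mean."""
    cfg.validate()
    _require(cfg.alignments, "alignments SAM/BAM")
    out = _outdir(cfg)
    fracs = pair_metrics.proper_pair_fractions(cfg.alignments, _pair_windows(cfg))
    thr = pair_metrics.fit_fraction_threshold(fracs, "below", k=cfg.k)
    flagged = pair_metrics.flag_windows(fracs, thr)
    write_bed(flagged, out / "improper_pair.bed")
    _write_fractions(fracs, out / "proper_pair_fractions.tsv")
    return {"threshold": thr, "flagged": flagged}


def run_variants(cfg: PipelineConfig) -> dict[str, object]:
    """Homozygous-variant stage: consume a VCF when provided, otherwise run
    the minimal internal caller; expand hom_alt sites by the flank and merge."""
    cfg.validate()
    out = _outdir(cfg)
    layout = _layout(cfg)
    if cfg.vcf:
        sites = [s for s in homozygosity.load_variants(_require(cfg.vcf, "VCF"))
                 if s.genotype == "hom_alt" and s.chrom in layout]
    else:
        _require(cfg.alignments, "alignments SAM/BAM")
        sites = [s for s in homozygosity.call_homozygous_sites(
            cfg.alignments, cfg.assembly, cfg.min_depth,
            cfg.min_alt_fraction, cfg.min_baseq) if s.chrom in layout]
    regions_ = homozygosity.homozygous_regions(sites, layout, cfg.flank)
    write_bed(regions_, out / "homozygous_regions.bed")
    pd.DataFrame({
        "chrom": [s.chrom for s in sites], "pos": [s.pos for s in sites],
        "ref": [s.ref for s in sites],
        "alt": [",".join(s.alts) for s in sites],
        "depth": [s.depth for s in sites],
        "alt_fraction": [s.alt_fraction for s in sites],
    }).to_csv(out / "homozygous_sites.tsv", sep="\t", index=False)
    return {"sites": sites, "regions": regions_}


_TRACK_FILES = {
    "HIGH_COV": "high_cov.bed", "LOW_COV": "low_cov.bed",
    "SMALL_INSERT": "small_insert.bed", "LARGE_INSERT": "large_insert.bed",
    "IMPROPER_PAIR": "improper_pair.bed", "HOM_VARIANT": "homozygous_regions.bed",
    "MULTIMAP": "multimap.bed",
}


def load_tracks(cfg: PipelineConfig) -> dict[str, IntervalSet]:
    """Read the persisted evidence-track BEDs, erroring by name on any that
    an earlier stage has not produced yet."""
    out = Path(cfg.outdir)
    tracks = {}
    for name, fname in _TRACK_FILES.items():
        p = out / fname
        if not p.exists():
            raise FileNotFoundError(
                f"evidence track {name} not found: run the stage that writes "
                f"{fname} first")
        tracks[name] = read_bed(p) if p.stat().st_size else IntervalSet({})
    return tracks


def run_merge(cfg: PipelineConfig) -> dict[str, IntervalSet]:
    """Merge evidence tracks into LQ, LC and LQLC region sets."""
    cfg.validate()
    out = _outdir(cfg)
    tracks = load_tracks(cfg)
    lq = regions.build_lq(tracks["HIGH_COV"], tracks["SMALL_INSERT"],
                          tracks["LARGE_INSERT"], tracks["IMPROPER_PAIR"],
                          tracks["HOM_VARIANT"])
    lc = regions.build_lc(tracks["LOW_COV"])
    lqlc = regions.build_lqlc(lq, lc)
    lq_reasons = regions.annotate_reasons(
        lq, {n: tracks[n] for n in ("HIGH_COV", "SMALL_INSERT", "LARGE_INSERT",
                                    "IMPROPER_PAIR", "HOM_VARIANT")})
    write_bed(lq, out / "lq.bed",
              names=[",".join(sorted(r.reasons)) for r in lq_reasons])
    write_bed(lc, out / "lc.bed")
    write_bed(lqlc, out / "lqlc.bed")
    return {"LQ": lq, "LC": lc, "LQLC": lqlc, **tracks}


def run_report(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Summary and overlap reports over the merged tracks.

    ``summary.tsv`` mirrors the per-evidence and LQ/LC/LQLC feature-count /
    mean-size / percent-of-genome table; ``overlap.tsv`` reports annotation
    overlap per track, and ``attribution.tsv`` how much LC territory the
    multimapper windows explain.
    """
    cfg.validate()
    out = _outdir(cfg)
    layout = _layout(cfg)
    merged = run_merge(cfg)
    rows = []
    order = ["HIGH_COV", "SMALL_INSERT", "LARGE_INSERT", "IMPROPER_PAIR",
             "HOM_VARIANT", "LQ", "LC", "LQLC"]
    for name in order:
        s = regions.summarize(merged[name], layout)
        rows.append({"track": name, "n_features": s.n_features,
                     "mean_size": round(s.mean_size),
                     "total_bases": s.total_bases,
                     "pct_genome": s.pct_genome})
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    overlap_rows = []
    for name, (path, mode) in cfg.annotations.items():
        ann = read_bed(_require(path, f"annotation {name}"))
        rep = regions.overlap_report(name, ann, merged["LQ"], merged["LC"],
                                     merged["LQLC"], mode)
        overlap_rows.append({
            "annotation": name, "mode": mode, "total": rep.total,
            "in_LQ": rep.in_lq, "pct_LQ": rep.pct_lq,
            "in_LC": rep.in_lc, "pct_LC": rep.pct_lc,
            "in_LQLC": rep.in_lqlc, "pct_LQLC": rep.pct_lqlc,
        })
    overlap = pd.DataFrame(overlap_rows)
    overlap.to_csv(out / "overlap.tsv", sep="\t", index=False,
                   float_format="%.6g")
    # multimapper attribution of LC
    mm_tsv = out / "multimap_windows.tsv"
    attribution = pd.DataFrame()
    if mm_tsv.exists():
        mm_df = pd.read_csv(mm_tsv, sep="\t")
        windows = IntervalSet.from_records(
            list(zip(mm_df["chrom"], mm_df["start"], mm_df["end"])))
        res = coverage_gc.MultimapResult(
            windows, mm_df["raw_reads"].to_numpy(),
            mm_df["mm_reads"].to_numpy(), mm_df["pct_mm"].to_numpy(),
            merged["MULTIMAP"])
        att = coverage_gc.lc_attribution(merged["LC"], merged["MULTIMAP"], res)
        attribution = pd.DataFrame([dataclasses.asdict(att)])
        attribution.to_csv(out / "attribution.tsv", sep="\t", index=False,
                           float_format="%.6g")
    return {"summary": summary, "overlap": overlap, "attribution": attribution}


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full chain and write a provenance log (config + input
    checksums; no timestamps, so reruns are byte-identical)."""
    cfg.validate()
    out = _outdir(cfg)
    run_coverage(cfg)
    run_multimap(cfg)
    run_inserts(cfg)
    run_pairing(cfg)
    run_variants(cfg)
    reports = run_report(cfg)
    inputs = {"alignments": cfg.alignments, "assembly": cfg.assembly}
    if cfg.gaps:
        inputs["gaps"] = cfg.gaps
    if cfg.vcf:
        inputs["vcf"] = cfg.vcf
    log = {
        "config": yaml.safe_load(yaml.safe_dump(dataclasses.asdict(cfg))),
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()
                            if v and Path(v).exists()},
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return reports
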