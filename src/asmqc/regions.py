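"""Assemble evidence tracks into LQ / LC / LQLC region sets and report on them.

LQ (low quality) regions are the strongest misassembly evidence: high
GC-normalised coverage, excess small or large inserts, depressed proper
pairing, or proximity to a homozygous non-reference variant.  LC (low
coverage) regions are kept separate — they may reflect poor mappability or
library bias rather than misassembly — and LQLC is the merged union of both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

from .intervals import GenomeLayout, IntervalSet, intersect, merge_intervals

__all__ = [
    "EVIDENCE_CLASSES",
    "FlaggedRegion",
    "RegionSummary",
    "OverlapReport",
    "build_lq",
    "build_lc",
    "build_lqlc",
    "annotate_reasons",
    "summarize",
    "overlap_report",
]

EVIDENCE_CLASSES = ("HIGH_COV", "LOW_COV", "SMALL_INSERT", "LARGE_INSERT",
                    "IMPROPER_PAIR", "HOM_VARIANT", "MULTIMAP")

# evidence classes that contribute to LQ; LOW_COV feeds LC and MULTIMAP is
# attribution-only
_LQ_EVIDENCE = ("HIGH_COV", "SMALL_INSERT", "LARGE_INSERT", "IMPROPER_PAIR",
                "HOM_VARIANT")


@dataclass(frozen=True)
class FlaggedRegion:
    chrom: str
    start: int
    end: int
    reasons: frozenset[str]

    def __post_init__(self) -> None:
        if not self.reasons:
            raise ValueError("a flagged region needs at least one reason")
        unknown = self.reasons - set(EVIDENCE_CLASSES)
        if unknown:
            raise ValueError(f"unknown evidence classes: {sorted(unknown)}")


@dataclass
class RegionSummary:
    """Feature count, mean feature size and percentage of genome."""

    n_features: int
    total_bases: int
    genome_size: int

    @property
    def mean_size(self) -> float:
        return self.total_bases / self.n_features if self.n_features else 0.0

    @property
    def pct_genome(self) -> float:
        return 100.0 * self.total_bases / self.genome_size


@dataclass
class OverlapReport:
    """Annotation overlap against the LQ / LC / LQLC tracks."""

    name: str
    mode: Literal["feature_count", "base_count"]
    total: int
    in_lq: int
    in_lc: int
    in_lqlc: int

    def _pct(self, x: int) -> float:
        return 100.0 * x / self.total if self.total else 0.0

    @property
    def pct_lq(self) -> float:
        return self._pct(self.in_lq)

    @property
    def pct_lc(self) -> float:
        return self._pct(self.in_lc)

    @property
    def pct_lqlc(self) -> float:
        return self._pct(self.in_lqlc)


def build_lq(high_cov: IntervalSet, small_insert: IntervalSet,
             large_insert: IntervalSet, improper_pair: IntervalSet,
             hom_variant: IntervalSet) -> IntervalSet:
    """Merged union of the five LQ evidence tracks."""
    records = []
    for track in (high_cov, small_insert, large_insert, improper_pair, hom_variant):
        records.extend((iv.chrom, iv.start, iv.end) for iv in track)
    return merge_intervals(IntervalSet.from_records(records))


def build_lc(low_cov_windows: IntervalSet) -> IntervalSet:
    """Merged low-coverage windows."""
    return merge_intervals(low_cov_windows)


def build_lqlc(lq: IntervalSet, lc: IntervalSet) -> IntervalSet:
    """Merged union of LQ and LC."""
    records = [(iv.chrom, iv.start, iv.end) for iv in lq]
    records += [(iv.chrom, iv.start, iv.end) for iv in lc]
    return merge_intervals(IntervalSet.from_records(records))


def annotate_reasons(regions: IntervalSet,
                     tracks: Mapping[str, IntervalSet]) -> list[FlaggedRegion]:
    """Label each merged region with the evidence classes overlapping it."""
    merged_tracks = {name: merge_intervals(t) for name, t in tracks.items()}
    out = []
    for iv in regions:
        single = IntervalSet({iv.chrom: [(iv.start, iv.end)]})
        reasons = frozenset(
            name for name, t in merged_tracks.items()
            if intersect(single, t)[1] > 0
        )
        out.append(FlaggedRegion(iv.chrom, iv.start, iv.end, reasons))
    return out


def summarize(regions: IntervalSet, layout: GenomeLayout,
              excluded_chroms: tuple[str, ...] = ()) -> RegionSummary:
    """Feature count, mean size and percent of genome for a merged track.

    The genome denominator is the layout minus any excluded chromosomes
    (e.g. chrY for a female individual); regions on excluded chromosomes are
    not counted either.
    """
    layout = layout.drop(excluded_chroms)
    merged = merge_intervals(regions)
    n = 0
    bases = 0
    for chrom in merged.chroms:
        if chrom not in layout:
            continue
        arr = merged.by_chrom(chrom)
        n += len(arr)
        bases += int((arr[:, 1] - arr[:, 0]).sum())
    return RegionSummary(n, bases, layout.total_size)


def overlap_report(name: str, annotation: IntervalSet, lq: IntervalSet,
                   lc: IntervalSet, lqlc: IntervalSet,
                   mode: Literal["feature_count", "base_count"]) -> OverlapReport:
    """Count annotation features (or bases) falling in each region track.

    ``feature_count`` counts annotation features with >= 1 bp overlap (point
    variants, CNVR intervals); ``base_count`` counts overlapping bases
    (coding sequence, gene-model territory).
    """
    if mode == "feature_count":
        total = annotation.n_features
        vals = [intersect(annotation, t)[0].n_features for t in (lq, lc, lqlc)]
    elif mode == "base_count":
        total = merge_intervals(annotation).total_bases
        vals = [intersect(annotation, t)[1] for t in (lq, lc, lqlc)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return OverlapReport(name, mode, total, *vals)
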