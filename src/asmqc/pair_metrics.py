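"""Insert-size and proper-pairing window metrics on overlapping windows.

Paired-end libraries have a tight template-length distribution; windows where
an unusual fraction of pairs map abnormally far apart, abnormally close, or
in the wrong orientation carry structural-variation signatures of assembly
errors.  Fractions are computed on 1 kb windows overlapping by 200 bp
(step 800) and flagged beyond 2 SD of the genome-wide fraction distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ._samio import ReadTable, count_overlapping, load_read_table
from .intervals import IntervalSet, merge_intervals

__all__ = [
    "InsertSizeModel",
    "WindowFraction",
    "FractionThreshold",
    "fit_insert_model",
    "abnormal_insert_fractions",
    "proper_pair_fractions",
    "fit_fraction_threshold",
    "flag_windows",
]


@dataclass
class InsertSizeModel:
    """Mean/SD of the template-length distribution with symmetric 2-SD cutoffs."""

    mean: float
    sd: float
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("degenerate insert-size distribution (sd <= 0)")

    @property
    def small_cut(self) -> float:
        return self.mean - self.k * self.sd

    @property
    def large_cut(self) -> float:
        return self.mean + self.k * self.sd


@dataclass
class WindowFraction:
    chrom: str
    start: int
    end: int
    subset_count: int
    total_count: int

    @property
    def pct(self) -> float:
        return 100.0 * self.subset_count / self.total_count if self.total_count else 0.0


@dataclass
class FractionThreshold:
    """Mean/SD of window percentages and the one-sided k-SD cutoff."""

    mean_pct: float
    sd_pct: float
    direction: Literal["above", "below"]
    k: float = 2.0

    @property
    def cutoff(self) -> float:
        sign = 1.0 if self.direction == "above" else -1.0
        return self.mean_pct + sign * self.k * self.sd_pct

    def is_abnormal(self, pct: float) -> bool:
        return pct > self.cutoff if self.direction == "above" else pct < self.cutoff


def fit_insert_model(path_or_table: str | Path | ReadTable, k: float = 2.0,
                     min_pairs: int = 1000, trim_factor: float = 10.0) -> InsertSizeModel:
    """Mean and SD of absolute template lengths of proper FR pairs.

    Each pair is counted once (the mate with positive TLEN).  Template
    lengths above ``trim_factor`` × the median are discarded first: chimeric
    or cross-contig artefacts otherwise dominate the second moment.
    """
    table = path_or_table if isinstance(path_or_table, ReadTable) else load_read_table(path_or_table)
    tlens = []
    for chrom in table.chroms:
        t = table.tlen[chrom]
        keep = table.proper[chrom] & (t > 0)
        tlens.append(t[keep])
    tlens = np.concatenate(tlens) if tlens else np.empty(0, np.int64)
    if len(tlens) < min_pairs:
        raise ValueError(f"only {len(tlens)} usable pairs (< {min_pairs})")
    med = np.median(tlens)
    trimmed = tlens[tlens <= trim_factor * med]
    mean = float(np.mean(trimmed))
    sd = float(np.std(trimmed))
    return InsertSizeModel(mean, sd, k)


def _window_fractions(table: ReadTable, windows: IntervalSet,
                      subset_masks: dict[str, np.ndarray]) -> list[WindowFraction]:
    out = []
    for chrom in windows.chroms:
        w = windows.by_chrom(chrom)
        ws, we = w[:, 0], w[:, 1]
        s = table.start.get(chrom, np.empty(0, np.int64))
        e = table.end.get(chrom, np.empty(0, np.int64))
        total = count_overlapping(np.sort(s), np.sort(e), ws, we)
        mask = subset_masks.get(chrom, np.zeros(len(s), bool))
        sub = count_overlapping(np.sort(s[mask]), np.sort(e[mask]), ws, we)
        out.extend(WindowFraction(chrom, int(a), int(b), int(c), int(t))
                   for a, b, c, t in zip(ws, we, sub, total))
    return out


def abnormal_insert_fractions(path_or_table: str | Path | ReadTable,
                              model: InsertSizeModel, windows: IntervalSet,
                              ) -> tuple[list[WindowFraction], list[WindowFraction]]:
    """Per-window percentages of small- and large-insert reads.

    A read is small-insert when |TLEN| < ``small_cut`` and large-insert when
    |TLEN| > ``large_cut`` (strict; the two classes are mutually exclusive).
    Reads with TLEN 0 (mate unmapped or cross-contig) are in neither class.
    Denominators count every read overlapping the window by >= 1 bp.
    """
    table = path_or_table if isinstance(path_or_table, ReadTable) else load_read_table(path_or_table)
    small_masks, large_masks = {}, {}
    for chrom in table.chroms:
        t = np.abs(table.tlen[chrom])
        nonzero = t > 0
        small_masks[chrom] = nonzero & (t < model.small_cut)
        large_masks[chrom] = nonzero & (t > model.large_cut)
    return (_window_fractions(table, windows, small_masks),
            _window_fractions(table, windows, large_masks))


def proper_pair_fractions(path_or_table: str | Path | ReadTable,
                          windows: IntervalSet) -> list[WindowFraction]:
    """Per-window percentage of reads carrying the proper-pair flag (0x2)."""
    table = path_or_table if isinstance(path_or_table, ReadTable) else load_read_table(path_or_table)
    masks = {c: table.proper[c] for c in table.chroms}
    return _window_fractions(table, windows, masks)


def fit_fraction_threshold(fractions: Sequence[WindowFraction],
                           direction: Literal["above", "below"],
                           k: float = 2.0, min_windows: int = 100) -> FractionThreshold:
    """Plain mean/SD of window percentages over non-empty windows.

    Empty windows (no overlapping reads) are excluded so unsequenced
    territory does not deflate the mean; the cutoff is ``mean ± k·SD`` in the
    given direction.
    """
    pcts = np.array([f.pct for f in fractions if f.total_count > 0])
    if len(pcts) < min_windows:
        raise ValueError(f"only {len(pcts)} non-empty windows (< {min_windows})")
    return FractionThreshold(float(np.mean(pcts)), float(np.std(pcts)), direction, k)


def flag_windows(fractions: Sequence[WindowFraction],
                 threshold: FractionThreshold,
                 require_reads: bool = True) -> IntervalSet:
    """Merged regions of windows whose percentage is strictly beyond the cutoff.

    Windows without reads are never flagged (their pct of 0 is a reporting
    convention, not evidence).
    """
    flagged = [(f.chrom, f.start, f.end) for f in fractions
               if (f.total_count > 0 or not require_reads)
               and threshold.is_abnormal(f.pct)]
    return merge_intervals(IntervalSet.from_records(flagged))
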