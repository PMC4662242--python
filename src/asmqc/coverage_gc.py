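"""GC-normalised fragment coverage and abnormal-coverage window flagging.

The coverage evidence chain: filter read pairs (mapq and proper-pair), take
each pair's whole fragment span, compute per-base fragment depth, take the
median depth of each 1 kb window, normalise by GC content with a per-GC-bin
median-ratio factor, fit a robust normal to the normalised values and flag
windows beyond ``mean ± k·SD``.  Low-coverage windows are additionally
cross-examined against multimapper density: windows dominated by ambiguously
placed reads (mapq 0) are usually mappability artefacts, not misassemblies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from scipy.optimize import curve_fit

from ._samio import count_overlapping, load_read_table
from .intervals import GenomeLayout, IntervalSet, merge_intervals, _overlap_mask

logger = logging.getLogger(__name__)

__all__ = [
    "WindowCoverage",
    "GcNormModel",
    "RobustNormal",
    "extract_fragments",
    "window_median_coverage",
    "gc_percent",
    "fit_gc_model",
    "fit_robust_normal",
    "classify_coverage",
    "multimap_windows",
    "lc_attribution",
]


@dataclass
class WindowCoverage:
    """Per-window coverage metrics."""

    chrom: str
    start: int
    end: int
    median_cov: float
    gc_pct: int | None = None      # None when the window has no unambiguous bases
    norm_cov: float | None = None

    def __post_init__(self) -> None:
        if self.median_cov < 0:
            raise ValueError("median_cov must be >= 0")
        if self.gc_pct is not None and not (0 <= self.gc_pct <= 100):
            raise ValueError("gc_pct must lie in [0, 100]")


@dataclass
class GcNormModel:
    """Median-ratio GC normalisation.

    For a window with GC percentage g, the multiplying factor is
    ``f(g) = global_median / bin_median(g)``; bins with too few windows or a
    zero median are left uncorrected (f = 1).
    """

    global_median: float
    bin_median: dict[int, float]
    factor: dict[int, float]
    n_windows: dict[int, int]

    def f(self, gc_pct: int | None) -> float:
        if gc_pct is None:
            return 1.0
        return self.factor.get(int(gc_pct), 1.0)


@dataclass
class RobustNormal:
    """A normal law fitted to the central bulk of a sample, with k·SD cutoffs."""

    mean: float
    sd: float
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    @property
    def low_cut(self) -> float:
        return self.mean - self.k * self.sd

    @property
    def high_cut(self) -> float:
        return self.mean + self.k * self.sd


def extract_fragments(path: str | Path, min_mapq: int = 2,
                      require_proper: bool = True) -> IntervalSet:
    """Whole-fragment spans of retained read pairs.

    A pair is retained when both mates are primary, mapped to the same
    chromosome, properly paired (when ``require_proper``) and have mapping
    quality >= ``min_mapq``.  Each retained pair contributes one interval
    from the leftmost mate start to the rightmost mate end.  Orphans left
    after filtering are skipped and counted in the log.
    """
    pending: dict[str, tuple[str, int, int, bool]] = {}
    frags: list[tuple[str, int, int]] = []
    n_orphan = 0
    last_pos: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            if rec.reference_start < last_pos.get(chrom, 0):
                raise ValueError(f"input is not coordinate-sorted at "
                                 f"{chrom}:{rec.reference_start}")
            last_pos[chrom] = rec.reference_start
            ok = rec.mapping_quality >= min_mapq and (
                rec.is_proper_pair or not require_proper)
            qname = rec.query_name
            if qname not in pending:
                pending[qname] = (chrom, rec.reference_start, rec.reference_end, ok)
                continue
            mchrom, mstart, mend, mok = pending.pop(qname)
            if ok and mok and mchrom == chrom:
                frags.append((chrom, min(rec.reference_start, mstart),
                              max(rec.reference_end, mend)))
    n_orphan = len(pending)
    if n_orphan:
        logger.info("extract_fragments: %d unpaired reads skipped after filtering",
                    n_orphan)
    return IntervalSet.from_records(frags)


def window_median_coverage(depth: dict[str, np.ndarray],
                           windows: IntervalSet) -> list[WindowCoverage]:
    """Median per-base fragment depth of each window (zeros included)."""
    out = []
    for chrom in windows.chroms:
        track = depth.get(chrom)
        for s, e in windows.by_chrom(chrom):
            if track is None:
                med = 0.0
            else:
                med = float(np.median(track[s:e]))
            out.append(WindowCoverage(chrom, int(s), int(e), med))
    return out


_GC = frozenset(b"GCgc")
_ACGT = frozenset(b"ACGTacgt")


def gc_percent(seq: str | bytes) -> int | None:
    """Integer GC percentage of a sequence.

    Ambiguous bases are excluded from the denominator; a sequence with no
    unambiguous base has undefined GC (returns None) and is excluded from
    normalisation.
    """
    if isinstance(seq, str):
        seq = seq.encode()
    arr = np.frombuffer(seq, dtype=np.uint8)
    up = arr & 0xDF  # uppercase
    gc = int(((up == ord("G")) | (up == ord("C"))).sum())
    at = int(((up == ord("A")) | (up == ord("T"))).sum())
    denom = gc + at
    if denom == 0:
        return None
    return int(round(100.0 * gc / denom))


def annotate_gc(wins: list[WindowCoverage], fasta_path: str | Path) -> None:
    """Fill each window's gc_pct from the assembly sequence, in place."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    for w in wins:
        w.gc_pct = gc_percent(str(fa[w.chrom][w.start:w.end]))


def fit_gc_model(wins: Sequence[WindowCoverage],
                 min_bin_windows: int = 50) -> GcNormModel:
    """Fit the per-GC-bin median-ratio model and normalise the windows.

    Sets ``norm_cov = median_cov * f(gc_pct)`` on every window in place and
    returns the fitted model.  Bins with fewer than ``min_bin_windows``
    windows, or with a zero median, get f = 1 (no correction): the ratio is
    unstable there.
    """
    if not wins:
        raise ValueError("need at least one window")
    medians = np.array([w.median_cov for w in wins])
    global_median = float(np.median(medians))
    if global_median == 0:
        raise ValueError("all window medians are zero: degenerate library")
    by_bin: dict[int, list[float]] = {}
    for w in wins:
        if w.gc_pct is not None:
            by_bin.setdefault(int(w.gc_pct), []).append(w.median_cov)
    bin_median, factor, n_windows = {}, {}, {}
    for g, vals in sorted(by_bin.items()):
        m = float(np.median(vals))
        bin_median[g] = m
        n_windows[g] = len(vals)
        factor[g] = global_median / m if (len(vals) >= min_bin_windows and m > 0) else 1.0
    model = GcNormModel(global_median, bin_median, factor, n_windows)
    for w in wins:
        w.norm_cov = w.median_cov * model.f(w.gc_pct)
    return model


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_robust_normal(values: Sequence[float] | np.ndarray, k: float = 2.0,
                      n_iter: int = 2) -> RobustNormal:
    """Normal law describing the central bulk of ``values``.

    Heavy right tails (collapsed repeats can push window coverage to many
    times the mode) inflate the plain sample moments, so the fit is a
    least-squares Gaussian laid over the histogram (unit-width bins) of a
    central range, re-estimated iteratively: the first pass uses the 5th-95th
    percentile range, each subsequent pass restricts to ``mean ± 3·sd`` of
    the previous fit.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError("need at least 100 values for a robust fit")
    lo, hi = np.percentile(values, [5, 95])
    mean = sd = None
    for it in range(n_iter):
        edges = np.arange(np.floor(lo), np.ceil(hi) + 1.0)
        if len(edges) < 5:
            # all mass in very few unit bins: refine bin width
            edges = np.linspace(lo, hi, 16)
        counts, edges = np.histogram(values, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        if counts.sum() == 0:
            raise ValueError("robust normal fit failed: empty central range")
        mu0 = centers[np.argmax(counts)]
        sigma0 = max(float(np.std(values[(values >= lo) & (values <= hi)])), 1e-3)
        try:
            popt, _ = curve_fit(_gauss, centers, counts,
                                p0=(counts.max(), mu0, sigma0), maxfev=10000)
        except RuntimeError as exc:
            raise ValueError(f"robust normal fit did not converge "
                             f"(iteration {it}, range [{lo:.3g}, {hi:.3g}])") from exc
        mean, sd = float(popt[1]), float(abs(popt[2]))
        if sd <= 0 or not np.isfinite(mean) or not np.isfinite(sd):
            raise ValueError("robust normal fit degenerate (sd <= 0)")
        lo, hi = mean - 3 * sd, mean + 3 * sd
    return RobustNormal(mean, sd, k)


def classify_coverage(norm_cov: float, model: RobustNormal) -> str:
    """HIGH above ``high_cut``, LOW below ``low_cut``, otherwise NORMAL.

    Inequalities are strict: a value equal to a cutoff is NORMAL.
    """
    if norm_cov > model.high_cut:
        return "HIGH"
    if norm_cov < model.low_cut:
        return "LOW"
    return "NORMAL"


@dataclass
class MultimapResult:
    """Per-window multimapper tallies and the flagged (>50%) regions."""

    windows: IntervalSet
    raw_counts: np.ndarray       # reads overlapping each window
    mm_counts: np.ndarray        # multimapped reads overlapping each window
    pct: np.ndarray
    flagged: IntervalSet         # merged windows with pct > threshold


def multimap_windows(path: str | Path, windows: IntervalSet,
                     pct_threshold: float = 50.0,
                     read_table=None) -> MultimapResult:
    """Flag windows where more than ``pct_threshold`` % of overlapping reads
    are multimapped (mapq 0).

    Such windows are expected to explain most low-coverage territory: the
    coverage chain drops mapq-0 reads, so repeat-dominated windows look
    unsequenced.  Windows with no reads at all count as 0 %.
    """
    table = read_table if read_table is not None else load_read_table(path)
    raw_all, mm_all, flagged = [], [], {}
    for chrom in windows.chroms:
        w = windows.by_chrom(chrom)
        ws, we = w[:, 0], w[:, 1]
        s = table.start.get(chrom, np.empty(0, np.int64))
        e = table.end.get(chrom, np.empty(0, np.int64))
        mq = table.mapq.get(chrom, np.empty(0, np.int64))
        raw = count_overlapping(np.sort(s), np.sort(e), ws, we)
        mm_mask = mq == 0
        mm = count_overlapping(np.sort(s[mm_mask]), np.sort(e[mm_mask]), ws, we)
        raw_all.append(raw)
        mm_all.append(mm)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(raw > 0, 100.0 * mm / np.maximum(raw, 1), 0.0)
        flagged[chrom] = w[pct > pct_threshold]
    raw_cat = np.concatenate(raw_all) if raw_all else np.empty(0, np.int64)
    mm_cat = np.concatenate(mm_all) if mm_all else np.empty(0, np.int64)
    pct_cat = np.where(raw_cat > 0, 100.0 * mm_cat / np.maximum(raw_cat, 1), 0.0)
    return MultimapResult(windows, raw_cat, mm_cat, pct_cat,
                          merge_intervals(IntervalSet(flagged, chrom_order=windows.chroms)))


@dataclass
class LcAttribution:
    """How much low-coverage territory is explained by multimappers."""

    pct_mm_in_lc: float          # % of multimapper regions overlapping LC (by feature)
    pct_lc_in_mm: float          # % of LC regions overlapping multimapper regions
    median_reads_all: float      # median window read count, genome-wide
    median_reads_lc_non_mm: float  # median window read count in LC windows outside mm regions


def lc_attribution(lc_regions: IntervalSet, mm_regions: IntervalSet,
                   mm_result: MultimapResult) -> LcAttribution:
    """Attribute low-coverage regions to multimapper removal.

    Feature-level overlap fractions in both directions, plus the median
    per-window read count genome-wide and within LC windows that fall outside
    the multimapper regions.
    """
    from .intervals import intersect

    mm_in_lc, _ = intersect(mm_regions, lc_regions)
    lc_in_mm, _ = intersect(lc_regions, mm_regions)
    pct_mm = 100.0 * mm_in_lc.n_features / mm_regions.n_features if mm_regions.n_features else 0.0
    pct_lc = 100.0 * lc_in_mm.n_features / lc_regions.n_features if lc_regions.n_features else 0.0
    median_all = float(np.median(mm_result.raw_counts)) if len(mm_result.raw_counts) else 0.0
    lc_merged = merge_intervals(lc_regions)
    mm_merged = merge_intervals(mm_regions)
    counts = []
    i = 0
    for chrom in mm_result.windows.chroms:
        w = mm_result.windows.by_chrom(chrom)
        in_lc = _overlap_mask(w, lc_merged.by_chrom(chrom))
        in_mm = _overlap_mask(w, mm_merged.by_chrom(chrom))
        sel = in_lc & ~in_mm
        counts.append(mm_result.raw_counts[i:i + len(w)][sel])
        i += len(w)
    sel_counts = np.concatenate(counts) if counts else np.empty(0)
    median_lc = float(np.median(sel_counts)) if len(sel_counts) else 0.0
    return LcAttribution(pct_mm, pct_lc, median_all, median_lc)
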