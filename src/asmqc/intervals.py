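"""Genomic interval algebra and BED I/O.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` bases.  The module provides the small
set of interval primitives the region-flagging pipeline is built on —
fixed-width windowing, merging, intersection, gap-window removal and per-base
fragment depth — with semantics matching the defaults of the classic BED
toolchain (bookended intervals fuse on merge; any-overlap, ≥ 1 bp, counts as
intersection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "IntervalSet",
    "make_windows",
    "merge_intervals",
    "intersect",
    "remove_gap_windows",
    "fragment_depth",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


class GenomeLayout:
    """Ordered chromosome names and lengths; the denominator for
    percentage-of-genome statistics."""

    def __init__(self, chrom_lengths: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(chrom_lengths.items()) if isinstance(chrom_lengths, Mapping) else list(chrom_lengths)
        names = [c for c, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for c, n in items:
            if n <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length {n}")
        self._lengths: dict[str, int] = dict(items)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        items = []
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{i}: expected 'name<TAB>length'")
            items.append((fields[0], int(fields[1])))
        return cls(items)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeLayout":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls([(name, len(fa[name])) for name in fa.keys()])

    @property
    def chroms(self) -> list[str]:
        return list(self._lengths)

    @property
    def total_size(self) -> int:
        return sum(self._lengths.values())

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def items(self):
        return self._lengths.items()

    def drop(self, excluded: Iterable[str]) -> "GenomeLayout":
        """Layout with the given chromosomes removed (e.g. chrY for a female)."""
        excluded = set(excluded)
        return GenomeLayout([(c, n) for c, n in self._lengths.items() if c not in excluded])


def _as_array(ivals: Sequence[tuple[int, int]] | np.ndarray) -> np.ndarray:
    arr = np.asarray(ivals, dtype=np.int64).reshape(-1, 2)
    return arr


class IntervalSet:
    """Intervals grouped by chromosome, kept sorted by start.

    ``extra`` optionally carries the surplus BED columns of each record (in
    iteration order) as read from file; canonical writes drop them.
    """

    def __init__(
        self,
        by_chrom: Mapping[str, np.ndarray | Sequence[tuple[int, int]]] | None = None,
        chrom_order: Sequence[str] | None = None,
    ):
        self._data: dict[str, np.ndarray] = {}
        order = list(chrom_order) if chrom_order is not None else list(by_chrom or {})
        for chrom in order:
            arr = _as_array((by_chrom or {}).get(chrom, np.empty((0, 2), np.int64)))
            if arr.size and not (arr[:, 0] < arr[:, 1]).all():
                bad = arr[arr[:, 0] >= arr[:, 1]][0]
                raise ValueError(f"invalid interval {chrom}:{bad[0]}-{bad[1]}")
            if arr.size and (arr[:, 0] < 0).any():
                raise ValueError(f"negative coordinate on {chrom}")
            self._data[chrom] = arr[np.lexsort((arr[:, 1], arr[:, 0]))] if arr.size else arr
        self.extra: list[tuple[str, ...]] | None = None

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            grouped.setdefault(chrom, []).append((start, end))
        return cls(grouped)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def by_chrom(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty((0, 2), np.int64))

    @property
    def n_features(self) -> int:
        return sum(len(a) for a in self._data.values())

    @property
    def total_bases(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def __len__(self) -> int:
        return self.n_features

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, arr in self._data.items():
            for s, e in arr:
                yield GenomicInterval(chrom, int(s), int(e))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __repr__(self) -> str:
        return f"IntervalSet({self.n_features} features, {self.total_bases} bases)"

    def merge(self) -> "IntervalSet":
        return merge_intervals(self)


def make_windows(layout: GenomeLayout, width: int, step: int) -> IntervalSet:
    """Tile every chromosome with windows of ``width`` advancing by ``step``.

    The final window of each chromosome is truncated at the chromosome end;
    every base is covered by at least one window.  ``step`` may not exceed
    ``width`` (that would leave uncovered bases).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if not (0 < step <= width):
        raise ValueError("require 0 < step <= width (larger steps leave gaps)")
    data = {}
    for chrom, length in layout.items():
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        data[chrom] = np.column_stack([starts, ends])
    return IntervalSet(data, chrom_order=layout.chroms)


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Minimal non-overlapping set covering the union of the input bases.

    Overlapping and bookended (touching) intervals fuse, matching the default
    behaviour of BED-style merge with distance 0.
    """
    out = {}
    for chrom in s.chroms:
        arr = s.by_chrom(chrom)
        if len(arr) == 0:
            out[chrom] = arr
            continue
        # arr already sorted by start; fuse where start <= running max end
        run_end = np.maximum.accumulate(arr[:, 1])
        new_group = np.ones(len(arr), dtype=bool)
        new_group[1:] = arr[1:, 0] > run_end[:-1]
        group = np.cumsum(new_group) - 1
        n = group[-1] + 1
        starts = arr[new_group, 0]
        ends = np.zeros(n, dtype=np.int64)
        np.maximum.at(ends, group, arr[:, 1])
        out[chrom] = np.column_stack([starts, ends])
    return IntervalSet(out, chrom_order=s.chroms)


def _overlap_mask(features: np.ndarray, merged_other: np.ndarray) -> np.ndarray:
    """Boolean mask: which ``features`` overlap (≥1 bp) the merged, sorted
    intervals of ``merged_other``."""
    if len(features) == 0 or len(merged_other) == 0:
        return np.zeros(len(features), dtype=bool)
    # first interval of other whose end > feature.start
    j = np.searchsorted(merged_other[:, 1], features[:, 0], side="right")
    ok = j < len(merged_other)
    mask = np.zeros(len(features), dtype=bool)
    mask[ok] = merged_other[j[ok], 0] < features[ok, 1]
    return mask


def _pairwise_overlap_bases(a: np.ndarray, b: np.ndarray) -> int:
    """Overlap bases between two merged, sorted interval arrays."""
    i = j = 0
    tot = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if e > s:
            tot += e - s
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return int(tot)


def intersect(a: IntervalSet, b: IntervalSet) -> tuple[IntervalSet, int]:
    """Features of ``a`` overlapping ``b``, and the total overlap base count.

    Returns a pair: (i) the subset of ``a``'s features with ≥ 1 bp overlap
    with ``b`` (feature-count mode) and (ii) the number of bases in the
    intersection of the two base sets (base-count mode).
    """
    b_merged = merge_intervals(b)
    a_merged = merge_intervals(a)
    out = {}
    bases = 0
    for chrom in a.chroms:
        feats = a.by_chrom(chrom)
        other = b_merged.by_chrom(chrom)
        out[chrom] = feats[_overlap_mask(feats, other)]
        bases += _pairwise_overlap_bases(a_merged.by_chrom(chrom), other)
    return IntervalSet(out, chrom_order=a.chroms), bases


def remove_gap_windows(windows: IntervalSet, gaps: IntervalSet) -> IntervalSet:
    """Drop every window overlapping (≥ 1 bp) an assembly gap."""
    gaps_merged = merge_intervals(gaps)
    out = {}
    for chrom in windows.chroms:
        w = windows.by_chrom(chrom)
        out[chrom] = w[~_overlap_mask(w, gaps_merged.by_chrom(chrom))]
    return IntervalSet(out, chrom_order=windows.chroms)


def fragment_depth(fragments: IntervalSet, layout: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-base depth: number of fragments covering each base.

    Counts each fragment's full span once (pair-level, not read-level,
    coverage).  Fragments outside the layout are rejected by identity.
    """
    depth = {c: np.zeros(n, dtype=np.int32) for c, n in layout.items()}
    for chrom in fragments.chroms:
        arr = fragments.by_chrom(chrom)
        if len(arr) == 0:
            continue
        if chrom not in layout:
            raise ValueError(f"fragment on unknown sequence {chrom!r}: "
                             f"{chrom}:{arr[0, 0]}-{arr[0, 1]}")
        length = layout.length(chrom)
        bad = arr[:, 1] > length
        if bad.any():
            s, e = arr[bad][0]
            raise ValueError(f"fragment outside layout bounds: {chrom}:{s}-{e} "
                             f"(chromosome length {length})")
        diff = np.zeros(length + 1, dtype=np.int32)
        np.add.at(diff, arr[:, 0], 1)
        np.add.at(diff, arr[:, 1], -1)
        depth[chrom] = np.cumsum(diff[:-1], dtype=np.int32)
    return depth


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open); extra columns are preserved on
    the returned set's ``extra`` attribute, in iteration order."""
    records: list[tuple[str, int, int]] = []
    extras: list[tuple[str, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {fields[0]}:{start}-{end}"
                )
            records.append((fields[0], start, end))
            extras.append(tuple(fields[3:]))
    # keep the file's record order grouped by chrom, sorted within chrom
    order: dict[str, list[int]] = {}
    for i, (c, _, _) in enumerate(records):
        order.setdefault(c, []).append(i)
    data = {}
    extra_out: list[tuple[str, ...]] = []
    for chrom, idx in order.items():
        arr = np.array([(records[i][1], records[i][2]) for i in idx], dtype=np.int64)
        sort = np.lexsort((arr[:, 1], arr[:, 0]))
        data[chrom] = arr[sort]
        extra_out.extend(extras[idx[k]] for k in sort)
    s = IntervalSet(data, chrom_order=list(order))
    s.extra = extra_out
    return s


def write_bed(s: IntervalSet, path: str | Path, names: Sequence[str] | None = None) -> None:
    """Write a canonical BED file (BED3, or BED4 when ``names`` are given,
    one name per feature in iteration order)."""
    if names is not None and len(names) != s.n_features:
        raise ValueError("names length must equal feature count")
    with open(path, "w") as fh:
        i = 0
        for iv in s:
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")
            i += 1
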