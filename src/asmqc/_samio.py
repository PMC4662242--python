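"""Internal helpers for loading alignment records into flat numpy tables.

Window statistics need, for every primary alignment: the aligned span, the
mapping quality, the template length and the proper-pair flag.  Loading these
once into per-chromosome arrays keeps the window loops vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam


@dataclass
class ReadTable:
    """Per-chromosome flat arrays for primary, mapped alignments."""

    start: dict[str, np.ndarray]   # aligned reference start (0-based)
    end: dict[str, np.ndarray]     # aligned reference end (exclusive)
    mapq: dict[str, np.ndarray]
    tlen: dict[str, np.ndarray]    # signed template length as recorded
    proper: dict[str, np.ndarray]  # SAM flag 0x2
    n_reads: int

    @property
    def chroms(self) -> list[str]:
        return list(self.start)


def load_read_table(path: str | Path) -> ReadTable:
    """Single pass over a SAM/BAM collecting span/mapq/tlen/proper per read.

    Secondary, supplementary and unmapped records are skipped; every primary
    mapped read (regardless of mapq or pairing) is kept, so callers can apply
    their own filters.
    """
    cols: dict[str, list[tuple[int, int, int, int, int]]] = {}
    n = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cols.setdefault(rec.reference_name, []).append(
                (rec.reference_start, rec.reference_end,
                 rec.mapping_quality, rec.template_length,
                 1 if rec.is_proper_pair else 0)
            )
            n += 1
    start, end, mapq, tlen, proper = {}, {}, {}, {}, {}
    for chrom, rows in cols.items():
        arr = np.asarray(rows, dtype=np.int64)
        start[chrom] = arr[:, 0]
        end[chrom] = arr[:, 1]
        mapq[chrom] = arr[:, 2]
        tlen[chrom] = arr[:, 3]
        proper[chrom] = arr[:, 4].astype(bool)
    return ReadTable(start, end, mapq, tlen, proper, n)


def count_overlapping(starts_sorted: np.ndarray, ends_sorted: np.ndarray,
                      win_start: np.ndarray, win_end: np.ndarray) -> np.ndarray:
    """Number of reads overlapping each window by >= 1 bp.

    ``starts_sorted`` and ``ends_sorted`` are independently sorted copies of
    the read start/end arrays.  A read [s, e) overlaps window [ws, we) iff
    s < we and e > ws; with s < e always, the count is
    N - #{s >= we} - #{e <= ws}.
    """
    n = len(starts_sorted)
    if n == 0:
        return np.zeros(len(win_start), dtype=np.int64)
    start_after = n - np.searchsorted(starts_sorted, win_end, side="left")
    end_before = np.searchsorted(ends_sorted, win_start, side="right")
    return n - start_after - end_before
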