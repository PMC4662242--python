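"""Homozygous non-reference variants and their flanking low-quality regions.

When an individual's reads are mapped back to an assembly built from that
same individual, a correctly assembled position can never yield a homozygous
non-reference call: the assembly carries one of the individual's own alleles.
Homozygous calls therefore mark assembly errors (or base-calling artefacts),
and the region from 100 bases before to 100 bases after each such variant is
considered low quality.

Variant calling proper is external (a VCF is consumed); a minimal counting
caller is provided so the synthetic pipeline runs without external tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pysam

from .intervals import GenomeLayout, IntervalSet, merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSite",
    "load_variants",
    "call_homozygous_sites",
    "homozygous_regions",
]

GenotypeClass = Literal["hom_ref", "het", "hom_alt"]

_BASE_INDEX = {ord("A"): 0, ord("C"): 1, ord("G"): 2, ord("T"): 3,
               ord("a"): 0, ord("c"): 1, ord("g"): 2, ord("t"): 3}
_BASES = "ACGT"


@dataclass
class VariantSite:
    chrom: str
    pos: int                    # 0-based
    ref: str
    alts: tuple[str, ...]
    genotype: GenotypeClass
    depth: int | None = None
    alt_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.alt_fraction is not None and not (0.0 <= self.alt_fraction <= 1.0):
            raise ValueError("alt_fraction must lie in [0, 1]")
        if self.genotype == "hom_alt" and not self.alts:
            raise ValueError("hom_alt site without an alt allele")


def _classify_gt(gt: tuple[int | None, ...]) -> GenotypeClass | None:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return None
    if all(a == 0 for a in alleles):
        return "hom_ref"
    if len(set(alleles)) == 1:
        return "hom_alt"   # two identical non-reference alleles
    return "het"           # mixed, including two different alts (e.g. 1/2)


def load_variants(path: str | Path) -> list[VariantSite]:
    """Parse a single-sample VCF into variant sites with genotype classes.

    Records without a genotype call are skipped (and counted in the log);
    multi-sample files are rejected.
    """
    sites: list[VariantSite] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"expected a single-sample VCF, found {len(samples)} samples")
        sample = samples[0]
        for rec in vcf:
            gt = rec.samples[sample].get("GT")
            if gt is None or all(a is None for a in gt):
                n_skipped += 1
                continue
            cls = _classify_gt(tuple(gt))
            if cls is None:
                n_skipped += 1
                continue
            dp = rec.samples[sample].get("DP")
            sites.append(VariantSite(rec.chrom, rec.start, rec.ref,
                                     tuple(rec.alts or ()), cls,
                                     depth=dp))
    if n_skipped:
        logger.info("load_variants: %d sites without genotype skipped", n_skipped)
    return sites


def call_homozygous_sites(path: str | Path, fasta_path: str | Path,
                          min_depth: int = 8, min_alt_fraction: float = 0.9,
                          min_baseq: int = 13) -> list[VariantSite]:
    """Minimal counting caller for homozygous substitutions.

    Accumulates per-position base counts from primary mapped reads (bases
    below ``min_baseq`` ignored), then calls a site hom_alt when depth >=
    ``min_depth`` and the most frequent non-reference base accounts for at
    least ``min_alt_fraction`` of the unambiguous depth.  Only aligned-match
    cigar segments contribute (no indel calling).
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    counts: dict[str, np.ndarray] = {}
    pos_buf: dict[str, list[np.ndarray]] = {}
    base_buf: dict[str, list[np.ndarray]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            seq = rec.query_sequence
            quals = rec.query_qualities
            if seq is None:
                continue
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            codes = np.full(len(arr), -1, dtype=np.int8)
            for b, i in _BASE_INDEX.items():
                codes[arr == b] = i
            ok = codes >= 0
            if quals is not None:
                ok &= np.asarray(quals, dtype=np.int16) >= min_baseq
            # reference positions of each query base for match segments
            pairs = rec.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos = np.fromiter((q for q, _ in pairs), dtype=np.int64, count=len(pairs))
            rpos = np.fromiter((r for _, r in pairs), dtype=np.int64, count=len(pairs))
            keep = ok[qpos]
            pos_buf.setdefault(chrom, []).append(rpos[keep])
            base_buf.setdefault(chrom, []).append(codes[qpos[keep]].astype(np.int64))
    sites: list[VariantSite] = []
    for chrom in pos_buf:
        length = len(fa[chrom])
        mat = np.zeros((length, 4), dtype=np.int32)
        p = np.concatenate(pos_buf[chrom])
        b = np.concatenate(base_buf[chrom])
        np.add.at(mat, (p, b), 1)
        depth = mat.sum(axis=1)
        ref_seq = np.frombuffer(str(fa[chrom][:]).upper().encode(), dtype=np.uint8)
        ref_codes = np.full(length, -1, dtype=np.int8)
        for base, i in zip("ACGT", range(4)):
            ref_codes[ref_seq == ord(base)] = i
        candidate = depth >= min_depth
        idx = np.nonzero(candidate)[0]
        for pos in idx:
            rc = ref_codes[pos]
            row = mat[pos]
            alt_counts = row.copy()
            if rc >= 0:
                alt_counts[rc] = 0
            ai = int(np.argmax(alt_counts))
            if alt_counts[ai] == 0:
                continue
            frac = alt_counts[ai] / depth[pos]
            if frac >= min_alt_fraction:
                ref = _BASES[rc] if rc >= 0 else "N"
                sites.append(VariantSite(chrom, int(pos), ref, (_BASES[ai],),
                                         "hom_alt", depth=int(depth[pos]),
                                         alt_fraction=float(frac)))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def homozygous_regions(sites: Sequence[VariantSite], layout: GenomeLayout,
                       flank: int = 100) -> IntervalSet:
    """Expand hom_alt sites by ``flank`` bases each side and merge.

    The flank extends around the variant's full reference footprint
    (``[pos - flank, pos + len(ref) + flank)``), clipped at chromosome
    bounds.  Non-hom_alt sites in the input are ignored.
    """
    records = []
    for s in sites:
        if s.genotype != "hom_alt":
            continue
        length = layout.length(s.chrom)
        start = max(0, s.pos - flank)
        end = min(length, s.pos + len(s.ref) + flank)
        records.append((s.chrom, start, end))
    return merge_intervals(IntervalSet.from_records(records))
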