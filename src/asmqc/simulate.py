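"""Synthetic sample genome, corrupted assembly and projected read alignments.

The simulator exists so every detector can be exercised end-to-end with a
known answer.  It builds a random sample genome, derives an "assembly" from
it by planting misassemblies of six kinds, simulates paired-end fragments
from the sample, and *projects* each read into assembly coordinates through
the corruption's coordinate map (no aligner is run).  Each misassembly kind
produces the alignment signature a real aligner would show:

* ``collapsed_duplication`` — the sample carries two diverged copies, the
  assembly one: depth doubles over the kept copy and reads from the second
  copy plant paralog alleles.
* ``false_tandem_duplication`` — one sample copy appears twice in the
  assembly: reads inside the copies are ambiguous (mapq 0) and are split
  between them, halving usable coverage.
* ``inversion`` — pairs straddling a breakpoint lose FR orientation.
* ``assembly_deletion`` — the assembly carries extra sequence the sample
  lacks; spanning pairs project ~insert+L apart (large inserts).  (The kind
  is named from the sample's point of view, as in SV calling.)
* ``assembly_insertion`` — the assembly lacks sequence the sample carries;
  spanning pairs project ~insert−L apart (small inserts).
* ``substitution_error`` — the assembly's bases are wrong along a tract:
  every read disagrees, yielding homozygous non-reference calls.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .intervals import GenomeLayout, IntervalSet, merge_intervals, intersect

__all__ = [
    "SimConfig",
    "MisassemblySpec",
    "CorruptedAssembly",
    "make_sample_genome",
    "corrupt_assembly",
    "simulate_pairs",
    "project_alignments",
    "evaluate",
    "evaluate_expected",
    "default_scenario",
    "write_fasta",
    "EXPECTED_EVIDENCE",
]

KINDS = ("collapsed_duplication", "false_tandem_duplication", "inversion",
         "assembly_deletion", "assembly_insertion", "substitution_error")

#: evidence track expected to recover each planted kind
EXPECTED_EVIDENCE: dict[str, tuple[str, ...]] = {
    "collapsed_duplication": ("HIGH_COV",),
    "false_tandem_duplication": ("LOW_COV", "MULTIMAP"),
    "inversion": ("IMPROPER_PAIR",),
    "assembly_deletion": ("LARGE_INSERT",),
    "assembly_insertion": ("SMALL_INSERT",),
    "substitution_error": ("HOM_VARIANT",),
}

_CODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGT", b"TGCA"):
    _COMP[a] = b


@dataclass
class SimConfig:
    """Simulation parameters; the defaults describe a 40x paired-end library
    with a 427 +/- 80 bp insert distribution on a 500 kb single-chromosome
    genome."""

    seed: int = 42
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 500_000})
    gc: float = 0.42
    gc_profile: list[tuple[str, int, int, float]] = field(default_factory=list)
    depth: float = 40.0
    insert_mean: float = 427.0
    insert_sd: float = 80.0
    read_length: int = 100
    error_rate: float = 0.001
    base_quality: int = 30
    # optional GC-dependent library efficiency: list of (gc_fraction, relative
    # efficiency) control points, linearly interpolated; None = uniform
    gc_response: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.insert_mean <= 2 * self.read_length:
            raise ValueError("insert mean must exceed twice the read length")
        for _, n in self.chrom_lengths.items():
            if n <= 0:
                raise ValueError("chromosome lengths must be positive")


@dataclass(frozen=True)
class MisassemblySpec:
    kind: str
    chrom: str
    position: int
    length: int
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown misassembly kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not (0.0 <= self.divergence <= 0.1):
            raise ValueError("divergence must lie in [0, 0.1]")

    @property
    def sample_footprint(self) -> tuple[int, int]:
        """Sample-coordinate span consumed by this event (a collapse also
        claims the second copy's territory)."""
        if self.kind == "collapsed_duplication":
            return self.position, self.position + 2 * self.length
        if self.kind == "assembly_deletion":
            return self.position, self.position  # inserts into the assembly only
        return self.position, self.position + self.length


@dataclass(frozen=True)
class Segment:
    """A sample->assembly coordinate-map segment (strand -1 = inverted)."""

    sample_start: int
    sample_end: int
    asm_start: int
    strand: int = 1

    @property
    def asm_end(self) -> int:
        return self.asm_start + (self.sample_end - self.sample_start)


@dataclass(frozen=True)
class MmGroup:
    """A false-tandem-duplication registry entry: the sample copy and the two
    assembly copy start coordinates reads are split between."""

    sample_start: int
    sample_end: int
    copy_starts: tuple[int, int]


@dataclass
class CorruptedAssembly:
    sample: dict[str, np.ndarray]
    assembly: dict[str, np.ndarray]
    truth: dict[str, IntervalSet]
    segments: dict[str, list[Segment]]
    mm_groups: dict[str, list[MmGroup]]

    @property
    def sample_layout(self) -> GenomeLayout:
        return GenomeLayout({c: len(s) for c, s in self.sample.items()})

    @property
    def assembly_layout(self) -> GenomeLayout:
        return GenomeLayout({c: len(s) for c, s in self.assembly.items()})


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _CODE[rng.choice(4, size=n, p=p)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases at the given rate (always to a different base)."""
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hit:
        choices = _CODE[_CODE != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def _revcomp(seq: np.ndarray) -> np.ndarray:
    return _COMP[seq[::-1]]


def seq_to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


def write_fasta(genome: Mapping[str, np.ndarray], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            s = seq_to_str(seq)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def make_sample_genome(config: SimConfig) -> tuple[dict[str, np.ndarray], GenomeLayout]:
    """Random genome with controllable regional GC, deterministic under seed."""
    rng = np.random.default_rng([config.seed, 0])
    genome = {}
    for chrom, length in config.chrom_lengths.items():
        genome[chrom] = _random_seq(rng, length, config.gc)
    for chrom, start, end, gc in config.gc_profile:
        genome[chrom][start:end] = _random_seq(rng, end - start, gc)
    return genome, GenomeLayout({c: len(s) for c, s in genome.items()})


def corrupt_assembly(sample: Mapping[str, np.ndarray],
                     specs: Sequence[MisassemblySpec],
                     seed: int = 0) -> CorruptedAssembly:
    """Derive a corrupted assembly and its truth tracks from a sample genome.

    For ``collapsed_duplication`` the *sample* is first rewritten: the
    segment at ``[position+length, position+2*length)`` becomes a diverged
    copy of ``[position, position+length)``, so the returned sample genuinely
    carries two near-identical copies while the assembly keeps one.  Reads
    must therefore be simulated from the returned sample, not the input.
    Truth BEDs are in assembly coordinates.
    """
    rng = np.random.default_rng([seed, 1])
    sample = {c: s.copy() for c, s in sample.items()}
    assembly: dict[str, np.ndarray] = {}
    segments: dict[str, list[Segment]] = {}
    mm_groups: dict[str, list[MmGroup]] = {}
    truth_records: dict[str, list[tuple[str, int, int]]] = {k: [] for k in KINDS}

    by_chrom: dict[str, list[MisassemblySpec]] = {}
    for spec in specs:
        by_chrom.setdefault(spec.chrom, []).append(spec)

    for chrom, seq in sample.items():
        events = sorted(by_chrom.get(chrom, []), key=lambda s: s.position)
        # validate footprints: within bounds and non-overlapping
        prev_end = 0
        for spec in events:
            fs, fe = spec.sample_footprint
            fe = max(fe, fs + 1)
            if fs < prev_end:
                raise ValueError(f"overlapping misassembly specs on {chrom} at {fs}")
            if fe > len(seq) or spec.position >= len(seq):
                raise ValueError(f"misassembly spec exceeds {chrom} bounds")
            prev_end = fe
        chrom_gc = float(((seq == ord("G")) | (seq == ord("C"))).mean())
        parts: list[np.ndarray] = []
        segs: list[Segment] = []
        groups: list[MmGroup] = []
        cur_s = 0
        cur_a = 0

        def flank_to(p: int):
            nonlocal cur_s, cur_a
            if p > cur_s:
                parts.append(seq[cur_s:p])
                segs.append(Segment(cur_s, p, cur_a, 1))
                cur_a += p - cur_s
                cur_s = p

        for spec in events:
            p, L = spec.position, spec.length
            flank_to(p)
            if spec.kind == "collapsed_duplication":
                copy_a = seq[p:p + L].copy()
                seq[p + L:p + 2 * L] = _mutate(copy_a, spec.divergence, rng)
                parts.append(copy_a)
                segs.append(Segment(p, p + L, cur_a, 1))
                segs.append(Segment(p + L, p + 2 * L, cur_a, 1))  # aliased copy
                truth_records["collapsed_duplication"].append((chrom, cur_a, cur_a + L))
                cur_s, cur_a = p + 2 * L, cur_a + L
            elif spec.kind == "false_tandem_duplication":
                copy = seq[p:p + L]
                parts.append(copy)
                parts.append(copy.copy())
                segs.append(Segment(p, p + L, cur_a, 1))
                groups.append(MmGroup(p, p + L, (cur_a, cur_a + L)))
                truth_records["false_tandem_duplication"].append((chrom, cur_a, cur_a + 2 * L))
                cur_s, cur_a = p + L, cur_a + 2 * L
            elif spec.kind == "inversion":
                parts.append(_revcomp(seq[p:p + L]))
                segs.append(Segment(p, p + L, cur_a, -1))
                truth_records["inversion"].append((chrom, cur_a, cur_a + L))
                cur_s, cur_a = p + L, cur_a + L
            elif spec.kind == "assembly_deletion":
                # assembly carries L extra bases the sample lacks
                parts.append(_random_seq(rng, L, chrom_gc))
                truth_records["assembly_deletion"].append((chrom, cur_a, cur_a + L))
                cur_a += L
            elif spec.kind == "assembly_insertion":
                # assembly lacks L sample bases; truth marks the breakpoint
                truth_records["assembly_insertion"].append(
                    (chrom, max(0, cur_a - L // 2), cur_a + (L - L // 2)))
                cur_s = p + L
            elif spec.kind == "substitution_error":
                rate = spec.divergence if spec.divergence > 0 else 0.02
                parts.append(_mutate(seq[p:p + L], rate, rng))
                segs.append(Segment(p, p + L, cur_a, 1))
                truth_records["substitution_error"].append((chrom, cur_a, cur_a + L))
                cur_s, cur_a = p + L, cur_a + L
        flank_to(len(seq))
        assembly[chrom] = (np.concatenate(parts) if parts
                           else np.empty(0, dtype=np.uint8))
        segments[chrom] = segs
        mm_groups[chrom] = groups

    # clip truth at assembly bounds and build interval sets
    truth: dict[str, IntervalSet] = {}
    for kind, recs in truth_records.items():
        clipped = [(c, s, min(e, len(assembly[c]))) for c, s, e in recs
                   if s < len(assembly[c])]
        truth[kind] = IntervalSet.from_records(clipped)
    return CorruptedAssembly(sample, assembly, truth, segments, mm_groups)


@dataclass
class Fragments:
    """Simulated fragment coordinates on the sample genome."""

    starts: dict[str, np.ndarray]
    lengths: dict[str, np.ndarray]

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.starts.values())


def simulate_pairs(sample: Mapping[str, np.ndarray], config: SimConfig) -> Fragments:
    """Draw fragments uniformly over the sample genome.

    Fragment length ~ Normal(insert_mean, insert_sd) truncated at twice the
    read length; the count is chosen so expected per-base fragment depth
    matches ``config.depth``.  When ``gc_response`` is set, each fragment is
    kept with probability equal to the interpolated efficiency at its GC
    fraction (emulating PCR GC bias).
    """
    rng = np.random.default_rng([config.seed, 2])
    starts, lengths = {}, {}
    min_len = 2 * config.read_length
    for chrom, seq in sample.items():
        length = len(seq)
        n = int(round(config.depth * length / config.insert_mean))
        flen = rng.normal(config.insert_mean, config.insert_sd, size=n)
        flen = np.clip(np.rint(flen), min_len, length).astype(np.int64)
        s = rng.integers(0, length - flen + 1)
        if config.gc_response is not None:
            is_gc = ((seq == ord("G")) | (seq == ord("C"))).astype(np.int64)
            csum = np.concatenate([[0], np.cumsum(is_gc)])
            frac = (csum[s + flen] - csum[s]) / flen
            xs, ys = zip(*sorted(config.gc_response))
            keep = rng.random(n) < np.interp(frac, xs, ys)
            s, flen = s[keep], flen[keep]
        order = np.argsort(s, kind="stable")
        starts[chrom] = s[order]
        lengths[chrom] = flen[order]
    return Fragments(starts, lengths)


@dataclass
class ProjectionCounts:
    """Mass accounting for a projection run: every simulated pair is either
    projected or dropped, and multimapped reads are tallied."""

    n_pairs: int = 0
    n_projected: int = 0
    n_dropped_pairs: int = 0
    n_multimap_reads: int = 0


def _locate(seg_starts: np.ndarray, segs: list[Segment], mid: int) -> Segment | None:
    i = int(np.searchsorted(seg_starts, mid, side="right")) - 1
    if i < 0:
        return None
    seg = segs[i]
    return seg if mid < seg.sample_end else None


def project_alignments(fragments: Fragments, corruption: CorruptedAssembly,
                       config: SimConfig, out_path: str | Path) -> ProjectionCounts:
    """Project simulated pairs into assembly coordinates and write a sorted SAM.

    Each mate is placed by the coordinate-map segment containing the majority
    of its bases (its midpoint); a mate whose midpoint falls in sequence
    absent from the assembly makes the whole pair unmappable (dropped and
    counted).  Mates wholly inside a false-tandem copy are assigned to one of
    the two assembly copies (one draw per pair, mapq 0); pairs straddling an
    inversion breakpoint lose the proper-pair flag.
    """
    rng = np.random.default_rng([config.seed, 3])
    rl = config.read_length
    layout = corruption.assembly_layout
    counts = ProjectionCounts()
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in layout.items()],
    }
    qual = pysam.qualitystring_to_array(chr(config.base_quality + 33) * rl)
    records: list[tuple[int, int, object]] = []
    af = pysam.AlignmentFile(str(out_path), "wh", header=dict(header))
    tid = {c: i for i, (c, _) in enumerate(layout.items())}
    try:
        for chrom in fragments.starts:
            sample_seq = corruption.sample[chrom]
            segs = corruption.segments[chrom]
            seg_starts = np.array([s.sample_start for s in segs], dtype=np.int64)
            groups = corruption.mm_groups[chrom]
            chrom_len = layout.length(chrom)
            t = tid[chrom]
            for s, flen in zip(fragments.starts[chrom], fragments.lengths[chrom]):
                counts.n_pairs += 1
                mate_s = (int(s), int(s + flen - rl))  # forward-coordinate starts
                # one copy draw per pair keeps wholly-inside pairs concordant
                copy_draw = int(rng.integers(2))
                err_draw = [rng.random(rl) < config.error_rate for _ in range(2)]
                placed = []
                for mi in (0, 1):
                    sm = mate_s[mi]
                    group = next((g for g in groups
                                  if sm >= g.sample_start and sm + rl <= g.sample_end),
                                 None)
                    if group is not None:
                        pos = group.copy_starts[copy_draw] + (sm - group.sample_start)
                        placed.append((pos, 1, 0, None))   # (pos, strand, mapq, group)
                        continue
                    seg = _locate(seg_starts, segs, sm + rl // 2)
                    if seg is None:
                        placed.append(None)
                        continue
                    if seg.strand == 1:
                        pos = seg.asm_start + (sm - seg.sample_start)
                    else:
                        pos = seg.asm_start + (seg.sample_end - (sm + rl))
                    pos = int(np.clip(pos, 0, chrom_len - rl))
                    placed.append((pos, seg.strand, 60, None))
                if placed[0] is None or placed[1] is None:
                    counts.n_dropped_pairs += 1
                    continue
                # orientation: mate 0 is sequenced forward, mate 1 reverse;
                # an inverted segment flips the contained mate
                rec_info = []
                for mi in (0, 1):
                    pos, strand, mapq, _ = placed[mi]
                    reverse = (mi == 0) == (strand == -1)
                    seq = sample_seq[mate_s[mi]:mate_s[mi] + rl].copy()
                    err = err_draw[mi]
                    for i in np.nonzero(err)[0]:
                        choices = _CODE[_CODE != seq[i]]
                        seq[i] = choices[rng.integers(len(choices))]
                    if strand == -1:
                        seq = _revcomp(seq)
                    rec_info.append((pos, reverse, mapq, seq))
                    if mapq == 0:
                        counts.n_multimap_reads += 1
                (p0, r0, q0, s0), (p1, r1, q1, s1) = rec_info
                left, right = (0, 1) if (p0, r0) <= (p1, r1) else (1, 0)
                lpos = rec_info[left][0]
                rend = rec_info[right][0] + rl
                span = rend - lpos
                proper = (not rec_info[left][1]) and rec_info[right][1]
                for mi in (0, 1):
                    pos, reverse, mapq, seq = rec_info[mi]
                    opos, oreverse = rec_info[1 - mi][0], rec_info[1 - mi][1]
                    a = pysam.AlignedSegment()
                    a.query_name = f"frag_{chrom}_{counts.n_pairs}"
                    a.query_sequence = seq_to_str(seq)
                    a.reference_id = t
                    a.reference_start = pos
                    a.mapping_quality = mapq
                    a.cigartuples = [(0, rl)]
                    a.next_reference_id = t
                    a.next_reference_start = opos
                    a.template_length = span if mi == left else -span
                    a.query_qualities = qual
                    a.is_paired = True
                    a.is_proper_pair = proper
                    a.is_reverse = reverse
                    a.mate_is_reverse = oreverse
                    a.is_read1 = mi == 0
                    a.is_read2 = mi == 1
                    records.append((t, pos, a))
                counts.n_projected += 1
        records.sort(key=lambda r: (r[0], r[1]))
        for _, _, a in records:
            af.write(a)
    finally:
        af.close()
    return counts


def evaluate(flagged: Mapping[str, IntervalSet],
             truth: Mapping[str, IntervalSet]):
    """Base-level precision/recall of every evidence track against every
    planted kind.  Precision is reported as 1.0 when nothing was flagged
    (with the flagged base count alongside)."""
    import pandas as pd

    rows = []
    for kind, t in truth.items():
        t_merged = merge_intervals(t)
        for track, f in flagged.items():
            f_merged = merge_intervals(f)
            _, tp = intersect(f_merged, t_merged)
            fb, tb = f_merged.total_bases, t_merged.total_bases
            rows.append({
                "kind": kind, "track": track,
                "flagged_bases": fb, "truth_bases": tb, "tp_bases": tp,
                "precision": tp / fb if fb else 1.0,
                "recall": tp / tb if tb else 0.0,
            })
    return pd.DataFrame(rows)


def evaluate_expected(flagged: Mapping[str, IntervalSet],
                      truth: Mapping[str, IntervalSet]) -> dict[str, float]:
    """Recall of each planted kind by its expected evidence track(s)
    (tracks are unioned when a kind has more than one, e.g. LC + multimap
    for false tandem duplications)."""
    out = {}
    for kind, tracks in EXPECTED_EVIDENCE.items():
        if kind not in truth or truth[kind].n_features == 0:
            continue
        records = []
        for tr in tracks:
            if tr in flagged:
                records.extend((iv.chrom, iv.start, iv.end) for iv in flagged[tr])
        union = merge_intervals(IntervalSet.from_records(records))
        t_merged = merge_intervals(truth[kind])
        _, tp = intersect(union, t_merged)
        out[kind] = tp / t_merged.total_bases if t_merged.total_bases else 0.0
    return out


def default_scenario(seed: int = 42) -> tuple[SimConfig, list[MisassemblySpec]]:
    """The default end-to-end scenario: one 500 kb chromosome, 40x depth,
    one planted event of each kind.

    Event sizes follow each signature's physical reach.  Copy-number events
    (collapse, false tandem duplication, substitution tract) are 3-5 kb:
    their evidence covers the whole event.  Breakpoint-limited evidence
    restricts the others: abnormal pairs only straddle junctions, reaching
    about one insert length (plus a window) inward, so the inversion is
    1.5 kb and the indel events 300 bp — sizes at which their designated
    tracks can cover the truth interval.
    """
    config = SimConfig(seed=seed)
    specs = [
        MisassemblySpec("collapsed_duplication", "chr1", 50_000, 5_000, divergence=0.02),
        MisassemblySpec("false_tandem_duplication", "chr1", 150_000, 4_000),
        MisassemblySpec("inversion", "chr1", 250_000, 1_500),
        MisassemblySpec("assembly_deletion", "chr1", 330_000, 300),
        MisassemblySpec("assembly_insertion", "chr1", 380_000, 300),
        MisassemblySpec("substitution_error", "chr1", 430_000, 3_000, divergence=0.02),
    ]
    return config, specs
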