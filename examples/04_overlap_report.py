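"""Annotation overlap reporting: how much of a call set falls in flagged
regions.

Given LQ/LC/LQLC tracks, an annotation (variant calls, CNVRs, gene models)
is scored either by feature count (>= 1 bp overlap per feature) or by
overlapping bases, with percentages of its total — the shape of the
standard summary tables of this protocol.
"""

import numpy as np

from asmqc.intervals import IntervalSet
from asmqc.regions import build_lqlc, overlap_report, summarize
from asmqc.intervals import GenomeLayout

rng = np.random.default_rng(42)
layout = GenomeLayout({"chr1": 100_000})

lq = IntervalSet({"chr1": [(s, s + 2_000) for s in range(10_000, 30_000, 5_000)]})
lc = IntervalSet({"chr1": [(s, s + 3_000) for s in range(25_000, 60_000, 10_000)]})
lqlc = build_lqlc(lq, lc)

for name, track in (("LQ", lq), ("LC", lc), ("LQLC", lqlc)):
    s = summarize(track, layout)
    print(f"{name:4s}: {s.n_features} features, mean {s.mean_size:.0f} bp, "
          f"{s.pct_genome:.2f}% of genome")

# point variants scattered uniformly: expect ~pct_genome of them flagged
variants = IntervalSet({"chr1": np.column_stack([p := rng.integers(0, 99_999, 2_000),
                                                 p + 1])})
rep = overlap_report("variants", variants, lq, lc, lqlc, "feature_count")
print(f"\n{rep.name}: {rep.total} total; "
      f"{rep.in_lq} ({rep.pct_lq:.1f}%) in LQ, "
      f"{rep.in_lc} ({rep.pct_lc:.1f}%) in LC, "
      f"{rep.in_lqlc} ({rep.pct_lqlc:.1f}%) in LQLC")
print("An excess over the genome percentages would indicate the call set is "
      "enriched in unreliable territory.")
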