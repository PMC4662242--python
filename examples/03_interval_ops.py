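"""Interval algebra underneath the pipeline: windows, merge, intersect.

All coordinates are 0-based half-open (BED convention); merging fuses
bookended intervals, and intersection counts any >= 1 bp overlap.
"""

from asmqc.intervals import (GenomeLayout, IntervalSet, intersect,
                             make_windows, merge_intervals, remove_gap_windows)

layout = GenomeLayout({"chr1": 5_000})

windows = make_windows(layout, width=1000, step=800)
print("1000 bp windows with 200 bp overlap on a 5 kb chromosome:")
print(" ", [(int(s), int(e)) for s, e in windows.by_chrom("chr1")])

gaps = IntervalSet({"chr1": [(1999, 2001)]})
kept = remove_gap_windows(windows, gaps)
print(f"after dropping windows touching the gap at [1999,2001): "
      f"{kept.n_features} of {windows.n_features} windows remain")

evidence = IntervalSet({"chr1": [(0, 1000), (900, 1800), (1800, 2200), (4000, 4500)]})
merged = merge_intervals(evidence)
print("\nmerging evidence regions (overlapping and bookended fuse):")
print(" ", [(int(s), int(e)) for s, e in merged.by_chrom("chr1")],
      f"({merged.total_bases} bases)")

annotation = IntervalSet({"chr1": [(100, 110), (2195, 2205), (3000, 3010)]})
feats, bases = intersect(annotation, merged)
print(f"\nof {annotation.n_features} annotation features, {feats.n_features} "
      f"overlap the merged regions ({bases} overlapping bases)")
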