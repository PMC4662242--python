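# Methods

This note records the models, parameter choices and numerical conventions
behind `asmqc`, and what the synthetic validation does and does not
establish.

## Rationale

When the individual whose DNA produced a draft assembly is resequenced and
the reads are mapped back to that assembly, every locus should look like a
well-behaved resequencing experiment against a correct reference:
coverage near the library mean after GC correction, template lengths from
the library's insert distribution, FR-oriented proper pairs, and — because
the assembly carries one of the individual's own haplotypes — no
homozygous non-reference variants. Misassemblies violate these in
characteristic ways:

| assembly error | signature |
|---|---|
| collapsed duplication (two sample copies, one assembly copy) | ~2× coverage; paralog sequence variants called as hom/het sites |
| false tandem duplication (one sample copy, two assembly copies) | reads split between copies: low coverage, mapq-0 multimappers |
| inversion / misoriented contig | pairs straddling breakpoints lose FR orientation |
| assembly carries extra sequence (sample deletion) | spanning pairs ~insert + L apart (large inserts) |
| assembly lacks sample sequence (sample insertion) | spanning pairs ~insert − L apart (small inserts) |
| wrong bases along a tract | every read disagrees → homozygous calls |

The pipeline measures each signature on windows and flags outliers;
because each evidence class is two-or-more SD from its own genome-wide
distribution, a few percent of windows are flagged even on a perfect
assembly — the tracks are screening evidence, strict by design.

## Models and estimators

**Fragment coverage.** Pairs with both mates mapped, properly paired and
mapq ≥ 2 (both mates) contribute one interval from leftmost mate start to
rightmost mate end. Per-base depth of these intervals is summarised as the
median over each 1 kb non-overlapping, gap-free window. The median (not
the mean) keeps collapsed-repeat windows from dragging estimates.

**GC normalisation.** Windows are binned by integer GC percentage
(ambiguous bases excluded from the denominator; windows with no
unambiguous bases are excluded from normalisation). Each usable bin's
coverage is rescaled by `f = global_median / bin_median`, which makes the
per-bin median equal the global median exactly — a fixed point the test
suite checks on a GC-biased simulation. Bins with fewer than 50 windows or
a zero median get `f = 1`: the ratio is noise-dominated there, and
applying no correction is safer than a wild one. The floor is
configurable.

**Robust normal fit.** The `norm_cov` distribution has a heavy right tail,
so the mean/SD are estimated by least-squares fitting a Gaussian to the
histogram (unit-width bins) of a central range: first pass over the
5th–95th percentile range, then a refit restricted to mean ± 3·SD of the
first pass. This is deterministic, converges in two passes, and on
samples with up to 5 % right-tail contamination recovers (μ, σ) within
5 % for μ ∈ {20, 41, 80}, σ ∈ {3, 7, 15} (tested). Cutoffs are
mean ± k·SD with k = 2; classification is strict (a value equal to a
cutoff is NORMAL).

**Insert-size model.** Mean/SD of |TLEN| over proper FR pairs (each pair
counted once via its positive-TLEN mate), after discarding values above
10× the median — a deterministic stand-in for the version-dependent
trimming of the usual metrics tools; chimeric templates otherwise dominate
the second moment. Small/large cutoffs are mean ∓ 2·SD, symmetric by
construction.

**Window fractions.** On 1 kb windows stepped by 800 bp (consecutive
windows share 200 bp), a read counts toward a window if its aligned span
overlaps it by ≥ 1 bp; denominators come from the *unfiltered* alignment
set. Thresholds are plain mean ± 2·SD of the window percentages over
non-empty windows — empty windows are reported with 0 % but excluded from
fitting so unsequenced territory does not deflate the mean — and windows
with no reads are never flagged.

**Homozygous variants.** A site is hom_alt when the genotype call carries
two identical non-reference alleles (VCF route), or, in the internal
counting caller, when depth ≥ 8 and the leading non-reference base
reaches ≥ 90 % of bases with quality ≥ 13. The caller is intentionally
minimal (substitutions only, match-cigar segments only): it exists so the
synthetic pipeline runs without external callers, not to replace one.
Each hom_alt site is expanded across its full reference footprint plus
100 bp on each side (a SNV yields a 201 bp region), clipped at chromosome
ends, and merged.

**Multimapper attribution.** Windows where > 50 % of overlapping reads
have mapq 0 (the aligner convention for equal-best placements) are
tracked separately: these explain low-coverage territory caused by the
mapq filter rather than by the assembly, and the attribution report gives
the overlap fractions between multimapper regions and LC plus median
per-window read counts inside and outside.

**Region assembly.** LQ = merge(HIGH_COV ∪ SMALL_INSERT ∪ LARGE_INSERT ∪
IMPROPER_PAIR ∪ HOM_VARIANT); LC = merge(LOW windows); LQLC =
merge(LQ ∪ LC). LOW_COV and MULTIMAP never enter LQ. Merging fuses
bookended intervals (distance 0); all coordinates are 0-based half-open,
in BED. Excluded chromosomes (e.g. chrY for a female individual) are a
config list applied uniformly to layout, reads and reports.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| window width / coverage step | 1000 / 1000 bp | non-overlapping coverage windows |
| pair-metric step | 800 bp | 200 bp overlap between fraction windows |
| mapq floor | 2 | coverage-chain read filter |
| k | 2 | SD multiplier for every cutoff |
| GC bin floor | 50 windows | below this, f = 1 |
| multimapper window | > 50 % mapq-0 reads | attribution track |
| variant flank | 100 bp | hom-site expansion each side |
| caller depth / alt fraction / baseq | 8 / 0.9 / 13 | internal caller only |

Overlapping fraction windows use width 1000 with step 800, so
consecutive windows share 200 bp; a step of 200 (80 % overlap) is a
defensible alternative reading of the protocol and is configurable.

## The simulator: stated world and limits

Defaults: one 500 kb chromosome at uniform GC 0.42, 40× fragment depth,
insert 427 ± 80 bp, 100 bp reads, base error 0.001 at constant Q30,
seed 42. One event of each kind is planted: collapse 5 kb at 2 %
divergence, false tandem duplication 4 kb, inversion 1.5 kb, indels
300 bp, substitution tract 3 kb at 2 %. Sizes follow each signature's
physical reach: copy-number signatures cover their whole event, but
insert/orientation evidence lives within ~1 insert length of a
breakpoint (and the inside mates of straddling pairs map near the
*opposite* inversion breakpoint), so multi-kb inversions/indels cannot be
*covered* — only bracketed — by those tracks; 1.5 kb and 300 bp are the
scales at which base-level recall of the truth interval is attainable.

Alignment is coordinate projection, not a real aligner: each mate is
placed by the map segment containing its midpoint (majority of bases);
reads whose midpoint falls in sequence absent from the assembly drop the
whole pair (counted); soft-clipping, indel cigars, base-quality
variation, PCR duplicates and chimeras are not modelled. Reads wholly
inside a false-tandem copy are assigned to one of the two assembly
copies — one draw per pair, so concordant pairs stay concordant; pairs
with one mate outside keep template geometry relative to the first copy.
A green synthetic test therefore establishes that the *detectors*
respond correctly to the planted signatures, not that a particular real
aligner produces those signatures; collapse divergence sites, for
instance, surface as ~50/50 mixed (het-like) calls, which the hom_alt
filter deliberately does not count — the collapse is caught by coverage,
the wrong-base tract by hom calls.

For the collapse, the simulator rewrites the *sample* genome (planting
the second diverged copy) before deriving the assembly, since a random
genome cannot already contain two near-identical copies; reads are
simulated from the returned sample. GC bias is emulated by thinning
fragments with probability given by a piecewise-linear efficiency curve
over fragment GC.

## Numerical conventions and degenerate inputs

* Strict inequalities at every cutoff; values at a cutoff are normal.
* Merging at distance 0 with bookended fusion; any-overlap (≥ 1 bp)
  intersection and gap-window removal.
* Robust fit errors out below 100 values or on non-convergence; the GC
  model errors on an all-zero median library; the insert model on < 1000
  usable pairs or zero SD.
* Empty interval sets flow through every operation (empty in → empty
  out); precision over zero flagged bases is reported as 1.0 with the
  zero count alongside.
* Windows at chromosome ends are truncated; every base is covered by at
  least one window when step ≤ width (enforced).
* All randomness derives from a single seed through named substreams, so
  simulation, projection and the whole pipeline are byte-reproducible.

## Known limitations

* The internal caller handles substitutions only; indel variants reach
  the pipeline via the VCF route.
* Orientation classes (FF/RR/RF) are not decomposed and discordant pairs
  are not clustered into SV calls; this is window screening, not SV
  calling.
* Mappability is observed (mapq-0 fraction), not modelled from k-mer
  uniqueness; loess-style GC correction is out of scope.
* Genome-scale percentages from full-scale runs of this protocol
  (hundreds of millions of reads on multi-Gb genomes) are not
  reproducible at desk scale; the tests reproduce the reference
  threshold and reporting arithmetic exactly and validate the detectors
  on the synthetic world instead.
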