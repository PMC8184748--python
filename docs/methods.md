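# Methods

## The problem

Targeted proximity-ligation sequencing of FFPE tissue (FFPE-TLC) detects
chromosomal rearrangements of selected target genes (e.g. *MYC*, *BCL2*,
*BCL6* in lymphoma) without relying on fusion-spanning reads: a
rearrangement places the partner locus in spatial proximity to the probed
target, so ligation products accumulate over megabases flanking the
breakpoint. The caller's task is to find, per sample and target
("viewpoint"), the genomic regions with significantly elevated clustering of
ligation products, while rejecting the considerable topological and
methodological noise of degraded FFPE libraries.

## The statistic

Reads are split-aligned; fragments with mapping quality above zero are kept;
a read is assigned to the viewpoint with the largest summed fragment overlap
and discarded if it overlaps none. The reference is digested in silico at
the restriction motif (NlaIII, CATG), and coverage is reduced to restriction
segments: a segment is covered if at least one fragment of at least one read
overlaps it, with per-read deduplication (several fragments of one read on
one segment count once).

For each interval width *w* (scales 5 kb and 75 kb by default), every bin
gets a **proximity frequency** f = number of covered segments whose start
lies in the bin. Gaussian smoothing along each chromosome (sigma = 0.75 bin
units, kernel span 31 bins, truncated and renormalized — also over the
available support at chromosome edges) yields the **proximity score** p.

Two permutation nulls (1000 permutations each) give a per-bin expectation
and spread:

* **shuffle** — f values permuted among all eligible bins genome-wide, then
  smoothed per chromosome;
* **swap** — only nonzero f values permuted among the positions that had
  nonzero f. In sparse libraries the shuffle null underestimates the
  expectation (most bins are empty), so z-scores computed from it explode;
  the swap null restores calibration there.

The final per-bin z is the **minimum** of the two null z-scores, with a
standard-deviation floor of 1e-6 (floored bins are flagged).

On the viewpoint's own chromosome the distance decay of contact frequency
dominates. The probed envelope ± 250 kb is masked; each flank (probed edge
to chromosome end) is smoothed and fitted by isotonic regression constrained
non-increasing with distance from the probed region; the residual
(smoothed − fit) replaces p. The same residual statistic is applied to every
permutation of the null, so observed and expected are on one scale. Bins
within ± 3 Mb of the viewpoint are never called (true 3D proximity, not
rearrangement).

Bins with z > 5.0 are merged when gaps are below 1 Mb; a merged region's
integrated z is the 90th percentile (linear interpolation) of its member-bin
z. Regions are grouped across scales within 10 Mb, and a group is emitted
only if **every** configured scale contributes (both 5 kb and 75 kb z must
exceed 5.0). The largest scale's integrated z is the **enrichment score**;
if several largest-scale members fall in one group, their maximum is taken
and the footprint is the union (flagged). Trans calls are significant at
enrichment ≥ 8.0; cis calls at > 16.0. Known covariates (GC, mappability,
restriction-site density) are deliberately not modeled; the eligible-pool
mask is the extension point for stratified permutation.

### Numerical choices

* Null moments accumulate with block-merged Welford updates, so degenerate
  pools (all values equal, single nonzero bin) give exactly zero variance.
* Permutations are drawn one at a time from a counter-based (Philox) stream
  keyed by (seed, scale, null type, domain), so results are reproducible and
  a naive loop oracle can replay the identical stream.
* Segment-to-bin assignment is by segment start; a segment counts in exactly
  one bin. Segment boundaries sit at the motif's first base (the motif
  belongs to the downstream segment); any consistent convention shifts
  results by at most the motif length.
* 0-based half-open coordinates throughout; BED-compatible output.

## Post-processing

Overlapping significant calls from ≥ 2 primary viewpoints in one sample are
reported as an amplification event; calls to the IGH area are exempt
(double/triple-hit rearrangements legitimately recur there). A per-viewpoint
blacklist removes recurrent off-target regions (shipped hg19 defaults:
IGL → chr9:131.5–132.5 Mb, IGK → chr22:22–24 Mb; other builds need
user-supplied coordinates). Butterfly matrices (2D contacts between the
target and partner windows, fragments binned by midpoint) support breakpoint
localization: the cut maximizing the absolute quadrant-density contrast
classifies the event as reciprocal (both complementary quadrants enriched),
one-sided, or none; matrices with fewer than 50 pairs are classified none.
Fusion reads are consecutive split-alignment pairs bridging the viewpoint
and the call footprint whose junction does not coincide with a restriction
site (± 1 bp, the signature of an ordinary ligation junction); ambiguous
junctions are dropped rather than auto-resolved — the final clinical
classification remains a reporting annotation.

## The synthetic-library generator

Controlled-access patient data are not required for verification: the
generator emits pre-aligned split reads with ground truth. Each read has one
anchor fragment in the probed envelope plus a Poisson number of ligated
fragments. Cis partners follow a truncated power-law contact decay
(d + d0)^(−gamma) of linear distance on the cell's derivative chromosome, so
in rearranged cells (a configurable fraction) the partner locus acquires
cis-like decay across the breakpoint; fragments spanning the derivative
junction are split, producing genuine fusion reads. Reciprocal, one-sided
and insertion events are supported. FFPE degradation is emulated by making a
random segment subset unobservable (sparsity), which exercises the swap-null
pathway.

Two features keep desk-scale libraries statistically representative of
genome-scale ones:

* **Windowing.** The mini-genome (default 50 Mb: two 10 Mb chromosomes
  hosting viewpoint and partner, four 7.5 Mb background chromosomes) is
  treated as a window of a virtual full-size genome (1 Gb for trans
  thinning; 125 Mb virtual chromosome for cis decay): ligations landing
  outside the window are generated but unobserved. Per-bin background
  coverage then matches a deeply sequenced genome-wide library rather than
  piling 1e6 reads onto 50 Mb. The genome must also be large enough that a
  planted partner's signal does not dominate its own permutation pool — on a
  much smaller genome the null sd becomes signal-contaminated and z-scores
  saturate regardless of signal strength, which is a property of the pool
  geometry, not of the method.
* **Off-target field.** Hybridization capture is not spatially uniform; real
  libraries show overdispersed background with occasional recurrent piles
  (the reason the swap null and the blacklists exist). Trans background is
  therefore placed by a lognormal weight field (sigma 1.5 per 25 kb block),
  keyed by a *panel seed* so that all samples captured with one panel — e.g.
  a positive sample and the control it is diluted into — share the same
  field. Setting `background_dispersion = 0` recovers a uniform background
  (the uniformity property test runs there).

Default parameters (all configurable): gamma = 2.0, d0 = 10 kb,
ligations/read ~ Poisson(0.3), trans rate 0.4, sparsity 0.5, fragment length
~ N(150, 50) clipped to [30, 500] bp, 2% MQ-0 fragments, target median
segment length 141 bp (recognition-site spacings drawn exponentially;
accidental motifs in the random background are scrubbed first so digestion
boundaries are exactly the planted sites). The free knobs were fixed once so
that synthetic titrations reproduce the sensitivity regime measured on real
libraries — detection of a reciprocal translocation at 5% rearranged cells
with ~1e6 on-target reads and at 75 K reads undiluted, loss of detection
below that — and then frozen. The steep decay exponent (gamma = 2 rather
than the ~1 of intra-arm contact frequency at Mb scales) reflects the
strong short-range dominance of ligation products captured from degraded
FFPE material; with gamma = 1 the heavy tail would make arbitrarily small
dilutions detectable, which real titrations rule out.

What the generator does **not** model: sequence-level errors and mapping
ambiguity, PCR duplicates, probe-capture efficiency profiles within the
envelope, chromatin-compartment structure, copy-number variation, and
genuine long-range cis contacts beyond the monotone decay. Passing tests
therefore demonstrate the caller's statistical behavior under the assumed
contact model with realistic sparsity and background dispersion — not
robustness to alignment artifacts or CNV, which real validation data must
cover.

## Experiment harnesses and problem sizes

`pliertlc.harness` re-enacts the characterization designs at desk scale:
titration (mix a 50%-rearranged library into its matched control at
rearranged-cell fractions 5%/1%/0.2%, 1e6 reads, 3 replicates), read-depth
downsampling (20 random draws at 1e6 reads of the 5% dilution and at 75 K
reads of the undiluted sample; run at 200 permutations to keep 40 caller
runs fast), specificity (20 negative samples at sparsities 0.3/0.5/0.7,
400 K reads), and a detection-power curve over fractions
{0, 0.2%, 1%, 5%, 50%} × 10 seeds at 300 K reads. A detection counts only
when the planted partner is called and no false-positive call appears
anywhere; any extra call voids the repeat.

## Known limitations

* One viewpoint per simulated library; multi-viewpoint panels are exercised
  through hand-built read sets and the amplification logic, not the
  generator.
* The both-scales rule is applied uniformly to cis and trans groups; the
  90th percentile is taken over selected (z > 5) bins only.
* Shuffle permutations are genome-wide over the eligible pool with
  per-chromosome smoothing (the alternative — per-chromosome permutation —
  is a one-line change of the pool mask).
* Breakpoint localization assumes a single dominant transition in the
  butterfly window; complex nested events are classified conservatively.
* hg38 blacklists are not shipped; coordinates must be supplied.
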