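# Methods

## The comparison model

A rearrangement is an unordered pair of breakpoints plus a caller class
label (CTX, ITX, DEL, INV) and a read-pair support count. Coordinates
are 0-based; breakpoints are points, intervals half-open; the canonical
order of the two breakpoints follows the genome file's chromosome order,
never lexicographic, so canonicalization is stable across inputs.

Two events *match* iff their chromosome pairs are identical and both
per-side distances are ≤ the window half-width (default 500 bp,
boundary inclusive). Caller type labels are deliberately ignored during
matching: the same junction is often re-called with a different class in
another sample, and coordinates plus chromosome identity are the
reliable signal.

Classification of a pair runs direct matching, then rescue, then
look-up, in both directions. Rescue and look-up can only move events
from specific to shared, never back. A rescued or looked-up event
counts toward the shared set of the pair, hence toward both tumors'
totals (total = shared + specific per tumor); this is why the two
directional percentages of a pair differ while the shared count is a
single number.

### Greedy matching and its oracle

The matching multiplicity rule is not dictated by the problem, so the
package uses greedy one-to-one matching by ascending summed two-side
distance, ties broken toward the partner candidate with lower (left,
right) coordinates, then by the first catalogue's coordinates — fully
deterministic. Greedy is not guaranteed maximum-cardinality in theory;
the test suite checks it against an independent Hopcroft–Karp
maximum-matching oracle (networkx) on 1,000 random catalogues of ≤ 30
events: exact agreement on fixtures whose events are separated by more
than two window widths (where candidates are unambiguous), and within
one of the maximum on deliberately colliding fixtures, with any
shortfall logged. At realistic event densities (tens to hundreds of
events per genome, 500 bp windows) collisions are rare.

### Filters

Applied in a fixed order with first-match attribution (the output set is
order-invariant; only the report attribution depends on order):

1. support ≥ ⌈sequence coverage / 3⌉, floored at 2 (at 9× the threshold
   is 3 read pairs);
2. normal-pool matches removed with the same two-sided 500 bp rule (the
   pool-matching window is not separately specified anywhere
   authoritative, so the pair-matching window is reused); any pool match
   removes — the pool filter is deliberately not one-to-one;
3. intrachromosomal span < 7,000 bp removed (strict inequality: a
   7,000 bp event survives); CTX exempt;
4. breakpoint inside a centromere mask; 5. inside a segdup mask — point
   tests, no padding, since the masks are already broad regions.

A missing pool skips filter 2 with a logged warning (studies often have
matched normals for only a subset of patients); an empty pool is a
present-but-empty pool and removes nothing.

### Copy-number similarity

Windows are the union of both samples' segmentation breaks; within a
window each sample's copy number is constant. Gaps a profile does not
cover are treated as normal ploidy, because common segmentation outputs
omit unremarkable regions. States are compared categorically
(loss/normal/gain against ploidy, default 2, configurable; an exact-CN
mode exists) — categorical comparison is robust to caller level noise.
The event metric counts windows, not lengths, and excludes windows
normal in both samples; with no aberrant window it is undefined and
flagged (never 0 %). The length metric weights agreement by window
length and includes shared-normal stretches. Both metrics are symmetric
and invariant under identical refinement of both profiles (the window
*count* changes under refinement, so the event metric's invariance is
asserted on the state-pair run sequence).

### Barcodes

The cohort-wide non-redundant catalogue is built by single-linkage
clustering of all samples' events under the matching rule. Single
linkage can chain clusters beyond one window width; this is accepted
and logged, and each cluster's representative is the member with the
(lower) median left coordinate. Sample clustering uses the Jaccard
("asymmetric binary") distance — defined as 0 for two all-zero rows —
with Ward linkage. Ward formally assumes Euclidean distances; applying
it to a Jaccard matrix reproduces the semantics of the standard
binary-distance + Ward recipe and is a deliberate fidelity choice.

### Clonality

Normalized support = read pairs / overall sequence coverage (physical
coverage available via a flag). For rescued sides the partner's raw-call
support is used; for looked-up sides the evidence read-pair count
(floored at 1 — a shared call implies at least one observed pair). CTX
events contribute one table row flagged `two_sided` so plots can show
both breakpoint sides.

### Hotspots

The density track is a per-chromosome Gaussian KDE with σ equal to the
stated 10 kb bandwidth, evaluated on a 10 kb grid, each chromosome
weighted by its share of all breakpoints. This makes the track a single
genome-wide density (trapezoid integral ≈ 1, tolerance 1e−3; kernel
tails are truncated at chromosome ends, which costs ≲ 1e−3 of mass at
these scales) without kernel mass leaking across chromosome boundaries.
Both breakpoints of every event contribute, so duplicating a catalogue
leaves the track unchanged while doubling heatmap cells. Hotspots are
maximal grid runs strictly above the threshold (default 3×10⁻⁶ per bp);
runs separated by even one sub-threshold grid point stay separate.
Heatmap cells divide the pair's event count by the combined chromosome
length in 50 Mb units (diagonal: the chromosome's own length); the "per
50 Mb" normalization is ambiguous in general, so this choice is
explicit and configurable via `bin_size`.

### Enrichment

Genic area = gene body plus 2,000 bp upstream of the TSS, strand-aware,
inclusive at exactly 2,000 bp. The genic null draws the observed number
of breakpoints uniformly over the unmasked genome (masking configurable
off), matching the catalogue filters; its mean converges to
n × (genic bp / unmasked bp) and is tested against that binomial closed
form. The cancer-gene null draws equally many genes without replacement
from the annotated universe; it is a real simulation (per-draw index
sampling), with the hypergeometric closed form used only as the
independent cross-check in tests. Two-sided empirical p = 2 × tail
count / n_sims, capped at 1; a zero tail is reported as the bound
2/n_sims rather than 0. Fold = observed / null median, one decimal.

### Validation and cohort summaries

Percentages are kept unrounded internally and reported rounded to the
nearest integer, half away from zero. Cohort summaries take medians over
the directional rows (median of an even count = mean of the two central
values, then the reporting rule). Gained/lost are the
metastasis-specific and primary-specific counts of primary–metastasis
comparisons. Two aggregations of P(shared-in-metastasis | in-primary)
are emitted — pooled over events and the per-pair mean — because they
answer different questions; neither is preferred. Validation summaries
omit categories with zero tested assays, and emit both readings of
"overall accuracy excluding germline" (subtracting germline-confirmed
assays from numerator and denominator, or ignoring the germline
annotation), since the exclusion arithmetic is ambiguous.

## The synthetic generator

`simulate` emulates what a low-coverage paired-end WGS study of
clonally related tumor pairs feeds this pipeline. Defaults are the
study conditions: 5 × 50 Mb chromosomes with mid-chromosome centromere
masks, 100 somatic events per primary, shared fraction 0.89, 14
metastasis-private events, 5 germline polymorphisms shared with the
normal pool, physical/sequence coverage 22.3×/9.3×.

* Breakpoints are uniform over the unmasked genome; duplicates are
  rejected and redrawn; intrachromosomal spans are log-uniform between
  20 kb and 5 Mb (above the 7 kb filter, below chromosome scale). Event
  classes are drawn at roughly even frequencies (CTX 28 %, ITX 23 %,
  DEL 22 %, INV 27 %).
* Each sample observes an event with independent Gaussian jitter per
  breakpoint (sd 100 bp, truncated to chromosome bounds) — realized
  once, at truth construction, so the truth object itself carries each
  sample's coordinates.
* Support is Poisson(physical coverage × clonal fraction) — the
  simplest model that yields realistic sub-threshold events. Clonal
  fractions follow Beta(5, 2) (right-skewed toward clonal, mode 0.8); a
  configurable fraction of shared events (default 0.1) is made
  subclonal in one randomly chosen sample, with clonal fraction set so
  that expected support sits just below the catalogue threshold — these
  exercise the rescue path; a subset of those (default 0.05 of shared)
  is additionally withheld from the raw call list and visible only as
  read-pair evidence — the look-up path. Evidence read pairs land
  within ±150 bp of the breakpoints.
* CN profiles place non-overlapping aberrant segments (log-uniform
  0.5–10 Mb, states {0,1,3,4}); each is shared between the samples with
  probability `shared_cn_fraction` (default 0.35) or assigned to one
  sample; gaps are normal.
* The synthetic annotation tiles non-overlapping genes (23 kb bodies,
  alternating strand) so the extended genic footprint covers the target
  fraction of the genome (default 0.433).

What the generator does **not** emulate: read-level data (no FASTQ/BAM),
microhomology or replication-mechanism signatures at junctions,
chromothripsis-style clustered breakpoint foci, caller-specific artefact
modes, or CN profiles correlated with the rearrangements. Passing tests
therefore demonstrate the correctness of the matching, filtering and
statistical machinery under the stated generative model — not the
behavior of any particular SV caller on real reads.

Everything is deterministic given the seed; per-patient and per-stage
RNG streams are derived with `numpy.random.SeedSequence`.

## Problem sizes in the test suite

Tests run at desk scale by design: matcher-oracle equivalence on 1,000
random ≤30-event catalogues; shared-fraction recovery over 20 seeds ×
100 events (tolerance ±3 percentage points on the seed-averaged
estimate); genic-null calibration with 2,000 simulations of 1,000
breakpoints against the binomial closed form (3 s.e.); cancer-gene null
with 10,000 draws against the hypergeometric pmf (χ² goodness of fit at
p > 0.01); p-value calibration over 200 replicate true-null analyses
(400 draws each; the fraction at p ≤ 0.05 must stay ≤ 0.075); barcode
pair-recovery on 6 simulated patients at shared fraction 0.9. The full
suite runs in well under a minute.

## Known limitations

* Greedy matching can fall one short of the maximum matching in
  adversarial breakpoint pile-ups (logged when the oracle test sees it).
* Strand/orientation of SV ends is not modelled; matching is purely
  coordinate-based, so reciprocal translocation partners 500 bp apart
  are indistinguishable from re-detections.
* The 7 kb small-event rule uses event span, not per-end distances.
* Ward-on-Jaccard is not a metric-space-correct Ward; see above.
* CN similarity assumes a single genome-wide ploidy; no purity or
  subclonal CN correction.
* The conditional likelihood P(shared-in-met | in-primary) is reported
  in two aggregations; with few pairs they can differ by several points.
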