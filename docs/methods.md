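# Methods

## Coordinate model

Everything inside the package is 0-based half-open on the reference
forward strand.  RepeatMasker `.out` (1-based inclusive, `C` = minus),
`.align` (minus-strand consensus coordinates descending), UCSC chains
(query coordinates strand-relative when qStrand is `-`) and wiggle
(1-based) are converted at the I/O boundary and nowhere else.  Minus-strand
copy alignments are normalized so consensus coordinates always refer to the
consensus forward orientation; downstream binning is therefore
strand-agnostic, which is what makes binding profiles comparable across
copies inserted in either orientation.

## Family enrichment

For TE group *g* (subfamily, family or class) and factor *f*:

* *p* = union length of *g*'s copies on non-excluded chromosomes ÷
  non-excluded genome length.  chrY is excluded by configuration when the
  cell line is female-derived.  Overlapping copies of one group count once
  per base; each `.out` row is one copy (fragment joining of interrupted
  insertions is not attempted — per-row treatment is what the per-base
  fraction arithmetic assumes).
* *n* = all summits of *f* (TE-resident or not); *k* = summits inside
  copies of *g*.  A summit inside overlapping copies is assigned
  deterministically to the copy with the smallest start, then smallest
  copy id.
* Two-tailed binomial p-value under the minimum-likelihood convention:
  the sum of P(X=i) over all i with P(X=i) ≤ P(X=k)·(1+1e-7), the
  convention of R's `binom.test`/scipy's `binomtest`.  It is computed by
  direct pmf summation here; scipy's implementation is used only as an
  independent cross-check in the tests.
* Bonferroni multiplier = (#groups with a genomic fraction) × (#factors),
  i.e. the tests actually performed.  Significance at corrected p < 0.05.
* Reported fold enrichment is (k/n)/p.  Published per-family fold figures
  computed from rounded percentages can disagree with this ratio (e.g. a
  subfamily at 10.6% of TE-bound sites over a 0.01% genomic fraction is
  ~1000-fold by this definition); the ratio of the actual counts is what
  the package reports.

## Consensus projection and profiles

A summit inside a gapless alignment block maps linearly to the consensus.
A summit falling in a genomic insertion (no consensus base) is assigned
the nearest downstream consensus-forward coordinate and flagged; flagged
events stay in bin counts but are excluded from motif-position statistics.
Summits outside the aligned span are counted unmappable.

Profiles use 100 bins, `bin = floor(pos·100/L)` clipped to 99.  The
coverage denominator counts **all** copies of the subfamily aligning over
each consensus site (not only bound ones), averaged within each bin, and
the normalized value is events ÷ coverage × 10⁵ (events per copy per bin,
scaled for display).  This is the 5′-truncation correction: under uniform
per-copy binding a truncation-heavy subfamily shows raw counts rising
toward 3′ but a flat normalized profile, which the test suite verifies.

Uniformity over 10 segments of 10 bins: fewer than 30 events → not tested;
30–100 → exact Monte-Carlo multinomial test (Pearson statistic, R=100 000
resamples from a fixed seed, p=(1+#{T_sim ≥ T_obs})/(R+1)) — a 1×10
goodness-of-fit has no standard Fisher-exact construction, and the MC
multinomial preserves the exactness intent at small n; >100 → χ² with
9 df.  The Bonferroni multiplier for profile tests is the number of
(subfamily × factor) profiles actually tested, reported alongside.

Motif scanning: log₂ likelihood-ratio scores against an explicit
background, p-values from the exact score distribution over background
k-mers computed by dynamic programming on a 10⁻³-bit score lattice; query
scores are computed on the same lattice so boundary ties resolve
identically (the tests compare against exhaustive 4^k enumeration).  Both
strands are scanned; default reporting threshold p < 10⁻⁴.  Peak regions
for scanning are contiguous runs of bins above 3× the profile median
(configurable).

## Signal profiles and states

Meta-profiles average the signal per offset over ±400 bp (10-bp centered
moving average, truncated at edges); windowed tracks (20-bp DNase windows)
are treated piecewise-constant at base resolution.  The control set is
uniform random genomic positions retained if they fall inside a TE copy.
Group comparison is a Welch two-sample two-tailed t-test on per-site mean
scores over the window — "per-site means" rather than pooled per-base
values, so sites are the unit of independence.  Read matrices subsample
reads without replacement to a fixed target (seeded) before accumulating
coverage, emulating normalization of libraries to a fixed read count.
Chromatin segmentations are consumed, not learned; the 8-state →
promoter/enhancer/other rollup is a configuration map.

## Liftover and origin dating

A 10-bp window around each summit is mapped through the single
highest-scoring chain overlapping it; the mapping succeeds iff ≥95% of
bases land inside that chain and the image is one target interval
(approximating the liftOver minMatch default; configurable).  Failure
reasons distinguish no chain, a gap within the best chain, and splits
across chains.  Species without chain data are `no_data` and never
influence a call.

The origin clade is the MRCA of the reference and the mapped species most
distant on the tree, resolved by node depth from the reference (topology,
not branch lengths); a time-calibrated tree is cosmetic metadata here
since no dating computation is performed.  A per-subfamily maximal-clade
table caps calls: a site in a lineage-restricted subfamily that appears to
map outside the subfamily's range is flagged inconsistent and capped.
Missing chains can only make calls younger, never older — the ablation
test verifies this monotonicity.

## Colocalization and density

Within each TE category, copies bound by factor *a* are split into
bound/not-bound by *b* and tested against a baseline binding probability
with a one-sample χ² (1 df, no continuity correction — the plain named
test).  The default baseline is the category's average b-binding
probability; a genome-wide baseline may be passed explicitly.  Categories
with ≤10 a-bound copies are reported not-testable.

Density scans count bound copies per kilobase in 100-kb windows at 50-kb
steps (10-kb steps for single-chromosome scans); a copy belongs to the
window containing its midpoint, so totals over a non-overlapping tiling
conserve the copy count.  The top locus merges the contiguous run of
top-1%-density windows around the argmax.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with these defaults as the standard conditions:

* two 2-Mb chromosomes; eight species on a labeled amniote-like tree
  (human reference through Hominini … Theria);
* five subfamilies, ~3000 copies: an ancient eutherian wave (MIR-like
  SINE and heavily 5′-truncated L2-like LINE, ~25% divergence), a young
  simian ERV1-like LTR wave (~8%), and motif-free Alu-like/L1-like
  background families (2%/15%);
* an ERα-response-element-like palindrome planted at a fixed consensus
  interval of the three source subfamilies, retained intact by 70–80% of
  copies and scrambled in the rest;
* four factors × 500 summits; 30–50% placed at retained motif instances
  (jitter ±2 bp), the rest uniform.  A shared "active" subset (30%) of
  retaining copies attracts 70% of planted summits of every factor — this
  is what creates factor colocalization within the same copies — and
  hot-locus copies are preferentially active, so the planted 200-kb hot
  locus is also the density argmax;
* per-base conservation ~N(0.017, 0.15) with +0.25 uplift within ±50 bp
  of bound summits; 20-bp-window DNase track with analogous uplift;
* chains built from the true insertion bookkeeping: a copy is present in
  exactly the species descending from its insertion clade, so mappability
  is exact by construction rather than by alignment;
* divergence realized as per-base substitution at a copy-specific rate
  (no indels by default; a configurable indel mode exists to exercise
  projection gap handling).

Every bundle passes a self-audit that re-parses all emitted files and
checks them against the manifest.  What the generator does **not**
emulate: sequence-level homology between species (chains are bookkeeping,
not alignments), fragmented/nested insertions, CpG-biased substitution,
read-level noise (summits are generated directly since peak calling is
out of scope).  Passing tests therefore demonstrate the correctness of
the statistical machinery under the stated model, not robustness to every
artifact of real annotations.

Reduced-scale presets (`small`, `null`) keep the unit-test and calibration
runs fast; the acceptance script runs the full default scale.  All
randomness flows from a single seeded generator, and identical configs
produce byte-identical bundles.

## Numerical choices and degenerate inputs

* Binomial and χ² p-values are floored at the smallest positive float
  where the analytic value underflows.
* Zero-coverage profile bins are NaN and flagged, never zero.
* Zero variance in both groups of a profile comparison returns p=1 (equal
  means) or p→0, flagged degenerate.
* Conserved elements require length strictly >20 bp and lod strictly >60
  before CDS subtraction.
* Ties everywhere (overlapping host copies, equidistant TSSs, equally
  distant species) are broken deterministically and documented at the
  operation.

## Limitations

* Fragment joining of interrupted RepeatMasker hits is not implemented;
  fractions and copy counts are per-row.
* The liftover is single-chain; reciprocal-best filtering and paralog
  disambiguation are out of scope.
* The exact-MC uniformity test is exact only up to Monte-Carlo error
  (~1/√R); R is recorded with each result.
* Real `.align` dialects vary; the parser handles the standard layout and
  ignores Kimura-divergence footers, but exotic variants may need
  adaptation.
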