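# Methods

## Model and procedure

`chicmax` treats interaction calling as peak detection on one-dimensional
bait-centric profiles. The assumptions are minimal: (i) within ~1.5 Mb the
expected background contact frequency of a bait is dominated by genomic
separation and decays monotonically; (ii) a chromatin loop produces a local
excess of signal spanning contiguous restriction fragments; (iii) no
parametric form for either is trusted enough to fit per bait, because a
single bait's data are too sparse and a strong loop would contaminate any
fitted background near itself.

Per bait, the pipeline is: restrict to cis, non-bait, covered fragments
with interval gap ≤ *c* from the bait; loess-smooth counts against fragment
midpoint (degree 1, tricube, no robustness iterations, span *s*); mark
every index attaining the maximum of its centred window of *w* covered
fragments (ties all reported, edges truncated); retain a maximum iff its
smoothed value strictly exceeds the geometric mean of raw counts in its
distance bin of width *b*. The strict inequality is what makes a constant
profile yield zero calls; it is evaluated with a 1e-12 relative epsilon so
exact mathematical ties never pass on floating-point noise. Bait-to-bait
pairs are excluded before profiling (double-captured products produce
artificial maxima), and trans pairs are out of scope.

Replicate handling is a separate, explicit step: a reference-replicate call
survives only if every other replicate called an interaction for the same
bait within *d* bp, measured as interval gap (identical, overlapping or
directly adjacent fragments are zero). The merged row keeps the reference
coordinates and diagnostics and annotates the matched partner fragment ids
per replicate. A `min_replicates` relaxation and a midpoint-distance metric
exist for sensitivity analysis but are off by default.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| *w* | maxima window, covered fragments | 20 | 50 is the documented stricter alternative; simulations here use 50 because the window should not be narrower than the loess span in covered fragments (s·n ≈ 50 at n ≈ 1000), otherwise the flanks of one smoothed bump can themselves win smaller windows |
| *s* | loess span fraction | 0.05 | internally floored so each local fit sees ≥ 3 points |
| *c* | cis window, bp | 1,500,000 | beyond this the background is no longer distance-dominated |
| *b* | geomean bin width, bp | 30,000 | filter robust to the choice |
| *d* | merge threshold, bp | 20,000 | chosen from the closest-distance distribution between replicates (`repdist`) |

Baits with fewer than max(3, ⌈s·n⌉) covered fragments are skipped with a
logged warning, not an error. Baits are processed independently and one at
a time, so memory is flat in the number of baits.

## Synthetic data generator

The generator emulates what the caller assumes about real promoter CHi-C:
a contiguous digest (default fixed 1-kb fragments, a 4-cutter-like scale;
lognormal lengths optional); expected counts
`depth · eff_bait · (gap + ε)^(−α)` with α = 1 and ε = 5 kb; per-bait
lognormal capture efficiencies (σ = 0.25); negative-binomial counts
(dispersion 0.2; Poisson optional) with zero-count pairs omitted so only
covered fragments appear. The default depth scale (2.5 × 10⁵) yields
≈ 1100 covered fragments per bait within the 1.5-Mb window — deep proximal
coverage decaying to sparse single-read distal coverage, with proximal
counts in the tens, as in real data.

Planted loops are triangular enrichments (apex amplitude ×10, half-width 8
fragments) — loop signal in fragment-resolution CHi-C spreads over
contiguous fragments rather than a single spike. Defaults place three
loops per bait at 60–250 kb separation, ≥ 70 kb apart: the genomic range
where regulatory loops typically sit and where the profile has detection
power at this depth (a 10× multiplier on a distal expected count of 0.1
reads is statistically invisible; that is a property of the data, not the
caller). Replicates are independent resamplings sharing the planted truth,
optionally with each peak centre re-planted within a jitter bound to mimic
fragment-level irreproducibility.

What the generator does **not** emulate: correlated background structure
(domains, compartments), capture-probe sequence biases, trans contacts,
bait-to-bait products, mappability gaps. Passing recovery tests therefore
show the algorithm does what it claims on distance-decay-plus-loops data;
they do not certify false-positive rates on real chromatin, where
correlated structure will generate more maxima.

## Planted-truth evaluation conventions

Recovery is scored in covered-fragment index space. A planted loop is
recovered if a call lies within ±2 covered fragments of the planted
enrichment region (not of the single apex fragment — the planted signal
genuinely spans the region, and the maximum of a smoothed bump on a sloped
background is not apex-exact). A call is spurious if it is farther than
that from every planted region. Calls in the first and the last genomic-
distance bin are excluded from the bookkeeping: the point of closest
approach to the bait is the apex of any decaying profile and is always a
windowed maximum (the standard 4C-style viewpoint exclusion), and the
truncation at the cis-window boundary makes maxima in the outermost bin
equally ill-defined. Planted loops are never placed in either zone.

Under these conventions the full pipeline (caller per replicate, 4
replicates, jitter ≤ d/2, merge at d = 20 kb) recovers planted loops with
recall ≈ 96–99% and precision ≈ 98–100% at 50 baits; the residue consists
of per-replicate misses of marginal loops — the bait-specific geometric
mean is inflated by a strong loop's own reads within its distance bin, a
known cost of bait-specific backgrounds — propagated through the strict
all-replicates rule, plus rare weak maxima coinciding across replicates
within d. Single-replicate calling alone has high recall but low precision
(~0.3); the replicate merge is what removes irreproducible noise maxima,
which is the design's entire point.

## Numerical and design choices

- Loess is delegated to statsmodels' lowess; the test suite checks it
  against an independently written tricube local-linear regression
  (agreement ~1e-14 with matched neighbour counts).
- Windowed maxima use a truncated rolling maximum
  (`maximum_filter1d` with −∞ padding), verified against an O(n·w)
  double-loop oracle.
- Quantile normalization follows the classic order-statistic-mean scheme;
  ties receive the mean of the order statistics they span. Exact
  idempotence and identical sorted columns hold for tie-free data; tie
  averaging in one column perturbs the pooled order statistics of a second
  pass, so on tied data these properties hold only up to that averaging.
- ChAs doubles each undirected edge into both orientations before the
  Pearson correlation (the standard numeric-assortativity convention;
  cross-checked against igraph). Note the correlation is invariant under
  any affine map of the feature values applied to both endpoints — also
  for negative scale factors, since both coordinates flip together.
- Interval overlap uses searchsorted over sorted merged intervals;
  "overlap" always means any-bp intersection.
- The enrichment background defaults to fragments covered by ≥ 1 read in
  the raw dataset (a practical stand-in for mappability); an explicit
  fragment list overrides it. Other-end fragments are deduplicated before
  counting, with a per-interaction option.
- All randomness flows through `numpy.random.default_rng` seeded from the
  spec, so every generator output is bit-reproducible; figure output omits
  volatile metadata so identical inputs give identical bytes.

## Problem sizes

The test suite runs the full recovery experiment at 10 baits (module test)
and 50 baits × 4 replicates (acceptance), and one 2000-bait dataset with
~2.2 M covered pairs for the scale check (≈ 45 s end to end on one core).
The acceptance script repeats these from a user seed.

## Known limitations

- No interaction-strength score or p-value is attached to calls.
- The bait-proximal apex and cis-window boundary regions are structurally
  call-prone; downstream consumers should mask them as described above.
- Bait-specific geometric means overestimate the background around very
  strong loops, costing sensitivity to marginal loops in the same bin.
- The merge is reference-oriented: a loop missed by the caller in the
  reference replicate is lost even if all other replicates saw it.
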