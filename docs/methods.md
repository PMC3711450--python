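# Methods

This note documents the models, parameter choices, numerical details and
limitations of `capture3c`, in the order the pipeline runs.

## Fragment maps

The genome is digested in silico at every exact occurrence of the enzyme's
recognition site.  Conventions:

- Coordinates are 0-based, half-open everywhere; BED/bedGraph outputs keep
  this convention, and any 1-based display is the presentation layer's job.
- The cut is placed at the *start* of the recognition site (the site
  belongs to the downstream fragment).  Read 5′ ends in viewpoint-capture
  data abut the site boundary, which this convention matches; an optional
  `cut_offset` shifts cuts by the enzyme's biochemical cleavage offset for
  users who prefer it.
- IUPAC ambiguity codes in the *site* expand to character classes;
  ambiguity codes in the *genome* never match (conservative).
- Palindromic sites (the common case for 6-cutters such as HindIII, EcoRI,
  BamHI) are searched on the forward strand only; a non-palindromic site
  triggers a warning and a both-strand search.
- Zero-length fragments (adjacent sites, or a site at the chromosome edge)
  are dropped; per chromosome the fragments are sorted, gap-free and tile
  the full length.

A 6-bp cutter hits i.i.d. uniform sequence every 4⁶ = 4096 bp on average,
which is the assay's native resolution (~4 kb).

## Counting

Reads are assigned by their strand-aware 5′ position (alignment start on
+, end − 1 on −), not by midpoint or overlap: the 5′ end marks the ligation
junction.  Unmapped, secondary and supplementary records are dropped;
`min_mapq` defaults to 10 (excludes typical multi-mappers).  Reads on
chromosomes absent from the fragment map are tallied as "unassigned", never
an error, so counts + unassigned always equals the input read count.

The informative-read filter keeps reads whose 5′ end lies within
`tolerance` of a fragment boundary.  The biochemically expected position is
exactly at the boundary, but end repair and alignment clipping commonly
shift one base, so the default tolerance is 1 bp; 0 is available for
strictness.  Duplicate reads are *not* collapsed by default (deduplication
is not part of the standard workflow for this assay); a flag collapses
identical (chrom, 5′, strand) tuples.

Window mode tiles each chromosome with half-open windows (last window
truncated).  Overlapping mode halves the step, so each position is covered
by two windows.  Windows below 1 kb trigger a warning, not an error.

## Power-law normalization

The reverse-cumulative count distribution R(t) is evaluated at every
distinct observed count (no binning) after removing regions with fewer than
`min_count` = 50 reads and the viewpoint fragment ± 1 neighbour (these
carry self-ligation and incomplete-digestion signal).  Unweighted OLS of
log₁₀ R on log₁₀ t gives the library's slope and offset; fewer than three
distinct surviving counts is an error suggesting a lower `min_count`.

Counts are then mapped onto a reference line with slope α_ref = −1.35 and
depth n₀ = 10⁶.  The reference line needs an intercept convention, which we
fix as l_ref = log₁₀(n₀ / ζ(−α_ref)): a library of m regions following the
discrete law P(T ≥ t) = t^α_ref holds m·ζ(−α_ref) reads in total, so a
reference library of n₀ reads has R(1) = n₀ / ζ(−α_ref).  Two consequences
define the convention's correctness: a library already distributed as the
reference law maps to itself (identity), and re-fitting the power law on
normalized values always returns slope α_ref.  Every downstream statistic
uses only relative signals, so any consistent constant would do; this one
is documented and tested.

The mapping is strictly increasing and tie-preserving; zero counts map to
zero.

## Cis background and scoring

Regions on the viewpoint chromosome are ordered by *absolute* distance
between region midpoint and viewpoint midpoint.  Pooling up- and downstream
doubles the data per distance stratum and the decay is approximately
symmetric; a signed-distance option exists for asymmetric loci.

The background is a penalized cubic smoothing spline with the classical
`spar` parameterization: predictors are rescaled to [0, 1], the penalty
weight is λ = r·256^(3·spar − 1) with r = tr(XᵀWX)/tr(Ω) the standard
design-dependent scale factor (X the cubic B-spline design matrix on knots
at the unique predictor values, thinned to ≤ 200 quantile-spaced knots for
large inputs; Ω the exact Gram matrix of second derivatives, integrated
with 2-point Gauss–Legendre per knot span, which is exact for the
piecewise-quadratic integrand).  Duplicate predictor values are aggregated
to weighted means with multiplicity weights.  `spar` defaults to 0.1 and is
restricted to [0.06, 0.4] unless explicitly overridden; smaller values
follow the data more closely.

Fitting details:

- The viewpoint region ± 1 is excluded from the fit *and* from the call
  output.
- Zero-signal regions are excluded from the fit (they would drag the spline
  down in the sparse far-cis tail) but are retained for scoring with an
  interpolated expectation — their z is typically far negative.
- Expected values are clamped at 0 before residuals are formed.
- The residual SD is a single global scalar (n − 1 denominator) over the
  fitted regions, not distance-local.
- Outside the fitted distance range the spline extrapolates as a constant.
- A residual SD within 10⁻⁸ of zero (relative to the signal scale) is a
  degenerate background and an error, as is a constant trans signal.

z = (obs − exp)/SD; p = 1 − Φ(z), upper tail only — only enrichment over
background constitutes an interaction, so depleted regions are never calls.

Because the spline is linear in the response and λ does not depend on the
response scale, multiplying all signals by a positive constant leaves every
z, p and q unchanged (verified by test).

A known limitation: the global residual SD understates the Poisson noise
of high-count near-viewpoint regions and overstates that of far regions, so
near-viewpoint z-scores run hot and far z-scores run cold.  Under null
simulations the called fraction stays well below the FDR level, but callers
interested in contacts inside ~50 kb should treat them with extra care.

## Trans scoring

The global mean and SD (n − 1) are computed over all regions genome-wide
excluding those within ±100 kb of the viewpoint midpoint; z is reported for
every trans-chromosome region against these two scalars.

## q-values

q-values use the step-up construction q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ π₀·m·p₍ⱼ₎/j, which
reduces exactly to Benjamini–Hochberg at π₀ = 1 (tested against an
independent implementation).  π₀ is estimated by the bootstrap method:
π₀(λ) = #{p > λ}/(m(1 − λ)) on the grid λ = 0.05…0.95 (step 0.05); 100
bootstrap resamples estimate the MSE of each π₀(λ) around the minimal
value, and the λ with smallest MSE wins.  Estimates are clamped into
(0, 1].  Two degenerate regimes are handled conservatively: fewer than 10
p-values, and p-value distributions with no mass near 1 (which drive the
raw estimate to 0, because the uniform-null assumption behind π₀
estimation is violated) — both fall back to π₀ = 1 with a warning, which
can only make calls more conservative.

Cis and trans q-values are computed in separate batches: the two z-scores
have different null models, and the dense cis batch would otherwise
dictate π₀ for the small trans batch.

## Replicates

Candidates are the union or intersection of the per-replicate significant
sets.  Counts, RPM and normalized RPM are averaged over *all* k replicates,
including those where the region was not individually significant — the
averages are meant as representative values, and the `support` column
exposes asymmetry.  Per-replicate p-values are combined by Fisher's method
(X = −2 Σ ln pᵢ, upper χ²(2k) tail; p = 0 is clamped to the smallest
positive float with a warning), and q-values are recomputed on the combined
candidate batch, again separately for cis and trans.  With k = 1 the
combination is the identity and the single-sample significant set is
reproduced.  Call sets from different region grids (fragment vs window, or
different window sizes) are rejected.

## Annotation, export, domainogram

A gene is reported when any significant call overlaps its strand-aware
window [TSS − upstream, TES + downstream] (defaults 50 kb / 5 kb; mirrored
for − strand).  Enlarging the windows can only add genes.  Each gene is
reported once with its best (minimum q) supporting call.

bedGraph export writes the UCSC dialect (one `track type=bedGraph` header,
0-based half-open records), omits zero values, and refuses overlapping
regions, which the format cannot represent.  Text export writes a fixed,
documented column order with floats at 6 significant digits; round-trips
reproduce values to that precision.

The domainogram re-runs the window pipeline for sizes 2–30 kb in 1-kb steps
(29 sizes).  Windows are tiled over the *whole* cis chromosome — keeping
the power-law fit and the spline background on the same footing as the
ordinary window analysis — and the q of the window covering each 1-kb
position within the requested span is recorded.  When too few windows pass
the count filter for a power-law fit (small windows, shallow libraries),
the domainogram falls back to simple RPM for that size.  For export and
plotting, q is transformed to −log₁₀(q) capped at 10; cells of the
viewpoint window ± 1 are undefined and exported as 0.

## Simulator

The generator emulates exactly the structure the caller assumes, so that
every stage is testable with known ground truth:

- Chromosomes are i.i.d. uniform A/C/G/T, reproducible from the seed.
- A cis fragment at distance d from the viewpoint receives weight
  (1 + |d|/d₀)^−γ — a *shifted power law*, not an exponential, so the count
  distribution entering the normalization fit is itself power-law-like.
- Spiked fragments multiply their weight by a fold factor and are recorded
  in the ground-truth table; reads land on trans fragments uniformly with
  probability `trans_fraction`.
- A read's 5′ end abuts a fragment boundary (pointing into the fragment)
  with probability `informative_fraction`, else it falls uniformly inside
  the fragment with random strand.
- Alignments are emitted as coordinate-sorted BAM (or SAM) with mapping
  quality 60 and ungapped CIGARs.

Defaults — two 5-Mb chromosomes, HindIII, γ = 1.2, d₀ = 10 kb,
trans_fraction = 0.05, informative_fraction = 0.9, 2×10⁵ reads — give
~2,400 fragments and full-pipeline runs in about a second, while keeping
per-fragment counts high enough that the distance decay, the < 50-count
filter and the spike contrast all behave as they would in a deeply
sequenced library.  The expected-proportion table depends only on the
configuration, never on the seed.

The helper `choose_spike_fragments` places spikes between 100 kb and
1.5 Mb from the viewpoint, at least 10 fragments apart: inside the steep
near-viewpoint decay a 10× spike is absorbed by the spline, and adjacent
spikes merge into local bumps the near-interpolating spline partially
follows, so separated mid-range spikes are the appropriate model of
distinct interacting loci.

What the simulator does *not* model: sequence-level errors and quality
strings, PCR duplicates, mappability variation, fragment-length-dependent
capture efficiency, undigested/self-ligated backbone products beyond the
viewpoint's own neighbourhood, and biological variability between
replicates (replicates differ only by sampling noise).  Passing tests
therefore demonstrate the statistical machinery under the model's own
assumptions, not robustness to every artifact of real libraries.

## Reference-law sampling

For slope-recovery checks, counts are drawn from the reference law by
inverse-transform sampling of P(T ≥ t) = (t/c)^α on t ≥ c with c set to
the 50-count fitting threshold.  Sampling the post-filter support emulates
the deeply sequenced libraries the fit targets, where the ≥ 50-count
population is abundant; sampling from c = 1 instead leaves only ~0.5% of
10⁴ regions above the filter and the fit degenerates to a handful of
order statistics.

## Problem sizes in the test suite

The suite simulates at the default scale (two 5-Mb chromosomes, 2×10⁵
reads) for calling behavior, 20 null replicates for FDR aggregation, a
20-Mb single chromosome for the fragment-resolution check, and 10⁶ reads
for law-of-large-numbers checks of the generator — sizes at which every
targeted effect is comfortably resolved while the whole suite runs in well
under a minute of simulation time.
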