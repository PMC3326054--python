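# Methods

This note documents the models implemented in `amplimit`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic data
can and cannot tell you about real sequencing runs.

## The geometric detection model

A sequencing run of *k* reads from a community is treated as *k* independent
draws from the community's relative-abundance distribution.  For a taxon at
abundance *p*, the read index of its first occurrence is geometric, and the
probability of observing it at least once is `F(k; p) = 1 − (1 − p)^k`.
Everything else is algebra on this CDF:

- `reads_required(p, c)` returns the smallest *k* with `F(k; p) ≥ c`.  It is
  computed as `⌈ln(1 − c)/ln(1 − p)⌉` and then nudged by direct CDF
  evaluation so that `F(k) ≥ c > F(k − 1)` holds *exactly* in floating
  point; this makes `reads_required` and `min_detectable_abundance` mutual
  inverses over the whole practically relevant range (k ≤ 10^5, verified in
  the test suite).
- `min_detectable_abundance(k, c) = 1 − (1 − c)^(1/k)` is the abundance whose
  required depth is exactly *k*.  At c = 0.95 this gives 0.332% at 900 reads
  and 0.746% at 400 reads.  Reported cutoffs are rounded to one decimal in
  percent (0.3%, 0.7%), which is the package's display convention, not a
  change to the underlying value.

Assumptions worth keeping in mind: reads are exchangeable (no PCR
jackpotting), *p* is the post-amplification read fraction (so 16S copy-number
bias must be applied *before* using a genomic abundance as *p*), and
detection means "at least one read" — no multi-read detection criterion is
offered.

The model's independent-draw assumption is an approximation to rarefaction
(sampling *without* replacement); it is accurate when the subsample depth is
small relative to the library (the exact probability is hypergeometric,
`1 − C(N−m, k)/C(N, k)`, which the test suite compares against directly).

## Empirical detection curves

`multiple_rarefaction` subsamples a library's count vector without
replacement (multivariate hypergeometric draws) `n_subsamples` times at each
depth of a grid — by default 10…100 by 10, 100…1,000 by 100, 1,000…10,000 by
1,000 and 10,000…90,000 by 10,000, deduplicated and capped at the library
size — and records, per taxon, the fraction of subsamples containing it.
100 subsamples per level bounds the binomial standard error of each
proportion at 0.05.

### Bootstrapped Kolmogorov–Smirnov fit

The observed statistic is `D = max_k |F̂(k) − F(k; p)|` over the level grid.
Bootstrap replicates re-draw the per-level detection indicators from the
empirical proportions (`Binomial(n_subsamples, F̂(k))/n_subsamples`) and
measure `D* = max_k |F̂*(k) − F̂(k)|` — the sampling variability of the curve
around itself.  The p-value `(1 + #{D* ≥ D}) / (n_boot + 1)` therefore asks
whether the model misfit exceeds what subsampling noise alone produces.
This scheme is calibrated (a true geometric curve is retained ≥ 90% of the
time at α = 0.05 in the suite's 100-run check) and powered (a curve from a
2×-misspecified abundance is rejected).  The alternative of recomputing the
*model* distance on bootstrap curves would concentrate `D*` at `D` and have
no power, so it was not used.

## The mock-community simulator

`mock_community()` defines twelve taxa over nine genera with input
abundances 0.75, 3 × 0.075, 3 × 0.0075, 2 × 0.00075, 2 × 0.000075 and
0.0000075 (normalized to sum to one), spanning the five orders of magnitude
that make detection limits interesting in respiratory communities.  Default
16S copy numbers are literature-typical per-genome values (3–8); they are
configurable, and analyses that depend on unbiased composition run with
copy-number bias off.

Simulation of a library of *n* reads proceeds as:

1. taxon labels: one multinomial draw in the (optionally copy-number
   adjusted) abundances; the label vector is then shuffled;
2. per read, from its own deterministic child RNG stream: a read length from
   `Normal(250, 50)` (non-positive draws redrawn), applied to the
   reverse-complement of the taxon's reference amplicon (sequencing runs
   from the reverse primer); then homopolymer noise; then positional errors;
3. a single 5-base multiplex identifier (MID) per library, prepended on
   output.

Reference amplicons are seeded random 350-bp sequences generated at load
time — taxonomy travels as ground-truth labels, so no genomes are downloaded
and no taxonomic assignment step exists in the pipeline.  Downstream,
`trim_and_length_filter` truncates reads to a uniform 230 bp and drops
shorter reads (for `Normal(250, 50)` lengths this retains Φ(0.4) ≈ 65.5%).

Error model defaults:

- positional substitution/indel rate ramps linearly from 0.004 at the 5′
  base to 0.005 at the 3′ base; 90% of drawn errors are substitutions and
  10% indels (insertion/deletion equiprobable), a split typical of
  read-simulator practice;
- each maximal homopolymer run of length *n* is redrawn as
  `round(max(0, Normal(n, σ(n))))` with `σ(n) = 0.03494 + 0.06856·n`,
  flow-signal-style constants from the pyrosequencing simulation
  literature.  Runs of length 1 participate (σ(1) ≈ 0.10 leaves them intact
  essentially always); `σ` identically zero is the identity, negative `σ` is
  rejected.

What the simulator does *not* emulate: flowgram-level signal processing,
per-base quality scores, chimeras, PCR amplification bias, and real
taxonomy assignment error.  Tests passing on simulated libraries therefore
validate the statistical machinery — composition recovery, detection
probabilities, threshold behaviour — not platform-specific artefact rates.

## Abundance filtering and contamination

`normalize_to_depth` rarefies each sample to a common depth without
replacement (samples below the depth are dropped with a warning);
`apply_abundance_cutoff` zeroes, per sample, taxa whose relative abundance is
strictly below the cutoff (ties at the cutoff are retained) and drops taxa
zeroed everywhere.  Counts are *not* renormalized — filtering and
renormalization are deliberately separate operations so that filtered and
unfiltered profiles remain directly comparable.  Filtering is idempotent and
monotone in the cutoff.

`classify_contaminants` first consolidates counts at genus level (OTU-level
splits of one genus should not inflate contaminant counts), then labels any
observed genus outside the known community as a bona fide contaminant and
reports per-sample contaminant read fractions; contamination percentages are
computed after depth normalization when both are used.
`fit_yield_contamination_power_law` fits `fraction = a·yield^b` by log-log
least squares; declining contamination with rising DNA yield shows up as
b < 0.

The practical filtering recipe is: rarefy to depth *k*, then cut at
`min_detectable_abundance(k)`.  At that cutoff, a spiked contaminant well
below the threshold is removed with high probability while community members
at ≥ 2× the cutoff are retained — but both guarantees are binomial, not
absolute: a taxon sitting exactly at 2× the cutoff still falls below it in
~3% of samples at k = 900 by sampling noise alone.  The property tests
assert pooled rates accordingly.

## Community comparison

- **Weighted UniFrac** uses the branch-proportion formulation:
  `raw = Σ_b l_b |p_A(b) − p_B(b)|`, normalized by
  `Σ_b l_b (p_A(b) + p_B(b))`, computed in one postorder pass.  This accepts
  multifurcating (star) trees; on strictly bifurcating rooted trees it
  matches scikit-bio's implementation to 1e-12 (tested).  The packaged
  genus-level tree is a labeled stand-in, so UniFrac values on it validate
  the algebra, not any published distances.
- **Shannon index** uses the natural log by default (base is a parameter).
- **Exact Mann–Whitney U** enumerates all `C(m+n, m)` group assignments of
  the pooled data (bound m+n ≤ 12 by default), computing U with mid-rank tie
  handling; the two-sided p-value is the permutation probability of a
  deviation `|U − mn/2|` at least as large as observed, which respects the
  enumeration null under ties.  Both one-sided alternatives are available;
  two-sided is the default.
- **PERMANOVA** is one-way with free label permutation,
  `p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1)` (scikit-bio backend).  Note
  that with two well-separated groups the attainable p-value is bounded not
  by the floor `1/(n_perm+1)` but by the rate of permutations that map the
  groups onto each other and tie `F_obs` exactly (e.g. ≈ 9/1001 in
  expectation for two groups of five at 1000 permutations).
- **PCoA** is classical scaling on the Gower-centered squared-distance
  matrix, implemented directly so that negative eigenvalues (non-Euclidean
  structure) are reported rather than zeroed; coordinates are built on
  positive axes only and explained fractions are relative to the positive
  eigenvalue mass.

## Problem sizes and determinism

Default analysis sizes were chosen so a full pipeline run is comfortable on
a laptop: replicate libraries of 5,000 reads, one deep library of
50,000–100,000 reads for detection curves, 100 subsamples per rarefaction
level, 1,000 bootstrap/permutation replicates.  These match the regime the
thresholds are meant for (hundreds to tens of thousands of reads per
sample).  Every stochastic function takes a seed or Generator; library
simulation derives one child stream per read from the top-level seed, so
identical inputs give byte-identical FASTA/FASTQ output regardless of
platform.

## Known limitations

- The geometric model ignores overdispersion from PCR and library
  preparation; real detection probabilities for hard-to-lyse organisms can
  sit well below the model's curve for their nominal abundance.
- Copy-number adjustment uses per-genome copy numbers as fixed constants;
  real communities mix strains with different copy numbers.
- The exact MWU's enumeration bound (default 12 total observations) is
  intentional — beyond it, use a large-sample method.
- `min_detectable_abundance` concerns presence/absence only; it says nothing
  about the accuracy of abundance *estimates* near the detection limit.
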