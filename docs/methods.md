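# Methods

This note documents the models, conventions and design choices behind the
package, in the order data flows through the pipeline.

## Fragment report and detection convention

The unit of input is a long-format fragment-ion table (one row per fragment
× channel × sample) in the canonical schema described in `karma.io`. DIA
extraction tools encode "not detected" both as an empty cell and as
intensity 0; the reader normalises both to 0.0 and *detection* means
intensity strictly greater than the configurable threshold (default 0).
Column names are mapped through a dialect dictionary, since vendor header
sets differ; the canonical names are a documented default, not a hard
requirement.

## Labeling quantification cascade

1. **Fragment filters.** Rows flagged by the extraction tool are removed;
   only proteotypic, y-series, single-lysine fragments are kept. The
   requirement that a fragment be "found in both heavy and light channels"
   is evaluated experiment-wide by default: a fragment is retained if it
   has at least one detection in each channel anywhere, and per-sample
   zeros then propagate into the precursor sums. The stricter per-sample
   interpretation is available as `both_channels_scope="sample"`. The
   experiment-wide reading matches library-level fragment retention and,
   importantly, keeps pre-pulse (t = 0) samples quantifiable, where the
   heavy channel is structurally empty.
2. **Aggregation.** Fragment intensities are summed per precursor per
   channel (`sum_all`); the targeted-assay convention of summing only the
   3 most intense fragments per channel is available as `top3`.
3. **Presence filter.** A precursor is kept only if detected in at least
   `min_reps_per_timepoint` replicates (default 2 of 3; the acute-depletion
   variant uses 1) at *every* post-labeling time point. Time 0 never
   participates in presence filtering, RMSE computation or ratios; it is
   carried through and reported.
4. **Fractional labeling.** FL = H/(H+L) per precursor and sample; missing
   when H + L = 0.
5. **Two-pass protein median.** Pass 1 computes per-sample medians over all
   of a protein's precursors. Each precursor's RMSE from those medians is
   computed over the post-labeling samples where the precursor has an FL
   value (no imputation — imputing values for missing samples would pull
   RMSEs toward the median and bias pruning). The ⌊n · discard_fraction⌋
   highest-RMSE precursors are discarded (default fraction 0.5, so odd n
   discards ⌊n/2⌋ and retains the larger half); ties are broken by
   retaining the more intense precursor (summed H + L), then the
   lexicographically smaller id, making the prune deterministic. Pass 2
   reports the median over survivors. The medians are *not* recomputed
   iteratively after pruning; a single prune pass is applied.
6. **Derived comparisons.** For bait normalisation, replicates are first
   aggregated by the median per protein per (bait, condition, time), then
   divided by the bait's value; samples with missing or zero bait FL
   propagate as missing. Treated/control ratios are computed per
   (replicate, time point) pair where both sides are quantified and
   summarised as mean ± SEM with the pair count.

The manual, blinded exclusion of visually noisy trajectories that a human
analyst would perform is replaced by an *optional* automated filter
(`max_replicate_sd`): proteins whose replicate SD of FL exceeds the
threshold at any post-labeling time point are dropped and logged. It is off
by default because automated and manual curation are not equivalent.

## Label-free tier enrichment

Precursor intensities (fragment sums over proteotypic, non-flagged
fragments; precursors absent from any replicate omitted) are median
normalised across samples: each sample is divided by its median over
detected precursors and rescaled by the grand median of sample medians, so
sample medians equalise while the data keep their original unit scale.
Note the anchor makes the transform invariant to rescaling any one sample
only when that sample does not itself hold the grand median — with three or
more samples the anchor is set by the middle sample and single-sample
rescalings cancel exactly. Protein intensity is the mean of the top-3
precursors per sample, requiring at least 3 precursors per protein. The
enrichment score takes, per protein, the replicate-median per bait, then
the ratio of the median over early-tier baits to the median over late-tier
baits. Proteins with no late-tier signal receive an infinite fold with an
explicit flag; exclusion lists (for the complex's own subunits and NTRs)
are user-supplied, never hard-coded.

## Intermixing extent

In a mixed heavy/light lysate pulldown the co-purified background proteins
trace the heavy share of the mixture, while any heavy signal among the
tagged complex's subunits must have exchanged in during purification. The
cascade runs with two extra filters — precursor H + L below 100 a.u. in a
sample is discarded, and only proteins with at least 4 precursor ions are
scored (both thresholds configurable; the intensity threshold is applied to
the channel-summed precursor intensity because the channel it refers to is
otherwise ambiguous). Extent = subunit FL / mean FL of co-purified
proteins, excluding the subunits themselves and (by default) the bait from
the reference. A subunit with no heavy signal anywhere is removed by the
two-channel fragment filter; when its light evidence alone passes the
intensity and precursor-count filters it is reported as a genuine
zero-exchange observation (extent 0) rather than a missing protein.

## Kinetic state model

A protein species moves through three states with first-order kinetics,

    free  --k_a-->  accessible  --k_m-->  inaccessible,

with uniform growth dilution μ = ln2/T_d on every state and constant
synthesis into the free state; synthesis switches to heavy label at t = 0.
The bait sees the accessible state (plus, optionally, a `w_free`-weighted
share of the free pool; default 0, i.e. the bait captures assembled
complexes). At the steady-state abundance distribution the labeled share
of the accessible pool has the closed form

    FL(t) = 1 − (λ₁ e^(−λ₂ t) − λ₂ e^(−λ₁ t)) / (λ₁ − λ₂),
    λ₁ = k_a + μ,  λ₂ = k_m + μ,

(confluent limit handled explicitly), which the tests verify against an
independent Runge–Kutta integration to 10⁻⁸. The reported statistic is the
inaccessible share of the assembled (accessible + inaccessible) pool at
steady state,

    φ = k_m / (k_m + μ),

stated in the fit output metadata. Bulk protein follows
FL(t) = 1 − 2^(−t/T_d) (growth dilution only, no degradation — turnover in
budding yeast is growth-dominated, and degradation terms are out of scope).

**Identifiability.** With `w_free = 0` the trajectory is symmetric in
(λ₁, λ₂), so (k_a, k_m) is identified only up to a swap. The fitter
resolves this by the convention k_a ≥ k_m: entry into bait reach is at
least as fast as maturation out of it, which is the regime the assay is
designed for. In addition, because φ is steeply sensitive to small k_m, a
noise-driven k_m > 0 would otherwise inflate φ on bulk-like data; the fit
therefore also estimates the nested two-state model (k_m = 0) and keeps the
maturation rate only when an extra-sum-of-squares F-test supports it
(default α = 0.05; `null_test_alpha=None` disables the guard). Optimisation
is bounded multistart least squares on log-rates (10 starts, deterministic
given a seed; step tolerance 1e-10, gradient tolerance 1e-8).

`T_d` is an input measured per strain, never fitted; simulations default to
120 min.

## FRAP and profile statistics

FRAP traces are normalised per frame as (I_bl − I_bg)/(I_total − I_bg) —
background subtraction plus bleach correction by whole-cell intensity —
and then rescaled so the mean pre-bleach level is 1, which anchors the
mobile-fraction definition. Recovery is fitted with a single-exponential in
half-time parameterisation, y(t) = y₀ + A·(1 − 2^(−t/τ½)); the mobile
fraction is A/(1 − y₀) clipped to [0, 1] (pre-bleach level 1, fitted bleach
floor y₀). The single-exponential is the minimal model reporting a τ½; the
model used is stated in the output.

Intensity profiles with sample standard deviation (n − 1 denominator)
above a cutoff (default 200 a.u.) are excluded before correlation;
cross-channel similarity is the sample Pearson coefficient, which requires
non-constant profiles. Peak positions on 1-D membrane line profiles are
seeded at the most prominent local maxima and refined by per-peak Gaussian
least squares on ±3 initial sigmas around each seed; seeds with overlapping
windows fall back to a joint multi-Gaussian fit. Distances are between
adjacent sorted centers, in units of the profile's spatial step.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the estimators rely
on: a 0/30/60/90 min pulse grid in 3 biological replicates; tier-dependent
kinetics (early subunits: k_a = 0.2/min, φ = 0.5 → faster labeling than
bulk at all sampled times; intermediate/late: k_a = 0.01 and 0.004/min with
φ = 0 → delayed labeling; NTR/bulk reference: pure growth dilution);
per-protein abundances log-normal around 10⁵ a.u. (the bait an order of
magnitude higher — it dominates its own pulldown); per-fragment intensities
split between channels by the protein's true FL with independent
multiplicative log-normal noise of mean exactly 1 (so heavy + light is an
unbiased split of the drawn total); Bernoulli fragment-wise missingness;
and decoy fragments (flagged, non-proteotypic, b-series, two-lysine,
single-channel) carrying deliberately corrupted labeling so that any filter
failure shows up as a wrong answer, not a silent pass. Default noise
σ = 0.2 and missingness 0.05; the multi-bait screen uses a designed
early:late abundance factor of 5 for the assembly-factor protein and
11 baits (4 early, 3 intermediate, 4 late) — an 11-handle design of
desk-scale size.

Not emulated: retention-time/m-z structure, intensity-dependent
missingness (available as an option but off by default), incomplete label
incorporation (heavy-lysine labeling is assumed pure), shared-peptide
protein inference, and identification error. Passing recovery tests on
these simulations therefore validates the estimators *given* correctly
assigned, lysine-labeled fragment quantities; they say nothing about
upstream identification or extraction quality on real data.

The early-over-bulk labeling ordering holds at the sampled post-labeling
times (30/60/90 min); at asymptotically small t any two-step cascade lags
the one-step bulk curve, so the ordering is a property of the design grid,
not of every instant.

## Problem sizes and determinism

Monte-Carlo studies in the tests and the acceptance script use 20 seeds
per condition, 100 random parameter draws for the closed-form/integrator
comparison, and 100 random small instances (≤ 5 proteins × 6 precursors ×
9 samples) for the brute-force equivalence check — sizes at which the
brute-force oracle is exact and the whole suite runs in about a minute.
Every stochastic component takes an explicit seed; the CLI expands its
single global seed into per-stage seeds via `SeedSequence([seed, stage])`
with fixed stage indices, so each stage is independently reproducible and
repeated runs are byte-identical.

## Known limitations

- The three-state model is this package's concrete formulation of a
  kinetic-state analysis; the forward model sits behind a small interface
  (`ksm_forward`, `KsmParams`) so a different published variant can be
  swapped in without touching the fitting machinery.
- φ near 1 is weakly identified on a 90-minute grid (λ₂ ≫ the sampling
  rate saturates the curve); the recovery study covers φ ≤ 0.6.
- The intermixing statistic is a single end-point measure; exchange
  kinetics over incubation time are not modelled.
- Fold-enrichment scores are ranks, not tests; no significance is
  attached.
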