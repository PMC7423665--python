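# Methods

## Model

The multi-trait-dependent extinction model treats each lineage's observed
duration (origination minus extinction time, in Myr) as exponential with a
lineage-specific rate; lineages reaching the recent boundary of the study
window are right-censored there and contribute only the survival term
exp(−μt). Rates decompose into a mean rate μ₀ (events/lineage/Myr) and
per-trait multiplier simplexes, rescaled so the arithmetic mean of the
lineage rates equals μ₀ exactly. Two consequences matter in practice:
(i) μ₀ is identified by the total number of extinctions and total observed
duration alone, independent of the multipliers; (ii) multipliers are
relative risks among states, invariant to state occupancy, so a rare state
can still show a strong effect.

The multiplier simplex of a trait with N states is parameterized as a
softmax of y ∈ R^N with y₁ ≡ 0 (N−1 free parameters). The hierarchy
y ~ N(0, τ⁻¹), τ ~ Gamma(α=1.5, β), β ~ Gamma(1, 0.1) shrinks multipliers
toward uniform; μ₀ has an Exponential(1) prior. Per-trait inclusion
indicators with prior P(I=1) = 0.05 implement variable selection: an
excluded trait contributes a constant factor to every rate. Posterior
inclusion frequencies convert to Bayes factors through the prior odds
(0.05/0.95); the 2lnBF thresholds 2/6/10 (positive/strong/very strong)
correspond to frequencies 12.5%, 51.4% and 88.7%. Frequencies of exactly
0 or 1 are clamped to (1/(n+1), n/(n+1)) before conversion so reported
Bayes factors stay finite; the raw frequency is reported alongside.

### τ conditional

A coherent conjugate update for the precision of a trait's y prior is
Gamma(α + K/2, β + ½Σy²) over the K = N−1 *free* parameters. An
alternative form using N/2 and a non-squared Σy is provided behind
`MTEConfig(printed_tau_conditional=True)` for comparison; it is not the
default because it is not the conditional implied by the normal prior (its
rate can even go non-positive) and it fails the prior-recovery test. The
default is the version under which a likelihood-free run reproduces the
prior exactly (verified by KS test against the closed-form compound-gamma
marginal τ ~ 0.1·BetaPrime(1.5, 1)).

### Sampler

One MCMC sweep: a multiplicative log-normal Metropolis step on μ₀
(Jacobian included), a blockwise normal random-walk update of one randomly
chosen trait's free y, conjugate Gibbs draws of every τ and of β, and a
Metropolis flip of one randomly chosen inclusion indicator. While a trait
is excluded its y vector is refreshed directly from its prior each sweep —
the likelihood does not see it, so this is a valid Gibbs step, and it
keeps the inclusion flip reversible and well-mixed (the flip always
evaluates a prior-typical y rather than a stale one). Proposal scales
adapt toward 30% acceptance during the burn-in (first 10% of iterations)
only and are frozen afterwards, preserving detailed balance for the
retained draws; every `sampling_freq`-th post-burn-in draw is retained.
All randomness flows from one integer seed; identical seeds give
byte-identical posterior logs.

The likelihood is evaluated on species aggregated by distinct trait-state
combination (extinct counts and summed durations per combination), which
is exact and makes each evaluation O(#combinations) rather than O(S).
Replicate longevity sets (dating uncertainty) are fitted independently
with per-replicate seeds and pooled by concatenating retained samples.

Default run length mirrors a full analysis (2×10⁶ iterations, thin 1000);
the test suite and acceptance script use 2×10⁵ iterations with thinning
10–100, which this package treats as its desk-scale standard: the
conjugacy and recovery checks show the chains are well within Monte-Carlo
error of their targets at that length for problems up to ~10³ species and
a handful of traits.

## Functional diversity

Functional entities (FEs) are distinct trait-state vectors. Per time bin
(default 23 one-Myr bins, 23→0 Ma) the module recomputes FEs from the
bin's present species and reports redundancy = S_bin/n_FE and
over-redundancy = % of species in FEs whose occupancy is *strictly*
greater than the bin's redundancy — strict, so a bin where all species
share one FE scores 0 rather than 100. Empty bins are NaN, not zero.

Species-level redundancy categories follow the verbal occupancy counts of
the log10 partition: unique {1}, very low {2–3}, low {4–10}, high {11–32},
very high {>32}. The "up to 32" upper bound is kept as printed even though
⌊10^1.5⌋ = 31; the boundary affects only occupancy-32 species. The
redundancy covariate fed back into the extinction model is computed once
from the full species pool (one category per species); a per-bin variant
would make the covariate time-dependent, which the single-window model
cannot use.

Gower distance averages per-trait contributions with equal weight:
0/1 mismatch for unordered traits, rank-range-normalized absolute
difference for ordinal ones. All traits default to unordered; body-size
classes may be flagged ordinal in the scheme. The trait space is a
classical PCoA of this matrix; negative eigenvalues (routine for
non-Euclidean Gower matrices) are dropped by default, with an optional
Cailliez additive correction. The quality score of an m-axis space is the
mean squared deviation between input distances and the embedded Euclidean
distances after rescaling the latter so both maxima coincide; the chosen
dimensionality minimizes this score over 2..4 axes (capped at 4 because
hull computation cost and the point-count requirement grow quickly with
dimension). Functional richness per bin is the convex-hull volume of the
bin's species in the chosen axes as a percentage of the pool's hull; bins
with too few affinely independent points are flagged missing.

Null expectations use richness-matched random assembly: for each bin,
subsets of the observed richness are drawn from the global pool without
replacement, the metric recomputed, and the observed value tested
two-sided against the 2.5–97.5% envelope. This is the package's own
standard construction for assembly null models; on a 5-species pool it
matches exhaustive subset enumeration, and random subsets are flagged at
about the nominal 5% rate.

## Simulator

The generator emulates the structure of a fossil-assemblage analysis:
categorical traits drawn independently per trait (uniform state
frequencies unless overridden), true rates computed by the *same code
path* as the inference side (single source of truth for the rate formula),
exponential durations, and uniform origination times over the window —
the model conditions on longevities and never models origination, so any
dispersal of origins suffices and uniform is the simplest testable
choice. Defaults are a 23–0 Ma window, μ₀ = 0.3 events/lineage/Myr
(mean duration ~3.3 Myr, leaving ~15% of lineages extant at the recent
boundary — a realistic censoring fraction for a Neogene marine-invertebrate
window), S = 1000 species, and effect sizes expressed as multiplier
simplexes (a 0.75/0.25 binary trait is a threefold rate ratio). Replicate
longevity sets perturb ts and te with truncated-normal noise of scale
0.25 Myr (the order of a stratigraphic-stage dating error), preserving
ts > te, the window bounds and the extinct flag — emulating repeated age
estimation without modelling preservation itself.

What the simulator does *not* emulate: fossil preservation and sampling
(occurrence counts, gappy records), speciation-rate heterogeneity,
temporal rate shifts, and correlated traits. Passing recovery tests
therefore show the estimator is correct *given* longevities of the assumed
censored-exponential form, not that longevity estimation itself is
unbiased on real occurrence data.

## Numerical choices and limitations

- Softmax is computed with max-subtraction; rate normalization is exact,
  and the mean-preservation invariant holds to 1e-10 relative tolerance
  for every sampled state.
- Presence binning uses half-open bins (older, younger] with
  positive-measure overlap, so a lineage whose extinction time falls
  exactly on a bin edge is not double-counted into the older bin.
- Longevity censoring clamps te to the window's young boundary only for
  lineages at or below it; extinct lineages are never altered.
- Time-bin metrics treat ties in over-redundancy strictly (see above);
  quality-score ties resolve to the smallest dimensionality.
- The single-window model estimates one μ₀ for the whole window; it does
  not detect temporal rate shifts, and a strong shift can masquerade as a
  trait effect if trait states are unevenly distributed through time.
- Traits are categorical only, with complete scoring required; there is
  no missing-trait imputation.
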