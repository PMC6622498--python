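# Methods

This note documents the measurement definitions, the generative model behind
the synthetic cohorts, the numerical conventions, and the choices made where
the design was genuinely open.

## Structure metrics

**Category proportions.** Two normalizations are implemented. The default,
`per-category-size`, divides the number of produced words in a category by
that category's checklist size (43, 28, 14, 27, 7 and 7 items for ANIMALS,
CLOTHING, VEHICLES, BODY-PARTS, FRUIT, DRINKS). The alternative,
`per-total-produced`, divides by the child's total productive vocabulary.
The default was chosen because published cohort-level High/Low assignment
rates pattern with category-relative production (small categories such as
FRUIT are frequently High-density, large ones such as CLOTHING rarely),
which a raw share-of-total metric would invert; the switch is exposed in
`category_proportions(mode=...)` for users who want the other reading.

**Density assignment.** Proportions are ranked descending; a category is
High iff its proportion is at least the third-highest value. This single
rule reproduces the published tie convention (a tie between ranks 3 and 4
promotes every category at that value to High) and degrades gracefully: an
all-tied child gets six High categories and a logged warning. Ordering among
tied categories is stabilized by category name so runs are deterministic.
Children who produce nothing in the six categories follow the same
degenerate all-High path with a warning and are never dropped silently.

**Median split.** Children with total productive vocabulary at or above the
sample median are High. With an odd sample of distinct totals this yields
the (n+1)/2 vs (n−1)/2 split (40/39 at n = 79); `ties_high=False` gives the
strictly-above variant.

**Semantic network.** Nodes are the child's produced nouns; an undirected
edge joins two nouns sharing ≥ 2 perceptual and/or functional features
(taxonomic and encyclopedic features never count; matching is by exact
feature id). Degree for a target word the child does not produce is
computed, by default, on the produced-noun network augmented with the
target node and its qualifying edges — the alternative (unproduced targets
score 0) is exposed via `augment_targets=False`. GCC always uses produced
nouns only.

**Clustering quotient.** A literal "triangles divided by connected triples"
gives 1/3 on a triangle graph, contradicting the requirement that a fully
closed network score 1; the standard transitivity `3T / P` with
`P = Σ_v C(deg v, 2)` is therefore used, and `0/0` is defined as 0.
`NormsAdjacency` precomputes the all-concepts shared-feature matrix so
cohort-scale work avoids the quadratic per-child pair scan; it is verified
against the direct implementation in the test suite.

## Gaze preprocessing

Samples arrive at 500 Hz (2 ms spacing) labeled TARGET / DISTRACTOR /
OTHER_ONSCREEN / OFFSCREEN; AOI membership for coordinate input is half-open
`[x0, x0+400) × [y0, y0+400)` on a 1280 × 1024 screen, so a point exactly on
a trailing edge is outside. Bins are half-open 50 ms intervals; the analysis
window is half-open [300, 2000) ms post label onset and contains exactly 850
samples. Endpoint conventions are stated here because only the endpoints
themselves are conventional.

The trial statistic is `ln((n_T + c) / (n_D + c))` with c = 0.5 by default.
Additive smoothing keeps the statistic defined at zero counts while
preserving antisymmetry under label swap; `c = 0` is available, in which
case zero-count trials are flagged `undefined_ratio` and excluded at the
track-loss stage. Increasing c shrinks |LogGaze| monotonically toward 0.

Filters apply sequentially — comprehension rating < 2 first, then < 20%
onscreen viewing among the survivors — because the published bookkeeping
percentages are stage-relative. "Viewed the screen" counts TARGET +
DISTRACTOR + OTHER_ONSCREEN samples, consistent with timecourse denominators
that include off-AOI looks. Every exclusion lands in a ledger whose stage
counts satisfy input = excluded + retained by construction.

## Inference

`LogGazeModel` wraps a linear mixed model with a single random intercept per
item (target word), estimated by REML through statsmodels' `MixedLM`.
Participants are deliberately not a random effect in the default
specification (crossed child intercepts frequently fail to converge at this
design size); a sensitivity mode (`participants="vc"`) re-adds them as a
variance component and reports convergence. Conditions are always modeled
separately; the package never pools them into three-way interactions.

Coding: High maps to −0.5 for both density and vocabulary group; continuous
predictors are standardized with the sample SD (ddof = 1) within the
modeled subset, before interaction columns are formed. p-values use the
normal approximation on t (z-test), the convention statsmodels applies to
mixed models; every printed panel footnotes this. The fixed-effect
correlation matrix is the normalized fixed-effect block of the REML
parameter covariance. A constant response short-circuits to the exact
degenerate solution (all slopes 0, p = 1) rather than a 0/0 fit. The
estimates and standard errors agree with R's lme4 (`lmer(..., REML=TRUE)`)
to ~1e-4 on shared fixtures; that cross-check runs in the test suite.

## Synthetic cohorts

The generator emulates the study's inputs, not its participants:

- **Checklist**: the six experimental categories at their real sizes, with
  the 12 experimental items (dog, bird, banana, apple, shoe, diaper, car,
  airplane, juice, milk, nose, mouth) in place, plus filler categories to a
  400-word checklist. The unrelated pairings are FRUIT–DRINK,
  VEHICLES–CLOTHING and BODY-PARTS–ANIMALS (mouth–dog closes the last set).
- **Norms**: each concept carries idiosyncratic perceptual/functional
  features, one taxonomic category-membership feature (shared category-wide,
  so the class filter is genuinely load-bearing) and one encyclopedic
  feature. Each concept pair receives, with probability `p_within` = 0.35
  inside a category and `p_between` = 0.03 across categories, a dedicated
  perceptual + functional feature pair, so the ≥ 2 edge rule fires for
  exactly the sampled pairs and empirical edge rates equal the configured
  probabilities by construction.
- **Vocabulary sizes**: log-normal with (μ, σ) = (4.10883, 1.42433),
  calibrated numerically so the [10, 374]-truncated distribution has median
  61 and mean 92.1 words (SD ≈ 84, near the observed 76.3). Per-child
  category weights are Dirichlet with concentration 30 around
  size-proportional baselines, enough cross-child variation that density
  rankings differ between children.
- **Design**: each child's 24 trials (12 related, 12 unrelated, four blocks
  of six) give every image four appearances — twice as target, twice as
  distractor, once per role per condition, twice per side. Side polarity is
  coherent across the pairings that share an image (the only arrangement
  consistent with full counterbalancing) and flips at random per child.
- **Ratings**: produced items rate 3–4, unproduced 2–3, and any rating
  drops to 1 with probability 0.048 — placing the comprehension filter's
  expected yield at the published bookkeeping scale (~90 of ~1900 trials).
- **Gaze**: a four-state Markov chain at 2 ms steps over [0, 4000) ms. At
  each step the chain holds its state with probability 0.97 or resamples
  from the phase's stationary distribution: neutral (target = distractor)
  before the 500 ms preference latency, preference-weighted after, with
  target:distractor odds `exp(η)`,

      η = β₀ + β_cond·cond + (β_gcc·gcc_z + β_deg·deg_z + β_den·density)
            · (1 + γ_cond·group) + item intercept.

  Coefficients are per condition, because the package's target phenomenon is
  condition-asymmetric: defaults are β₀ = 0.8, β_cond = 0.25, related
  {gcc −0.4, degree 0, density −0.2} with γ = −1.5 (effects concentrated in
  the high-vocabulary group), unrelated {gcc 0, degree 0, density +0.35}
  with γ = +1.5 (concentrated in the low-vocabulary group), item-intercept
  SD 0.3. These magnitudes are anchored to the size of standardized effects
  typical of LWL studies at this design size (|t| ≈ 2–4 in the fitted
  models). Stationary offscreen mass is 0.08, but 4.5% of trials are
  "fussy" (offscreen mass 0.9), which is what the 20% track-loss filter
  catches. The stay-probability 0.97 (mean run ≈ 67 ms) was chosen so the
  window log-ratio is approximately calibrated to η: the attenuation from
  the pre-latency window share and the convexity of the log-ratio in the
  clumped counts roughly cancel, making fitted full-model coefficients land
  within ~10% of their generative values.

Determinism: every stage draws from a dedicated child of one seed sequence
and every trial's gaze stream from a substream keyed by trial index, so the
same (config, seed) reproduces a cohort byte for byte and trial order never
changes draws. The realized coefficients and item intercepts serialize to
JSON (`SimTruth`) as the oracle for recovery tests.

**What the generator does not emulate**: saccade dynamics, fixation-duration
distributions, anticipatory baseline biases, side biases, trial-order and
fatigue effects, or any dependence of gaze on age. Passing recovery tests
therefore shows the pipeline recovers effects under a faithful rendering of
the design and statistic — not that the Markov chain is a model of toddler
oculomotor behavior, and not that effects of these sizes are guaranteed
detectable in real data.

## Problem sizes

The recovery and calibration studies use the full design size — 79 children
× 24 trials — with 100 replicate cohorts for effect-sign recovery and 200
for null calibration (400 condition-model fits), sharing one norms database
across replicates as a single study would. The null rejection band checked
is [0.02, 0.10] at α = .05 per structure term.

## Known limitations

- `MixedLM` occasionally warns near the random-intercept variance boundary;
  results are flagged via `converged` rather than re-tried with alternative
  optimizers.
- The z-test p-values are mildly anticonservative at 12 items relative to
  Satterthwaite-type corrections; the null-calibration test bounds the
  practical effect.
- The file-input path expects pre-labeled AOI states or raw coordinates per
  sample; fixation parsing, drift correction and calibration are upstream
  concerns and out of scope.
- With `per-total-produced` normalization the density assignment of very
  small vocabularies is dominated by a handful of words; the warning-laden
  degenerate paths are kept deliberately loud.
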