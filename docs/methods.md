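# Methods

This note documents the models and procedures implemented in `rangerisk`,
the defaults they ship with, and what the synthetic validation does and
does not demonstrate.

## Pipeline overview

For each species with at least `min_records = 4` occurrence records:

1. **Predictor screening** (once, on the current-scenario stack): drop one
   member of every variable pair with Pearson |r| > 0.8, then iteratively
   drop the variable with the largest variance inflation factor until all
   VIF ≤ 10. The retained set is frozen for all projections.
2. **Replicated maximum-entropy fit**: 7 replicates, each with a random
   75/25 train/validation split of the (cell-deduplicated) presences and a
   uniform background sample of up to 100,000 unmasked cells; per-replicate
   logistic suitability maps are averaged cell-wise, and train/test AUC is
   averaged across replicates.
3. **Binarization**: Fisher–Jenks four-class natural breaks fitted on the
   current averaged suitability; the range is the union of the upper three
   classes; areas are geodesic (spherical Earth, R = 6371 km).
4. **Projection**: every replicate model is projected onto each
   scenario × horizon stack (features clamped to training bounds), the
   projections averaged, and the *current-fitted* breaks reapplied.
5. **Threat classification**: loss fraction L = (A_now − A_future)/A_now is
   mapped to EX (L = 1), CR (≥ 0.8), EN (≥ 0.5), VU (≥ 0.3), NT (≥ 0.1),
   LC (otherwise, including expansions, which are flagged).

Species below the record minimum bypass the model. Their baseline category
(default LC, overridable per species) is elevated by the record-geometry
cascade — 3 records: triangle area < 100/500/10,000 km² → +3/+2/+1 levels;
2 records: great-circle distance < 10/50/500 km → +3/+2/+1; 1 record: +3 —
and held constant between the mid- and late-century horizons, since a
model-free assessment carries no trend information. Elevation caps at CR:
EX is reserved for demonstrated total range loss.

## Model assumptions

- **Presence–background**: only presences and landscape cells are used; the
  fitted Gibbs distribution q(x) ∝ exp(λ·z(x)) matches presence feature
  means up to the per-feature penalty slack (the KKT condition
  |E_q[z_j] − mean_P[z_j]| ≤ β_j holds at any interior optimum, and is
  asserted in the tests).
- **Feature classes** are linear + quadratic per variable (pairwise
  products optional, off by default). Quadratic features suffice to
  represent any axis-aligned Gaussian response; interactions or multimodal
  responses need products or more features and will be approximated.
- **Logistic output** p = e^H q/(1 + e^H q), H the entropy of the fitted
  background distribution: a uniform (uninformative) model scores exactly
  0.5 everywhere, and typical presence-like cells score near 0.5+.
- **Projection clamping** (default on) freezes the response beyond the
  training climate envelope instead of extrapolating the exponential.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `min_records` | 4 | records | below this, models are unreliable; the geometry cascade applies |
| `train_fraction` | 0.75 | — | conventional 75/25 split; validation forced nonempty |
| `background_cap` | 100,000 | cells | standard background ceiling; full scan on smaller grids |
| `r_max` / `vif_max` | 0.8 / 10 | — | conventional collinearity cutoffs |
| `n_replicates` | 7 | — | averaged map; per-replicate AUC always logged |
| `n_classes` | 4 | — | non/low/medium/high habitability |
| `beta` (b) | 0.05 | — | penalty β_j = b·sd_j/√m; slack tracks presence-mean sampling error |
| fit `tol` / `max_iter` | 1e−5 / 500 | — | relative-objective convergence of L-BFGS-B |
| Jenks / screening subsample | 10,000 | cells | seeded; exact on smaller grids |

The L1 weight's 1/√m scaling matters: a fixed β_j grants the fitted means a
constant slack regardless of evidence, which visibly broadens narrow niches
(we measured fitted envelopes several times wider than truth under a fixed
weight); scaling by the standard error of the presence means removes that
systematic blur while keeping the sparsity behaviour for small samples.

The optimizer is L-BFGS-B on the exact non-negative split λ = λ⁺ − λ⁻ of
the penalized concave objective. Sharp niches put the optimum at
coefficient magnitudes of several hundred along directions of nearly flat
curvature, where first-order (proximal) updates need tens of thousands of
iterations; the quasi-Newton solve reaches the same optimum (verified
against an independent derivative-free solver to 1e−3 objective units) in
tens of iterations.

## Numerical and convention choices

- **Split sizing**: training size = round-half-to-even of fraction × n,
  clamped so both sides are nonempty.
- **Cell membership** is half-open, [west, east) × [south, north); presences
  are deduplicated to one per cell before fitting.
- **Correlation-stage tie-break**: from the worst pair, drop the variable
  with the larger mean |r| against the remaining variables — deterministic
  and order-independent. Constant layers get correlation 0 with a warning.
- **VIF** is recomputed after every drop (one-shot removal can strand
  variables above the cutoff); perfect collinearity returns +inf.
- **Jenks** runs on unique values with multiplicities, so thresholds are
  always strictly increasing; the divide-and-conquer DP is exact (equal to
  exhaustive partition search on every instance tested). Values equal to a
  break go to the upper class. Breaks are fitted on the current map and
  reused for future projections — per-scenario refitting would confound
  range change with threshold drift.
- **EX tolerance**: L ≥ 1 − 1e−12 counts as total loss, absorbing
  floating-point dust in area sums.
- **Triangle areas** (3-record rule) use a planar shoelace under an
  equirectangular projection at the points' mean latitude — adequate at the
  sub-continental scales where the cascade's cutoffs bite; collinear or
  duplicate points give area 0.
- **Per-species seeds** derive from CRC32(master seed, species id), so
  adding or removing one species never perturbs another's results; the
  whole report bundle is byte-reproducible from (config, seed).
- **Richness** counts a species in a one-degree cell iff any flagged
  native-resolution cell overlaps it.

## The synthetic study

The generator builds what the pipeline needs with exact ground truth:

- **Climate**: a temperature-like layer (latitudinal gradient
  28 − 0.52·|lat| °C plus a gentle longitudinal harmonic), a
  precipitation-like layer (longitudinal sine, 500–1900 mm), optional
  auxiliary decoy layers, smooth seeded noise, and an optional
  near-duplicate layer to exercise the correlation filter. Default grid:
  90 × 180 cells at 2° (a 10-arc-minute grid is available through the same
  `GridSpec` for realism runs).
- **Scenarios**: additive per-variable shifts standing in for GCM deltas;
  defaults approximate moderate and high-emission warming at mid- and
  late-century (+1.4 to +3.3 °C, small precipitation increases).
- **Virtual species**: Gaussian suitability in (temperature, precipitation)
  with diagonal covariance; the truth range is the superlevel set
  suitability ≥ s\* = 0.1. The 10%-of-peak threshold treats the full
  tolerable envelope as range, matching the inclusive low+medium+high range
  definition used downstream; empirically the lowest Jenks break lands near
  the same contour, so truth and estimate binarize comparably. Niche
  centers sweep −11 to 22 °C — inside the landscape's realized climate
  envelope with roughly a two-sigma margin, because a species whose optimum
  occurs in no attainable climate has a truncated niche that no
  presence-based model can identify and would confound recovery with an
  unlearnable truth. Cold-margin species lose range poleward; equatorial
  species can expand when warming splits their band into two hemispheric
  ones.
- **Presences** are drawn cell-wise ∝ current suitability (with
  replacement, as real datasets repeat locations) at cell centers; fixed
  1/2/3-record geometries exercise every branch of the data-poor cascade.

With 20 such species the pipeline recovers the true loss fraction with a
mean absolute error of ~0.02–0.03 and assigns the truth-implied category
for ≥ 90% of species whose truth lies clear of the category cutoffs
(see `scripts/acceptance.py`).

**What this does not show.** The landscape is smooth and stationary; real
climate surfaces have topographic structure the generator omits. Presence
sampling is unbiased, whereas real records carry strong spatial effort
bias. Niches are axis-aligned Gaussians — exactly representable by the
default features — so recovery here bounds what the machinery can do, not
what messy data will give. Scenario deltas are spatially uniform;
real GCM deltas are not. Passing the synthetic suite therefore validates
the *implementation* (estimator, thresholds, bookkeeping, determinism),
not the ecological fidelity of any particular real-world application.

## Known limitations

- Hinge/threshold features and sampling-bias correction are not
  implemented; byte-compatibility with other MaxEnt implementations is a
  non-goal (the objective, not the binary, is the contract).
- The logistic transform compresses high suitabilities, which pulls the
  lowest Jenks break to a slightly lower suitability contour than the same
  break fitted on the raw scale; for species hugging the poleward climate
  margin this can bias estimated loss low by up to ~0.1.
- The baseline category for data-poor species is LC unless supplied;
  elevation from an assumed floor is a rule, not an inference.
- Expansions (L < 0) are reported as LC with an expansion flag; no
  down-listing logic is applied.
- The one-degree richness maps count binary ranges; they are not
  habitability-weighted.
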