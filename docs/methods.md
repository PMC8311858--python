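# Methods

## The analysis model

The pipeline treats a resting-state scan as an ROI-by-time matrix and a
subject's connectome as the matrix of Fisher-z-transformed Pearson
correlations between ROI signals (diagonal stored as 0 and ignored; |z|
capped at atanh(1 − 1e−7) so perfectly correlated signals stay finite).
Binary graphs are obtained by proportional thresholding: at proportion `p`
exactly `round(p·n(n−1)/2)` node pairs with the largest **signed** z-values
become edges.  Signed rather than absolute ranking is used because a
strongly negative correlation is not a "strongest connection"; an
absolute-value variant is available behind a flag for sensitivity
analyses.  Rounding is half-away-from-zero and ties are broken by
ascending (i, j) node order — ties are measure-zero for real data but
common in toy fixtures, and a deterministic rule makes runs bit
reproducible.

All node-level metrics are computed against a single *reference modular
partition*, never re-estimated per subject: system segregation of a node
is only interpretable relative to a fixed system decomposition.  The
reference is derived from the healthy-control group-mean z-matrix by
agglomerative clustering with Ward's criterion, where each node's feature
vector is its row of the mean matrix (diagonal zeroed, Euclidean
distance), cut to exactly k clusters.  This is the most literal reading of
clustering "the averaged correlation matrix"; treating 1 − r as a
precomputed distance is incompatible with exact Ward updates and is not
offered.  k is a required configuration value with default 7; no selection
criterion is pretended — a silhouette profile over k = 2..12 is reported
as guidance only (on the synthetic cohort it does peak at the planted
k = 7).

The participation coefficient `PC_i = 1 − Σ_m (k_i(m)/k_i)²` is computed
per threshold and averaged with equal weights; per-threshold values are
retained for reporting.  Isolated nodes get PC = 0 (no connections means
no connectivity diversity); this matters at sparse thresholds.
Within/between-module and per-hemisphere connection counts are read from
the same binary graphs as the PC computation and averaged over thresholds,
so they are fractional.  Conservation identities (within + between = mean
degree; per-module counts sum to mean degree; left + right counts
reproduce whole-brain counts) are enforced by construction and tested.

## Statistical battery

All models are ordinary least squares (statsmodels) or classical t-tests;
nothing is fit stochastically, so results are exactly reproducible.
Factor coding is fixed: gender reference F, treatment-arm reference sham,
cohort reference healthy-control.  Covariates enter uncentered in their
natural units.

* Pre-treatment, two separate fits (value = the node's threshold-averaged
  PC): `value ~ cohort + age + education + gender + motion` over everyone,
  and `value ~ severity + age + education + gender + motion` over patients
  only.  Two fits rather than one joint model keep the severity slope a
  patients-only quantity.
* Treatment: `Δvalue ~ arm + severity + age + education + gender + motion`
  (Δ = post − pre per patient), then per-arm paired t-tests and
  per-timepoint independent t-tests against the control group.
  Independent tests default to the pooled-variance Student form — with 16
  patients vs 19 controls that gives the df = 33 reporting pattern — with
  Welch behind a flag.
* Brain-behavior: `gain ~ ΔPC × arm + severity + age + education + gender`
  (no motion term in this model), with per-arm simple Pearson correlations
  reported alongside the interaction.
* Per-module comparisons of the target's connection counts against
  controls are corrected with a hand-rolled Benjamini-Hochberg step-up
  (cross-checked against statsmodels) **within the family of between-module
  tests of one analysis**; the primary target-node tests are reported
  uncorrected, and the own-module comparison is outside the FDR family.

Degenerate inputs are flagged rather than silently propagated: zero
within-pair variance with a nonzero mean difference yields an infinite t
with p = 0; rank-deficient designs and missing covariates raise errors
naming the subject and field.

## The synthetic cohort

The generator emulates the statistical skeleton of the study, not its
physiology.  Defaults: 76 nodes (38 per hemisphere, homolog pairs), 7
planted bilateral modules, 19 healthy controls scanned once, 16 + 16
patients scanned pre and post, severity uniform on 1–15 (a 0–15 dementia
rating scale; controls are 0), ages/education/gender drawn per group from
the study's demographic tables, scan length T = 210 samples with an option
for mixed-length cohorts (210/156-style two-protocol designs).

Signals are zero-mean multivariate normal draws from a two-level block
correlation matrix: `within_r = 0.5` inside modules, `between_r = 0.1`
across.  One target node (the left IFG-triangularis label) is perturbed:
its between-module correlations are `between_r + 0.02·severity`, minus a
flat `0.15` at the post-timepoint in the active arm only.  Perturbed
matrices are repaired to the nearest positive semi-definite correlation
matrix by eigenvalue clipping and rescaling; repair aborts if any entry
would drift more than 0.05, which would mean the planted contrast was
destroyed.  Behavioral gain (percent of maximal gain, 0–100) is by default
uncoupled noise; `make_behavior_gain` regenerates it from the *realized*
PC changes, standardized within arm, with per-arm slopes — the planted
brain-behavior interaction is the slope difference.  The effect-condition
coupling (slopes −10/+10, noise 8) plants a within-arm association of
|r| ≈ 0.78, the magnitude of the strong per-arm correlation the analysis
is designed to detect.

Seeding: one global seed fans out to per-subject substreams via
`SeedSequence(seed, spawn_key=(subject_index, stream))`, so adding a
subject never changes another subject's data, and cohorts are bit
reproducible.

What the generator does **not** emulate: hemodynamic autocorrelation,
scanner drift and motion artifacts, atrophy, spatially structured noise,
or heavy-tailed connectivity distributions.  Passing tests therefore show
that the pipeline recovers planted effects from correlation-level
structure at realistic sample sizes — not that such effects are present or
detectable in any particular real dataset.

## Study conditions for the Monte-Carlo checks

* Type-I calibration uses T = 60 samples per scan: under the all-null
  design the models' calibration does not depend on T, and short scans keep
  500 replicates affordable.  Measured rejection rates at α = 0.05 fall in
  [0.03, 0.07] for every model.
* Effect-recovery uses T = 1000.  The choice is a design trade-off probed
  before freezing: detection of the severity gradient *degrades* at very
  large T because edge retention saturates — once correlation noise
  (~1/√T) is small relative to the planted contrasts, every elevated edge
  of every patient is retained at the wider thresholds and the PC response
  flattens across the severity range.  T = 1000 keeps all detection rates
  above 88% over 200 replicates while one replicate costs well under a
  second.
* "Normalization" of the target's between-module count is checked as the
  post-treatment elevation over controls falling below half its
  pre-treatment size, not as raw non-significance: the planted flat
  treatment reduction (0.15) cancels the *average* severity elevation
  (0.02 × mean severity ≈ 0.16) but not each subject's exactly, and at
  T = 1000 even a 0.01 residual correlation offset is statistically
  visible.  Truly null components (sham change, control-ROI arm effects)
  are required to reject in ≤ 20% of replicates; measured rates sit at
  0–10%.  Control-ROI rates run slightly above α because proportional
  thresholding is global: shifting ~65 target-node edge values moves the
  retention cutoff for everyone, a small real spillover of rank-based
  thresholding rather than a defect of the tests.

## Known limitations

* Gaussian, temporally white signals make T an optimistic proxy for real
  effective sample size (autocorrelated BOLD data carry fewer independent
  samples per scan).
* The Ward feature representation (rows of the mean matrix) is one of
  several defensible readings of clustering a correlation matrix; results
  on real data could differ under a distance-matrix reading.
* The per-module FDR family is fixed to the between-module comparisons of
  one analysis; changing the family definition changes corrected p-values.
* The flat treatment effect is a simplification; a severity-proportional
  effect would make post-treatment normalization exact but adds a free
  parameter the planted design does not need.
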