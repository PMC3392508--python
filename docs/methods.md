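# Methods

## Trocar kinematics

The instrumented trocar is modelled as an ideal fixed pivot.  A 4-DOF
sample (θ₁, θ₂, d, roll) maps to the instrument tip at
R_y(θ₂) · R_x(θ₁) · (0, 0, −d), pivot at the origin, z pointing out of the
box toward the operator.  Tracking hardware of this kind does not define a
canonical rotation convention; extrinsic R_x-then-R_y is the simplest
gimbal model consistent with a pivoting port, and it is isolated in one
function so an intrinsic order or different axis pairing can be swapped
without touching anything downstream.  Two consequences are load-bearing
and tested: ‖tip‖ = d exactly (rotations preserve norm), and roll never
moves the tip (it spins the instrument about the axis the tip lies on).
Roll is carried through the data model anyway — dropping a measured channel
silently would make file round-trips lossy.  Depth 0 maps to the origin for
any tilt angles; it is a valid (degenerate) configuration, not an error.
Angles are degrees in files and public types; radians are internal.

## Motion analysis parameters

Definitions are in the README.  Non-obvious choices:

- **Angular area** is the axis-aligned bounding rectangle of the tilt
  excursions, (range θ₁)·(range θ₂).  "Workspace spanned by the farthest
  orientations" admits several formalisations with deg² units; the range
  product is the simplest and the one whose magnitudes line up with
  published reference values.  The convex-hull area of the tilt scatter
  (always ≤ the rectangle) is available via `angular_area(..., method="hull")`.
- **Volume** is the convex hull of the tip points, not a bounding box:
  "space used" means the occupied hull.  Fewer than four points, or a
  collinear/coplanar set, occupy zero volume and return 0 rather than
  raising — degenerate workspaces are real data (a novice holding one hand
  still).
- **Insertion distance** implements the total-variation definition
  Σ|Δd| literally.  Published reference values for this MAP (≈15–19 mm over
  multi-minute trials) are far smaller than a literal total travel would
  give, suggesting the original hardware reported a normalised or averaged
  quantity; the definition is implemented as stated and the discrepancy is
  noted rather than resolved.  Nothing downstream depends on its scale
  (features are standardised before classification).
- **Time** comes from timestamps, not sample counts, so jittered or gapped
  recordings report wall-clock duration.  Per trial, time is the longer of
  the two hands' durations.
- No smoothing is applied before metric computation by default; a box-car
  `moving_average` exists for noisy recordings but every shipped pipeline
  leaves it off, so computed MAPs are a pure function of the raw samples.

## Synthetic data

Two generator tiers emulate a validation study's data.

**MAP-level cohorts.**  Published tables give only marginal means and SDs
per group — no correlations, no raw trials.  `sample_map_cohort` therefore
draws each of the nine components independently from a zero-truncated
normal.  Naive truncation of N(mean, SD²) at zero would inflate the
realised mean whenever mean/SD is small (for the expert left-path
distribution, mean 2792.92, SD 1733.70, the shift is ≈200 mm); instead the
underlying (μ, σ) are solved numerically so the *truncated* distribution's
mean and SD equal the published values exactly.  A solution exists whenever
SD/mean stays below the half-normal limit ≈0.756; the largest ratio among
the 18 reference distributions is 0.66.  Component independence is a known
simplification: real MAPs are positively correlated (a slow trial is long
in path and time at once), which makes the independent cohorts somewhat
*easier* to separate multivariately (summary Mahalanobis distance ≈3.9)
than the real data presumably were.  Hooks for a correlation structure
exist in the design but default to none, because no published
parameterisation is available.  Consequently, classification accuracy on
these cohorts (≈99% resubstitution) should be read as "at least as
separable as the published 95.7%", not as a reproduction of the printed
Wald values, which depend on the unpublished correlation structure.

**Trajectory tier.**  `simulate_trajectory_pair` builds each hand's 100 Hz
stream as a sequence of minimum-jerk point-to-point submovements
(position profile 10τ³ − 15τ⁴ + 6τ⁵, the standard smooth primitive of human
reaching) between targets drawn uniformly inside the profile's angular and
depth spans, with band-limited Gaussian tremor (white noise box-car
filtered over 9 samples, rescaled to the profile's RMS amplitude) added to
the tip-equivalent angles and to depth.  Submovement duration is tip
distance / mean speed with a 0.12 s floor; recording stops at the task
duration cap (default 300 s, the conventional task time limit — novice
trials often run into it, matching the observation that novices rarely
finish a knot in time even though their *recorded* mean time sits below the
cap).  Default profiles (novice: 350 submovements at 25 mm/s, tremor
0.08 mm RMS, tilt half-range 6.5°, depth span 30 mm; expert: 200 at
32 mm/s, 0.02 mm, 5°, 18 mm) encode the robust empirical contrast — experts
make fewer, faster, steadier movements in a tighter workspace — and yield
expert < novice in expectation on all nine computed MAPs (verified over 50
seeds).  The simulator is a motor-control caricature, not a biomechanical
hand model: it has no task structure (no needle, no knot), no learning
within a trial, and no inter-hand coordination, so it validates the
kinematics → metrics → statistics chain, not surgical realism.

**Likert questionnaires.**  Items are parameterised by per-group probability
vectors over scores 1–5.  `likert_probs_from_mean_sd` reconstructs a vector
from a published (mean, SD) by moment-matching a normal discretised at bin
edges {1.5, 2.5, 3.5, 4.5}; shipped defaults cover nine face/content items
for expert and trainee groups.  Real questionnaire data are integer-valued,
item-correlated within respondent and sometimes missing; the generator
reproduces only the marginal score distributions.

All generators are pure functions of (parameters, seed); numpy
`SeedSequence` spawning keeps hands, trials and cohorts on independent
streams.

## Statistics

- **Per-MAP comparison**: two-group one-way ANOVA ≡ pooled-variance t-test
  (F = t²).  The pooled form is the default because it is the classical
  follow-up to a MANOVA and reproduces published per-MAP p-values computed
  from group summaries; Welch (Satterthwaite df) is available.  Both-SDs-zero
  inputs are degenerate: t = 0 / p = 1 on equal means, p = 0 flagged
  `degenerate` otherwise.
- **MANOVA**: for two groups all classical statistics reduce to Hotelling's
  T², computed directly with the exact F transform
  F = T²(n−p−1)/(p(n−2)) on (p, n−p−1) df.  A pooled covariance with
  condition number above 10¹² is ridge-regularised (λ = 10⁻⁸ × mean
  diagonal) and the result flagged.
- **Mann–Whitney U**: exact path enumerates every assignment of the pooled
  values to groups when min(n_x, n_y) ≤ 8 (and the C(n, n_x) budget ≤
  5·10⁵), handling ties by midranks, with two-sided
  p = P(min(U_x, U_y) ≤ observed); otherwise a normal approximation with
  midrank tie correction and 0.5 continuity correction (the convention
  appropriate for heavily tied Likert data).
- **Categorical**: Pearson χ² without continuity correction; Fisher's exact
  two-sided p sums hypergeometric masses ≤ the observed table's mass (the
  probability-mass convention — stated because two-sided Fisher rules
  differ between packages).  The questionnaire pipeline switches from χ² to
  Fisher whenever any expected cell count is below 5.
- **Multiplicity**: no correction across the nine MAPs by default, matching
  the analysis convention of the reference tables; Holm step-down is an
  opt-in flag.

## Classifier

One pooled logistic regression of group on all nine MAPs (not per-hand
models).  Features are z-scored first: units spanning five orders of
magnitude would otherwise make the numerical fit ill-conditioned and the
Wald ranking unit-driven; raw-scale coefficients remain recoverable from
the stored scaling.  Fitting is IRLS on the ridge-penalised log-likelihood
(penalty ½λ‖β₋₀‖², intercept unpenalised), convergence when the largest
coefficient step falls below 10⁻⁸, standard errors from the inverse
penalised observed information.  The default λ = 10⁻⁴ exists because
expert and novice task times barely overlap: near-separation sends the MLE
toward infinity and voids Wald inference.  If a fit still lands in the
separated regime — detected as any standardized slope exceeding 10, i.e.
an odds ratio above e¹⁰ per SD, which no overlapping data produce — λ is
escalated tenfold (warning emitted, escalation recorded in the model and
report provenance) until the estimates are finite and stable.  With λ = 0
on overlapping data the fit matches an independent maximum-likelihood
optimiser to 10⁻⁶ (tested against statsmodels).  Classification threshold
is 0.5 with probability-equal-to-threshold assigned to the expert class (a
documented tie-break; the choice is invisible in practice).  Accuracy is
resubstitution (training-set) accuracy — the figure simulator-validation
studies report — and is optimistic relative to held-out accuracy by
construction; cross-validation is deliberately out of scope.

## Problem sizes and tolerances

Test and acceptance runs use the study-scale cohorts (59 novices, 56
experts) throughout; stochastic properties average 20–50 seeded replicates
(classification accuracy, Wald-rank dominance, trajectory contrast), null
calibration uses 2500 replicates of the summary t-test, and parameter
recovery uses n = 2000 (logistic slope) and n = 5000 (cohort moments,
checked against the 3·SD/√n CLT band).  Geometry oracles are exact to
relative 10⁻⁹.  Exact Mann–Whitney enumeration is cross-checked against a
rank-free brute-force permutation oracle for all n_x + n_y ≤ 12 cases
sampled.

## Known limitations

- MAP components are generated independently; multivariate statistics on
  synthetic cohorts (T², Wald values) are not comparable to values from
  correlated real data, only their qualitative structure is (time dominant,
  all means ordered).
- The per-MAP univariate power implied by the published effect sizes is
  modest for the weakest effects (right angular area ≈0.6 per cohort), so
  single synthetic cohorts reproduce "significant on all nine MAPs" only in
  a majority of replicates, not always.
- The kinematic convention is declared, not measured; a different gimbal
  ordering changes tip paths (path length, volume) slightly but leaves
  depth- and angle-based MAPs untouched.
- The trajectory simulator's insertion-distance scale follows the literal
  total-variation definition and is therefore not comparable to published
  depth summaries (see above).
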