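# Methods

`penguinflow` implements a two-stage behaviour-classification workflow for
penguin-borne accelerometer records and the downstream energetics it feeds,
together with a synthetic deployment generator that provides ground-truth
labels for validation.  This note documents the models, the defaults and the
reasoning behind the open design choices.

## The analysis in brief

Raw tri-axial acceleration (surge, sway, heave; g) sampled at 25 Hz — or
decimated from 100 Hz — is decomposed into *static* acceleration, a 2 s
centred running mean capturing gravity and hence posture, and *dynamic*
acceleration (raw − static) capturing body motion.  From these we derive

- pitch = atan2(a_surge^st, sqrt((a_sway^st)² + (a_heave^st)²)) · 180/π,
- roll = atan2(a_sway^st, a_heave^st) · 180/π,
- VeDBA = ‖(a_surge^dyn, a_sway^dyn, a_heave^dyn)‖,

plus rolling standard deviations of the raw axes over 2/10/30/60 s windows,
of roll over 30 s and of pitch and VeDBA over 60 s (centred windows,
population SD, shrinking at the edges).  Pressure (1 Hz, mbar) is zeroed on
the mode of its distribution (1 mbar bins — the logger's resolution) and
divided by 100 to give depth in metres; its first difference is the
per-second depth-change rate.  1 Hz channels are upsampled to 25 Hz by
sample-and-hold.

Each foraging trip (bracketed by water-temperature/depth signatures; trips
split on ≥ 30 min of land signature) is partitioned into coarse subsets —
*diving* (submerged episodes exceeding 2 m for Adélie, 1 m for little
penguins, strict), *land/ice* (Adélie only, positive temperatures) and
*surface* — and per trip and subset a full-covariance Gaussian mixture is
fitted by EM over the subset's variable set:

- diving: VeDBA, pitch, SD of heave over 2 s, depth change;
- surface and land/ice: VeDBA, pitch, SD of heave over 10 s, SD of roll over 30 s.

Variables are centred and scaled (population SD).  EM restarts from random
row-sampled centres (pooled covariance, uniform weights), uses log-sum-exp
responsibilities in the E-step and weighted MLE with a 10⁻⁶ diagonal ridge in
the M-step, and stops when the relative log-likelihood change falls below
10⁻⁶.  The cluster count K minimises BIC = −2·logL + p·ln n with
p = K−1 + Kd + Kd(d+1)/2, inside behaviourally motivated bounds: 3–8 while
diving, 2–5 at the surface/on ice when the trip contains dives, 2–8
otherwise.

Clusters are mapped to named behaviours by a deterministic rule table on the
*unscaled* cluster centroids (thresholds in `LabelRules`), replacing manual
visual assessment.  The rules are per-cluster thresholds rather than
winner-take-all comparisons, so when BIC splits one behaviour across several
clusters each fragment still receives the same name: a centroid with mean
depth change above +0.5 m/s is a descent (a descending bird meets rising
pressure; sample-and-hold of the 1 Hz depth signal gives bout-transition
samples intermediate rates, hence the threshold sits at roughly half the
slowest realistic vertical travel speed rather than near zero), below
−0.5 m/s an ascent; remaining diving centroids with VeDBA > 0.5 g are
hunting, the rest swim/cruise.  Surface centroids: VeDBA < 0.06 g is `still`
(little penguins only), roll-SD > 12° preen/flap on water, VeDBA > 0.45 g
porpoising, otherwise slow surface swimming.  Land/ice: pitch > 60° splits
into walk/stand on VeDBA 0.2 g; pitch ≤ 20° is lying/tobogganing; the rest
preen/flap on land.  The rare `swim_cruise_2` variant is folded into
`swim_cruise` before any supervised training.

The supervised stage draws, per trip and behaviour class,
n\* = min(⌊smallest-class-size/2⌋, 1000) rows uniformly without replacement —
leaving at least half of every class for testing — after adjusting pitch by
the per-deployment median of near-surface reference samples (depth ≥ 2 m and
pitch < 60° for Adélie; depth ≥ 1 m for little), which removes
tag-attachment differences.  A random forest with mtry = 4 predictor
variables per split is trained over a tree-count grid (100/500/1000/1500 by
default) on a stratified 75/25 split, selected on minimal OOB-error decrease
(within 0.002 of the grid minimum), with optional 10-fold cross-validation
and one-vs-rest ROC/AUC on the hold-out.  The twelve predictors are VeDBA,
adjusted pitch, depth, depth change, the four heave SDs, roll SD (30 s),
pitch SD (60 s), VeDBA SD (60 s) and surge SD (2 s).

Two study designs are run end-to-end: *one-season* (train on all Season-1
trips, predict Season-1 hold-out rows and all of Season 2) and *two-season*
(⌊smallest-season/2⌋ trips sampled per season; agreement reported in four
role × season groups).  Agreement is the raw proportion of samples given the
same class by both routes, per trip.  Repeatability
R = V_between/(V_between + V_within) of pitch and VeDBA within each
behaviour uses the one-way Lessells–Boag moment estimator with the
unbalanced-design coefficient n₀ and the individual bird as the group.

For energetics, fine classes aggregate into three coarse components —
preen/flap-on-water, water (all swimming and within-dive classes, including
`still`), land/ice — and the activity-specific VeDBA of component c is
V_c = Σ_{i∈c} VeDBA_i / n_trip, so Σ_c V_c equals the trip-mean VeDBA
exactly.  Daily energy expenditure follows the linear calibration form

    DEE = β₀ + β_sex·1[male] + Σ_c β_c·V_c   [kJ/day],

total trip energy = DEE · hours/24.  The calibration coefficients are a
required configuration input with a provenance field; the package ships only
synthetic placeholder values, clearly flagged, and the test suite validates
the computation in a closed loop (data generated from the same linear form
are recovered exactly).  Method agreement is assessed with OLS fits of
DEE_EM on DEE_RF, with coarse-budget differences as optional covariates,
compared by AIC, with collinearity (|r| > 0.8) flagged.

## The synthetic generator

The generator emulates penguin foraging deployments with known labels.
Behaviour sequencing is a semi-Markov chain (exponential dwell times
truncated at 1 s) organised into a land block, an at-sea period alternating
surface phases with explicit dive cycles (descend to a uniform random target
depth at the configured vertical speed; a bottom phase alternating
hunting/cruising; an ascent timed to return exactly to the surface), optional
short on-ice rests (Adélie), and a closing land block.  Default grammars
carry 12 classes for Adélie and 10 for little penguins; `swim_cruise_2` is a
distinct rare state whose emission parameters deliberately equal
`swim_cruise`'s (its separate signal structure is disabled), and the little
penguin repertoire includes `still` (floating rest) and a single land-context
class (`walk`, colony attendance) in place of the Adélie ice classes.

Emissions construct the gravity vector from the behaviour's target pitch/roll
through the inverse of the pitch/roll equations above, guaranteeing
self-consistency with the feature stage, and add: AR(1) posture jitter
(τ ≈ 1 s), a slow roll oscillation (0.08 Hz — slow enough to survive the 2 s
running mean) whose amplitude drives the roll-SD signature of preening, and
white per-axis dynamic noise.  Hunting adds a 3 Hz sinusoidal heave wiggle
mimicking prey-pursuit signatures.  The per-axis noise scale is calibrated
analytically (Gauss–Hermite quadrature of the expected dynamic-vector norm,
including the ~1 % shrinkage from subtracting the 2 s window mean) so the
VeDBA recovered by the feature stage matches the configured mean; bout-level
intensity jitter (`vedba_sd_g`) adds realistic within-behaviour variability.

Per-individual mean shifts of pitch (SD 3°) and VeDBA (SD 0.02 g) are drawn
once per individual, a season effect (+2°, +0.02 g in Season 2) reflects
between-season differences, and every deployment receives a tag-attachment
pitch offset (SD 5°) that the pitch-adjustment step is designed to remove.
Surface behaviours sit at a sensor draft of ~0.35 m with slow bobbing, so
surface samples read water temperature (the sensor is submerged) while the
shallow episodes are still reassigned to the surface subset by the dive
filter; land samples read the land temperature.  Pressure is
atmospheric + 100·depth + 0.3 mbar sensor noise; the concentrated land
readings anchor the pressure mode at the surface value.

The `separation` parameter scales the between-behaviour contrast of the
pitch/VeDBA/amplitude emissions around their pooled means (0 = identical
emissions, 1 = defaults).  Vertical speeds are deliberately not scaled: they
are the kinematic scaffolding of the dive profile, and collapsing them would
remove dives altogether rather than blur their signals.  Consequently at
separation 0 the surface/land variable sets carry no class information while
depth change remains informative within dives.

What the generator does *not* emulate: GPS tracks, tidal or wave pressure
noise, magnetometer channels, temperature inertia, behavioural rhythms
(bout-duration autocorrelation, diel structure), prey-driven non-stationarity
and inter-class signal overlap as severe as in field data.  Classification
scores on synthetic data are therefore upper bounds of field performance;
passing tests demonstrate the correctness and internal consistency of the
pipeline, not field-grade accuracy.

## Problem sizes and numerical choices

Default study conditions are a desk-scale twin of a two-season field
campaign: 20 individuals per season × 1 trip × 2 seasons, with ~6 min at sea
(plus ~2.5 min land blocks at each end) per deployment at 25 Hz, ≈ 16 500
samples per deployment and ≈ 0.7 M samples overall.  The two-season design
then samples ⌊20/2⌋ = 10 training trips per season and holds out 20 trips
for prediction.  The end-to-end reference run (per-trip EM with full K
scans, a 1000-tree forest) takes ≈ 10 min on one core.

- EM uses 10 random starts; inside the pipeline each start runs a 25-sweep
  burn-in and only the best continues to convergence (the standard small-EM
  strategy); `fit_em` called directly runs every start to convergence.
- The 10⁻⁶ covariance ridge makes each M-step maximise a regularised
  objective; near-singular components (sample-and-hold depth change
  duplicates values 25×) can therefore lower the log-likelihood by a few
  units in a sweep.  Any decrease terminates the run on the previous, better
  parameters; only gross decreases raise an assertion.
- Components whose responsibility mass drops below one observation are
  reinitialised from a random row (logged) and the run restarts its
  convergence window.
- Degenerate inputs: zero-variance columns stay at 0 after scaling (with a
  warning); an all-zero static vector yields missing pitch/roll; behaviours
  with fewer than two rows in a trip are skipped from training; trips with
  no at-sea samples are dropped with a warning.
- Ties in the label rule table resolve by cluster index order; the
  `swim_cruise` slot goes to the largest unassigned cluster, the rest become
  `swim_cruise_2` (merged away downstream).
- Seeds: every stochastic stage (generator, EM starts, row/trip sampling,
  forest construction, train/test split) derives a child seed from the
  pipeline seed via hashed `SeedSequence` keys, so a run is reproducible
  bit-for-bit from its configuration.

## Known limitations

- The cluster→behaviour rule table is an explicit, configurable stand-in for
  expert visual assessment; its thresholds are tuned to the generator's
  emission geometry and would need recalibration for field data.
- BIC tends to the upper K bound on synthetic data because the 25×
  duplication of 1 Hz channels inflates the effective evidence; the
  threshold labeller absorbs the resulting over-splitting, but K itself
  should not be interpreted as the number of behaviours.
- The DEE coefficients shipped are placeholders for a closed-loop test, not
  a published calibration; real analyses must supply their own block with
  provenance.
- Agreement is a raw proportion (no chance correction), matching the
  reporting convention it mirrors.
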