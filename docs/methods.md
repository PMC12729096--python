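# Methods

This note documents the models and procedures implemented in `atcgaze`, the
parameter defaults and their rationale, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Recording geometry

All screen quantities are in centimeters, origin at the display's top-left
corner, y downward. The default geometry is a 61 × 34 cm radar display viewed
from 60 cm, sampled at 30 Hz (`ScreenGeometry`). Visual angle is the full
subtense θ = 2·atan(e/2d); its inverse maps angular thresholds into screen
units at the configured viewing distance. Viewing distances outside 30–120 cm
trigger a warning (plausibility band for a remote desktop tracker). Pixel
exports are converted once at read time when a display resolution is supplied.

Timestamps are milliseconds since scenario onset, with onset defined as the
first sample. Event durations are counted as *n_samples × sample period*
(33.33 ms at 30 Hz), for blinks and fixations alike; the alternative
last-minus-first convention differs by exactly one sample period and would
propagate into every duration mean.

## Event detection

**Blinks.** A blink is a maximal run of samples in which *both* eyes are
untracked and whose duration lies in the closed band [100, 600] ms. Both
edges are inclusive — the band is stated as a closed interval and no edge rule
is available, so 3-sample (100 ms) and 18-sample (600 ms) runs count. Longer
runs are reported separately as track loss; shorter ones are ignored as
single-sample dropouts. Samples with exactly one eye tracked are *not* blink
material (the loss must be simultaneous) but do carry a usable gaze position.

**Fixations.** The dispersion-threshold (I-DT) detector grows a window of
consecutive position-carrying samples while the window's dispersion stays
within 1° of visual angle, and emits a fixation when growth stops if the
window spans ≥ 100 ms; the centroid is the arithmetic mean of member
positions. The default dispersion metric is the maximum pairwise Euclidean
distance (the window fits in a disc of 1° diameter), reading "remaining
within 1°" as a containment bound; the classic x-range + y-range variant is
selectable (`dispersion_metric="range_sum"`). A single untracked sample
terminates the window: interpolating across even one 30 Hz dropout would
fabricate 33 ms of data, so no interpolation is attempted. The inner loop is
numba-compiled; the test suite checks it against an independent brute-force
maximal-window search on hundreds of random streams.

**Pupil.** Per-sample pupil diameter is the mean of the available eyes (one
suffices); the session index is the mean over such samples. A session with no
valid pupil samples yields NaN with a warning rather than an error, so batch
pipelines can continue.

## AOI model

The static partition comprises the centered 27.5 × 20.5 cm active sector, the
17 × 7.5 cm flight-plan sheet flush with the top-right corner, and the
out-of-sector remainder defined as the set complement — the three regions are
disjoint and cover the display. Rectangles are closed on their left/top edges
and open on right/bottom, making boundary hits deterministic; the sheet takes
precedence where the two rectangles brush each other (a 0.25 × 0.75 cm sliver
on the default display). Whether the out-of-sector region should include the
sheet area is genuinely ambiguous; this implementation keeps the three
regions disjoint, which makes the conservation property (sector +
out-of-sector + sheet time = total on-display time) exact.

Dynamic AOIs are rectangles of identical size for every aircraft (default
3.0 × 2.0 cm — the size is a free design parameter, chosen to cover a radar
symbol plus its data tag at the default viewport scale; configurable),
centered on the projected aircraft position and optionally extended toward a
tag offset. A fixation is assigned to the aircraft whose AOI contains its
centroid for the largest fraction of the fixation's duration on the sample
grid, with ties broken by the nearest AOI center at the fixation midpoint;
fixations contained by no AOI stay unassigned. Cumulative per-aircraft
fixation time clips fixations to an analysis window that starts at scenario
onset, or at sector entry for aircraft that enter late (operationalized as
the first 1 s grid time the projected symbol is inside the sector rectangle).
Attention time series use a trailing 10 s window stepped one sample at a
time — the finest grid, since no coarser step is canonical.

## Workload statistics

ISA is the mean of the eight in-task ratings (one per 2 min of a 16-min
scenario, enforced); NASA-TLX is the raw sum of six 1–20 components (6–120).
The 2 × 3 within-subject ANOVA is computed from the standard sum-of-squares
decomposition with each effect tested against its own subject-interaction
error term. For effects with more than two levels, sphericity is assessed
with Mauchly's test on orthonormal contrast scores; when p < .05 the
Huynh–Feldt epsilon rescales both degrees of freedom (the .05 trigger is a
design choice — the correction is standard but the trigger threshold is not
universally fixed). Partial η² = SS_effect / (SS_effect + SS_error). The
implementation is cross-checked against pingouin in the test suite (pingouin
is deliberately kept out of the runtime dependency set so it can serve as an
independent oracle). Zero-blink sessions propagate a missing blink-duration
mean and are dropped listwise from that ANOVA only. Degenerate tables with
zero effect and zero error variance report F = 0, p = 1.

Spearman correlations are computed over the six condition means (the natural
unit once conditions are the objects of inference; n = 6, so these are
descriptive with sign structure as the primary readout). Confidence intervals
use the Fisher z transform with the 1.06/√(n−3) standard error appropriate
for rank correlations; constant variables are flagged as undefined.

## Conflict detection & resolution

Separation between two aircraft states is (horizontal Euclidean distance in
NM, |altitude difference| in ft). A loss of separation requires *both*
lateral < 5 NM and vertical < 1,000 ft simultaneously — strict inequalities,
because safety is defined as keeping *at least* those margins. The checker
scans a 1 s grid (scripted times are whole seconds; configurable) after
applying the intervention log: altitude clearances change the vertical
profile at a finite default rate of 1,500 ft/min (an instantaneous level
change would trivialize resolution timing; the value is an ordinary jet
climb/descent rate and is configurable), speed clearances scale the
along-track ground speed. A conflict is solved iff the checker finds no
violation among that conflict's aircraft pairs over the whole scenario.

Group contrasts use Mann–Whitney U via scipy (exact for small untied
samples, tie-corrected normal approximation otherwise); the suite verifies
agreement with exhaustive permutation enumeration for group sizes ≤ 8.
The stepwise logistic regression mirrors the common forward-Wald procedure:
at each step the candidate with the smallest Rao score-test p ≤ .05 enters,
then any included predictor with Wald p ≥ .10 is removed, to a cap of 25
steps (entry/removal defaults follow the usual statistical-package
convention, as no thresholds are canonical here). McFadden R² = 1 −
lnL/lnL₀; VIF is computed on the selected predictors by OLS of each on the
rest. Quasi-complete separation — routine when a binary intervention
perfectly predicts success — is flagged in the result rather than raised:
fitting falls back from Newton to BFGS to a weak ridge penalty, and the
separation flag is set when slopes exceed ±15 or the likelihood saturates.

## Synthetic study generator

The generator emulates the *structure* of a 24-participant, 2 × 3
within-subject simulator study with 16-min sessions, so that every analysis
stage has a ground truth:

- **Scenarios.** Aircraft fly straight piecewise-linear trajectories in NM
  world coordinates, projected onto the sector rectangle by a fixed linear
  viewport (110 × 82 NM onto 27.5 × 20.5 cm — the scale is a free choice;
  linearity is what matters for the geometry tests). The conflict scheduler
  back-computes initial placements on a collision course so the lateral gap
  crosses 5 NM half a grid step before the scripted time, with the vertical
  margin already infringed by a climbing aircraft; the round trip through the
  separation checker is verified at construction. The 12-aircraft
  high-complexity scenario embeds the Easy pair (violation at 140 s; level
  standard-route POB456 vs climbing non-standard HYG532, which enters the
  sector ~25 s after onset) and the Difficult trio (REV756 climbing into
  KET456 at 240 s, with GPL751 converging on REV756 at 300 s and look-alike
  SRT346 uninvolved). All other traffic is made conflict-free by ≥ 2,000 ft
  vertical spacing, verified pairwise in the tests.
- **Gaze.** An alternating fixation/saccade renewal process (gamma fixation
  durations, mean 280 ms; 1–2 transit samples rendered *valid* so saccades
  can never masquerade as blinks) draws fixation targets over
  {non-conflict aircraft, sector points, out-of-sector, sheet} with
  condition-dependent weights targeting a ≈ 83/13/4% sector/out/sheet time
  split (sector weight rises with complexity: .78/.83/.88; sheet weight falls
  with traffic). Before each scripted violation, a boost probability directs
  fixations to the conflict aircraft, calibrated so the cumulative
  pre-violation dwell matches the calibration group means (35.67 s solvers vs
  16.11 s non-solvers for the Easy conflict; 68.56 vs 81.50 s for the
  Difficult one). Blinks are Poisson gaps (rates 14/9.5 per min for low/high
  traffic, −1.5 under high complexity) with truncated-normal durations kept
  strictly inside the 100–600 ms band (means 315/295 ms); pupil is a
  condition baseline (3.41/3.44 mm) plus a participant offset (SD 0.32 mm)
  and AR(1) noise.
- **Behavior.** Solver status per conflict is Bernoulli (8/24 Easy, 13/24
  Difficult). Solver logs issue clearances early enough to restore
  separation (verified by the checker by construction); non-solver logs are
  empty or contain only post-violation actions, so outcome classification is
  deterministic. ISA/NASA responses are monotone noisy functions of demand
  with participant random effects.
- **Metric tables.** `simulate_metric_table` draws session-level metrics
  directly from the same distributions, bypassing stream rendering; it exists
  for statistical calibration studies (type-I error at 200 replicates, power
  checks) where rendering hundreds of full cohorts would be pointless.
  `CohortParams.null()` equalizes all condition-dependent parameters for
  null-calibration runs.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so cohorts are bit-reproducible and per-participant substreams are
independent.

What the generator does **not** emulate: pupil light reflex and luminance
coupling, fatigue dynamics and their blink signature, head movement, smooth
pursuit (fixation targets hold the aircraft position at fixation onset —
negligible drift at realistic viewport speeds), saccade kinematics, and
expert scanpath strategies. Passing pipeline tests therefore demonstrate
correctness of the *analysis* under the stated measurement model, not
validity of any psychophysiological claim about real controllers; the
participant-level calibration values are generator targets and sign
structure, not quantities the pipeline could re-derive.

## Problem sizes and tolerances in the test suite

The acceptance-style tests run the full pipeline over 20 replicate 24 × 6
cohorts for the effect-sign checks (each qualitative contrast must hold in
≥ 90% of seeds), 200 reduced-size (n = 8) table-level replicates for type-I
calibration of the traffic F-test (binomial 95% band around 5%), 100 random
streams for both the blink-recovery and fixation-oracle equivalences, and
100 replicates of a 10-noise-predictor stepwise screen compared against the
1 − 0.95¹⁰ family-wise bound. Exactness claims are: blink counts and
in-band recovery exact; fixation detector identical to the brute-force
oracle; AOI count conservation exact and time conservation to float-sum
precision (1e-9 s); scripted violations exact on the 1 s grid.
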