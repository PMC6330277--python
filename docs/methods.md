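# Methods

## Generative movement model

Trials are simulated from the minimum-jerk model of point-to-point
reaching: along the movement axis,

    x(t) = D (10τ³ − 15τ⁴ + 6τ⁵),   τ = t/T,

with amplitude `D` (m) and duration `T` (s). The model is chosen
because its velocity profile is bell-shaped and single-peaked, its
acceleration crosses zero exactly at the velocity peak, and all seven
parameters the pipeline extracts have closed forms, so extraction can
be validated without any recorded data:

| quantity            | closed form            |
|---------------------|------------------------|
| peak velocity       | `1.875 · D/T`          |
| mean velocity       | `D/T`                  |
| peak acceleration   | `(10/√3) · D/T²`       |
| peak deceleration   | `−(10/√3) · D/T²`      |
| mean acceleration   | `1.875 · D/(T·Ta)`     |
| mean deceleration   | `−1.875 · D/(T·Td)`    |

To let tool use strengthen deceleration independently of total
duration, the simulator generalises to a two-half profile: an
acceleration phase of duration `Ta` (the first half of a minimum jerk
of duration `2Ta`) joined at the velocity peak to a deceleration phase
of duration `Td = T − Ta`. Position, velocity and acceleration are
continuous at the junction, the peak speed `1.875·D/T` is invariant to
the split, and the peak acceleration/deceleration become
`(10/√3)·D/(2·T·Ta)` and `−(10/√3)·D/(2·T·Td)`. The symmetric case
`Ta = Td = T/2` is the classic polynomial and is the default.

Each trial is sampled at 100 Hz with 0.5 s of stationary rest before
onset and 0.5 s of hold after offset (so onset/offset detection is
non-trivial), optional additive sinusoidal tremor on the movement axis
(default 5 Hz; amplitude 1 mm for simulated patients, 0 for controls),
and i.i.d. Gaussian positional noise per axis (default 0.5 mm,
representative of optical motion capture).

## Cohort design and defaults

The default `CohortDesign` mirrors the experimental structure the
package targets: 14 patients and 18 controls, two recorded sessions
(pre- and post-tool-use) of 6 trials × 2 hands each, and 7 tactile
estimates of a fixed 7 cm caliper gap per hand after each of the three
experimental sessions (pre, tool-use training, post).

Effect defaults were set once from the group statistics the paradigm
typically produces and are fully configurable:

* baseline reach `D = 0.33 m` in `T = 0.66 s` for controls (mean
  velocity ≈ 0.48 m/s, peak ≈ 0.89 m/s);
* bradykinesia: patient durations ×1.25 and amplitudes ×0.95
  (movement time ≈ 0.83 s, attenuated peaks);
* tool-use (Time) effect present only in controls: +0.06 s movement
  time and a ×1.15 deceleration-magnitude factor post-tool-use,
  realised by shrinking `Td`;
* between-subject duration SD 0.08 s, trial-to-trial SD 0.03 s;
* tactile estimates: 7 cm + session bias (+1.1, +1.0, +0.9 cm over the
  three sessions) + subject bias (SD 0.8 cm) + trial noise (SD 1 cm),
  truncated at 0.

One patient (configurable `n_tactile_missing`, default 1) contributes
no tactile data, so the tactile mixed ANOVA runs on 31 participants and
reports df = (2, 58) for Time and (1, 29) for Group — the degrees of
freedom of the motivating study's tactile analysis — while the
kinematic ANOVAs report (1, 30) from all 32.

For calibration studies (type-I error, contrast power) the
response-level shortcut `session_scores` draws participant × session
outcomes directly: a Gaussian subject intercept plus session noise with
an intraclass correlation of 0.5 (equal between/within variance split,
a neutral default for repeated measures), shifted by cell effects in
total-SD units. This is the same statistical structure the trajectory
route induces, without synthesising thousands of cohorts; the full
trajectory route is exercised at study scale in the pipeline tests.

What the simulator does *not* emulate: movement curvature and endpoint
error, submovements and corrective adjustments, asymmetric or
non-Gaussian tremor, marker dropout/occlusion, and any dependence of
tactile errors on kinematics. Passing tests therefore demonstrate that
the pipeline recovers known parameters and calibrated inferences under
an idealised reach model — not that it handles every pathology of real
recordings.

## Kinematic extraction

* **Smoothing**: 2nd-order Butterworth applied forward and backward
  (`scipy.signal.filtfilt`; net 4th-order, zero lag), cutoff 6 Hz —
  standard for reaching kinematics at 100 Hz. The cutoff must stay
  below Nyquist; for noiseless data the filter changes a minimum-jerk
  trajectory by less than 1 mm.
* **Differentiation**: speed is the Euclidean norm of the
  central-difference 3D velocity (one-sided at the ends), acceleration
  the central difference of speed. Both are invariant to rigid
  rotation/translation of the coordinate frame.
* **Segmentation**: the velocity peak is the global speed maximum
  (earliest on ties). A 5 %-of-peak threshold, required to hold for
  ≥ 50 ms (hysteresis, tremor-resistant), brackets the movement; both
  ends are then refined by walking outward while speed decreases
  monotonically, capped at 12 % of the detected span (the sub-threshold
  tail of a bell profile is < ~7 % of its span; the cap stops
  noise-driven runaways), and stepped one sample back inside because
  central differences smear one sample into the rest plateau. A pure
  threshold rule would shorten a bell-shaped movement by ~12 % (the 5 %
  crossings of the minimum-jerk speed quartic sit at τ = 0.059 and
  0.941); the refinement removes that bias. `refine=False` restores
  threshold-only behaviour. Speed that never exceeds 1 mm/s raises
  "no movement detected".
* **Scoring**: movement time is offset − onset time; mean velocity is
  path length over the phase divided by movement time (not the mean of
  instantaneous speed — the two differ under noise); the velocity-peak
  time and value are interpolated parabolically (sub-sample, clamped to
  half a sample); mean acceleration/deceleration are the net speed
  change over the sub-phase divided by its duration (the time-average
  of tangential acceleration; a mean over gradient samples carries an
  N/(N+1) discretisation bias); peak acceleration is the maximum of the
  acceleration series over [onset, peak], peak deceleration the signed
  minimum over [peak, offset]. Deceleration parameters are therefore
  negative, matching reporting conventions. Sub-phases with fewer than
  3 samples are rejected.
* **Collapsing**: the per-trial parameters are averaged per participant
  × session with hands pooled (a `per_hand` flag keeps them separate).
* The going phase ends at speed offset, not at target contact (no
  contact signal exists in marker data); this is the conventional
  choice and is flagged here because the two differ in principle.

Accuracy at 100 Hz (verified by the property tests): noiseless peaks
within 3 % and movement time within one frame-and-a-half (±0.03 s)
across D ∈ [0.2, 0.6] m, T ∈ [0.4, 1.2] s; mean velocity within 5 % and
phase means within 10 % — the means are limited by one-sample boundary
quantisation of the sub-phases (one sample out of 20 at T = 0.4 s is
already 5 %). Under 1 mm positional noise, velocity-scale parameters
hold to 10 % at the study's operating range while the
twice-differentiated acceleration peaks hold to 25 %: with a 6 Hz
cutoff, 1 mm of white marker noise leaves ~0.2 m/s² of acceleration
noise, which is not small relative to the ~0.8 m/s² true peak of a
slow, short reach. Tremor similarly obscures the lowest-speed portion
of patient movements, biasing detected movement time slightly
downward; group contrasts are unaffected in direction.

## Tactile scoring

Error = estimate − 7 cm (negative = underestimation), averaged per
participant × measurement session, hands pooled by default, no outlier
trimming. Session means (not trial-level data) enter the 2 × 3 mixed
ANOVA — the standard choice when the within-subject factor is session.

## Inference chain

The mixed (split-plot) ANOVA is computed from its sums-of-squares
decomposition, per stratum:

* between stratum, on subject means: Group (and the covariate in the
  ANCOVA) tested against subjects-within-groups,
  `SS_S = k·Σ(ȳ_i − ȳ_group)²`, df `N − 2` (`N − 3` with covariate);
* within stratum, on subject-centered responses: Time and Group × Time
  (and covariate × Time) tested against Time × subjects-within-groups,
  df `(N − 2)(k − 1)`.

Sums of squares are Type III — each effect is the residual-SS increase
from deleting its sum-to-zero-coded columns from the stratum's full
model — because the groups are unbalanced (14 vs 18). The equivalence
with a single full-design-matrix GLM projection is asserted to 1e−8 in
the tests. Partial η² = SS_effect / (SS_effect + SS_error-of-stratum),
internally consistent by construction. For 3-level within factors a
Greenhouse–Geisser correction is available behind a flag (off by
default; the 2-level kinematic analyses cannot violate sphericity).

ANCOVA: the covariate (age, one value per subject, centered) is
partialled from the between stratum, and covariate × Time joins the
within stratum — so a Time main effect that merely tracks the
age-confounded group composition loses support, matching the stratum
structure such re-analyses use. Adjusted cell means are evaluated at
the grand covariate mean.

Simple effects for the 2 × 2 design (`emm_simple_effects`): unweighted
(estimated marginal) cell means; Time-within-group contrasts use the
within-stratum error (`SE = √(2·MS_w/n_g)`); Group-within-time
contrasts use the Winer combined mean square `(MS_S + MS_w)/2` with
Satterthwaite degrees of freedom (and, under ANCOVA, the covariate
imbalance term `(x̄₁−x̄₂)²/S_xx` in the multiplier — an approximation,
documented as such). The Bonferroni family is the four reported
contrasts (Time|PD, Time|control, Group|pre, Group|post); adjusted
p = min(1, 4·raw).

Mann–Whitney U: U counts pairs `a < b` plus half-ties; the reported
statistic is `min(U, n₁n₂ − U)`. The two-sided p is exact by full
enumeration of group assignments (valid under ties) when `n₁ + n₂ ≤ 16`,
else a tie-corrected normal approximation without continuity
correction. Spearman's ρ is the Pearson correlation of mid-ranks with
the two-sided t-approximation p (via `scipy.stats.spearmanr`); constant
input is rejected as undefined.

`describe` formats mean and n−1 SD either by rounding half away from
zero or by truncation — the packaged clinical table's printed footer is
only consistent with truncation (e.g. mean age 66.86 printed as 66), so
the pipeline's descriptives default to truncate.

`power_two_sample` is the two-sided two-sample t power via the
noncentral t with `ncp = d·√(n₁n₂/(n₁+n₂))`; it is strictly increasing
in d, n and α (at d = 0.5, n = 14 + 14, α = .05 the power is 0.247 —
post hoc power at such sample sizes is low, whatever a report may
claim).

## Pipeline and reproducibility

`run_pipeline` executes simulate/ingest → extract → collapse → tactile
→ per-parameter ANOVA (+ simple effects when the interaction is
significant, + ANCOVA re-run) → tactile ANOVA → Spearman clinical
correlations (patients only: disease duration and UPDRS vs each
parameter, pre and post, plus tactile sessions) → Mann–Whitney
lateralization tests (left- vs right-affected patients) →
descriptives, writing CSVs, a §Results-ordered text report (movement
time, mean velocity, peak velocity, mean acceleration, peak
acceleration, mean deceleration, peak deceleration), and a run log that
echoes every configuration value so no silent defaults exist. Paths are
excluded from the log so that bundles are byte-identical across hosts
for a fixed seed; all tabular output uses a fixed float format. Any
stage failure aborts with a stage-tagged error.

Problem sizes used by the test suite and acceptance script: 200
simulated trials for recovery checks, 50 random datasets for the GLM
oracle, all `n₁, n₂ ≤ 8` for Mann–Whitney enumeration, 1000 null
replicates for type-I calibration and 500 for the simple-effect
dissociation (response-level simulator), and one full 32-participant
trajectory cohort for the design-shape check.

## Known limitations

* The univariate split-plot ANOVA assumes compound symmetry across
  within-subject levels; with only 2 levels this is vacuous, and for
  the 3-level tactile analysis the GG correction is opt-in.
* The exact Mann–Whitney enumeration is combinatorial; above
  `n₁ + n₂ = 16` the normal approximation is used.
* C3D motion-capture ingestion is not included; trajectories are read
  from `time,x,y,z` CSVs.
* The simple-effect standard errors under ANCOVA treat the covariate
  adjustment of the subject-level variance component approximately (see
  above); the ANOVA-path simple effects are exact under the model.
* Acceleration-scale parameters extracted from noisy 100 Hz data carry
  irreducible differentiation noise (see accuracy notes); conclusions
  about acceleration in slow, short movements should rest on group
  means, not single trials.
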