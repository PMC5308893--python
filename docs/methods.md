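# Methods

This note documents the analysis procedures, the generative model behind
the synthetic data, the numerical conventions, and the design choices
made where the underlying experimental literature leaves the procedure
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement core

**Speed.** Speed at frame *i* is the centroid displacement from frame
*i−1* to *i* multiplied by the frame rate, so each displacement is
assigned to its arrival frame and the first frame of a session is
undefined. The raw speed is smoothed with a five-frame running median
(the standard way to reject single-frame tracking glitches without
blurring genuine steps). At the series boundaries the window shrinks
symmetrically instead of padding: the result is deterministic, never
invents data, and differs from the interior filter only on the two
outermost frames at each end — negligible at 60 frames/s but pinned
down so that every re-computation is bit-reproducible.

**Tracking gaps.** Frame intervals longer than one nominal frame period
(tolerance 10⁻⁶ s) are flagged on read and the speed across them is
masked, never interpolated. Peri-event windows that touch a masked
frame are dropped and counted.

**Peri-event windows.** Relative to stimulation onset, the pre window
is [−2, 0) s and the post window [+1, +3) s; a frame belongs to a
window when its timestamp falls in the half-open interval. The post
window starts 1 s after onset because the suppression develops with a
sub-second time constant; by +1 s the effect is essentially complete.
Windows that cross a block boundary are dropped: pre speeds must not
mix stimulated and unstimulated epochs. Delta speed is the post-window
mean minus the pre-window mean of one event; mouse-level statistics
average events first, cohort-level statistics then average mice with
equal weight (mean ± SEM across mice).

## The stimulation protocol

A 30-min session is split into six 5-min blocks, alternating
no-stimulation / stimulation and starting unstimulated. Within each
stimulated block, 3-s trains are delivered every 10 s, giving 90 trains
and exactly 270 s of stimulation per session. Two presets exist because
the daily protocol is described with 25 Hz pulses in one place and
20 Hz in another; both are kept (`STANDARD_PROTOCOL`, 25 Hz;
`LONGTERM_PROTOCOL`, 20 Hz) and the package takes no position on which
is authoritative — every schedule-level quantity except the pulse count
is identical.

**Sham events.** Each sham event sits in a non-stimulated block at
exactly the same within-block phase as the real trains
(`block_start + k · train_period`). This is the least-assumption
reading of "equivalent periods in non-stimulated blocks", and it makes
real and sham events exchangeable under the null hypothesis — the
property the mean-reversion correction needs. Block indices are 0-based
throughout.

## The mean-reversion correction

Conditioning the post-stimulation speed on the pre-stimulation speed
produces regression toward the mean even without any stimulation:
events selected for fast pre speeds will on average slow down, and
events selected for slow pre speeds will speed up. The correction bins
sham events by the *same* quartile cut points as the real events and
subtracts the per-quartile sham delta from the per-quartile real delta
("delta-of-delta"). Because real and sham events are exchangeable under
the null, the subtraction cancels the reversion exactly in expectation;
it also cancels any additive shift of all speeds.

Conventions pinned here because no standard exists:

* quartile cut points are the 25/50/75% quantiles of the *real* events'
  pre-speed distribution, computed with linear interpolation between
  order statistics (pre speeds 1, 2, 3, 4 give cuts 1.75, 2.5, 3.25);
* sham events are binned by the real-event cuts so the two sets of bins
  are comparable;
* a value exactly at a cut point goes to the lower quartile;
* the sham subtraction is applied mouse by mouse, then averaged across
  mice; quartiles empty for a mouse are excluded from that quartile's
  cohort mean with the count reported.

## Zones and thigmotaxis

The arena (50 × 40 cm, origin bottom-left) is partitioned into edges
(strip within 2 cm of a wall), corners (10 × 10 cm squares at the four
corners, minus the edge strip), periphery (the remaining 10-cm band),
and center (the interior rectangle). The band and margin widths are
package defaults — the experimental zone dimensions are not public —
and both are configurable. Edge frames are excluded from
center/periphery/corner event statistics by default (they are tracked
but not analyzed). Boundary points are resolved by strict comparisons
against the distance-to-wall thresholds, so the zones partition the
arena exactly; a grid-sweep test verifies this at 1-mm resolution.

The normalized center distance of a point is its distance from the
arena center divided by the distance from the center to the wall along
the same ray, which for a rectangle reduces to
`max(|x−cx|/(W/2), |y−cy|/(H/2))`. Wall midpoints and corners both map
to 1, so the measure is comparable across directions.

Path-length fractions assign each displacement segment to the zone of
its arrival frame — the same convention as speed — and segments across
tracking gaps are excluded.

## ROI conditioning metrics

The conditioning rectangle is 13 × 10.5 cm, centered in the arena by
default. A visit is a maximal interval with the centroid inside the
rectangle (half-open boundaries, lower/left inclusive). There is no
minimum-dwell debounce by default, because closed-loop stimulation
terminates immediately on exit; a debounce parameter exists for noisy
tracking. The session metrics follow the printed definitions: entry
rate = entries / time outside; exit rate = exits / time inside. A visit
already in progress at session start is not an entry and one running at
session end is not an exit, so entries and exits differ by at most one.
Rates with zero denominators are flagged as undefined (NaN) rather than
guessed.

The scientific point of the metric pair: a pure slowing effect inflates
occupancy and depresses the exit rate while leaving the entry rate
unchanged, whereas a place preference would also raise the entry rate.
The simulator reproduces this dissociation *by construction* — ROI
stimulation only multiplies the intended speed, and no attraction or
repulsion toward the rectangle is ever injected.

## Ethogram analysis

Behavioral states are walking, rearing, jumping (mobile) and resting,
digging, grooming, scratching (immobile); not all time need be scored,
so probabilities sum to at most 1. Probabilities are scored time in
state within the analysis windows divided by total window time; records
straddling a window contribute their overlap. Jumping and scratching
stay in the schema even though they are typically too rare to analyze;
excluding them is a filter flag, not a schema change.

## Long-term regression

Per mouse-session baselines: `v_pre` (mean pre-window speed over the
session's events), `v_post`, their difference `delta`, and
`v_firstblock` (mean speed in the first, always unstimulated, block —
useful because it predates any same-day stimulation). For unstimulated
sessions the pre/post windows are evaluated at the sham schedule so the
quantities remain defined.

The regression is ordinary least squares,

    speed = β₀ + β₁·session + β₂·group + β₃·session·group

with session 1-based and uncentered and group coded 1 for the cohort
stimulated from day 1 (G1) and 0 for the delayed cohort (G2). β₃ is the
per-session speed change attributable to stimulation history. Mouse
identity is not modeled as a random effect — the regression is plain
OLS by design, and the simulated cohorts are generated without
per-mouse heterogeneity in the baseline speed, so the OLS confidence
intervals are calibrated for the data the package generates (verified
by simulation). Mixed-effects extensions are out of scope.

Two correlation procedures ask whether the transient suppression on day
*n* predicts short-term baseline changes while avoiding the confound
that both quantities trend across sessions:

* **A** regresses `v_pre(n+1) − v_pre(n−1)` on `delta(n)` (first and
  last sessions excluded);
* **B** removes each mouse's linear session trend from `v_pre` and
  regresses the residual at session *n+1* on `delta(n)`.

Both pool mouse-session pairs across mice (a per-mouse variant exists
behind a flag); all p-values are two-sided. If the response of either
regression is numerically constant (e.g. perfectly linear `v_pre` in
procedure B), the fit is reported flat: slope 0, R² 0, p 1.

## The synthetic-data generator

The movement model is the simplest stochastic process exhibiting every
feature the analyses measure; it is explicitly not a model of real
mouse locomotion. Components and defaults:

| parameter | default | meaning |
|---|---|---|
| `mu_v` | 6 cm/s | mean of the Ornstein-Uhlenbeck intended speed |
| `theta` | 0.6 s⁻¹ | reversion rate of the intended speed |
| `sigma_v` | 3 cm·s⁻¹·s⁻½ | OU noise (stationary SD ≈ 2.7 cm/s) |
| `heading_sigma` | 1.8 rad/√s | heading random-walk scale |
| `w_wall` | 1 cm/s | drift toward the nearest wall (thigmotaxis) |
| `state_exit_rates` | 0.15–0.5 s⁻¹ | behavioral-state switching |
| `state_multipliers` | 1, 0.2, 0, 0, 0.1 | per-state speed scaling |
| `g_stim` | 0.5 | multiplicative suppression gain during light |
| `tau_on_s` / `tau_off_s` | 0.5 / 1.5 s | gain onset/offset kinetics |
| `stim_rest_rate` | 0.3 s⁻¹ | light-gated extra mobile→rest hazard |
| `lambda_drift` | 0.15 cm/s | per-stimulated-session increment of `mu_v` |
| `fps` | 60 | frame rate; arena 50 × 40 cm |

The suppression gain relaxes toward `g_stim` with a 0.5-s time constant
while light is on (most of the decrease complete within a second, as
observed for the real effect) and back toward 1 with 1.5 s after
offset. `g_stim = 0.5` matches the roughly twofold transient
suppression; `lambda_drift = 0.15` matches the reported
session-by-group interaction slope. A wild-type-like animal is
`g_stim = 1`, `stim_rest_rate = 0`, `lambda_drift = 0` (the cohort
generator applies this automatically to WT mice). The optional
frequency scaling makes the suppression depth proportional to pulse
rate relative to 25 Hz, producing a negative dose-response correlation.

Sessions start from the stationary law of the state chain and of the
intended-speed process, so early blocks are statistically exchangeable
with late ones — a property the sham correction relies on. Positions
reflect at the walls; the wall-attraction drift switches off within
0.5 cm of a wall. All randomness derives from one integer seed through
`numpy.random.SeedSequence`; identical seed and configuration give
byte-identical output files. The per-frame dynamics run in a
numba-compiled loop fed with pre-drawn random arrays.

What the generator does **not** emulate: gait structure, body
orientation, tracking noise and dropouts (gaps can be injected but are
not generated), arena habituation within a session, per-mouse
heterogeneity, and any reward-driven spatial learning. Passing tests
therefore demonstrate that the estimators are correct and calibrated
for data with the assumed statistical structure, not that the
biological conclusions are right.

## Study sizes used by the test suite and acceptance script

Simulated checks run at reduced scale, chosen so every check retains
clear statistical margins: frame rates of 15–20 fps instead of 60,
sessions of 600–900 s where a full 1800-s session is not needed, and
~4200-s sessions (≈210 events per arm) for the quartile analyses.
The quartile-correction checks use 20–40 replicate sessions; the ROI
dissociation uses 20 sessions per condition; drift recovery uses 20
simulated cohorts (3+3 mice × 12 sessions) and the null-calibration
checks 50–100 cohorts and 200 sessions. The package defaults remain
the full-scale study conditions.

## Known limitations

* The cohort regression's confidence intervals assume independent
  homoskedastic session-level errors; with real per-mouse
  heterogeneity a mixed model would be required.
* The entry/exit-rate dissociation is a one-sided diagnostic: it can
  rule place preference out, but a mixed effect (slowing plus weak
  preference) would need the rates to be modeled jointly.
* Window means use frame membership by timestamp, so at very low frame
  rates the effective window length is quantized to the frame period.
* The ray-normalized center distance assumes a rectangular arena.
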