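# Methods

This note documents the models, conventions and numerical choices behind
`mmnav`, in the order data flows through the package.

## Coordinate frame and angles

The arena's horizontal plane is (x, z): x increases east, z increases south
(the common convention of block-world games). All angles are degrees in the
half-open wrap range (−180, +180], with the boundary tie resolved to +180.
Internally every direction is a *mathematical bearing* — 0° along +x,
counterclockwise positive, so (0,0)→(0,1) has bearing +90°. The canonical
log format stores this convention directly; `yaw_to_heading` /
`heading_to_yaw` convert raw game yaw (clockwise from +z) for adapters that
ingest native mod logs. Keeping one convention downstream means every angle
metric is game-agnostic.

Positions are continuous reals even though chests occupy integer blocks;
placements are recorded at the placed block's centre, which supports both
block-snapped and continuous logs.

## Log and environment formats

One CSV row per sample: participant, condition, phase, object id, spawn
corner, step index, time (s), x, z, heading, event
(`spawn|move|open_chest|place_chest`). A "step" is one logged sample
transition — the canonical cadence is one row per block of movement. For
denser (per-tick) logs, `collapse_jitter` merges consecutive samples with
horizontal displacement below 0.2 blocks, the same threshold below which a
transition is treated as stationary by every metric. Environment specs are
JSON; validation enforces exactly 12 chests forming a complete regular
grid, four mutually distinct corner spawns, and equality (to 1e-6 blocks)
of each corner's distance to its nearest chest.

The bundled default arena is 100 × 100 blocks with a 3 × 4 chest grid inset
20 blocks from the walls; the dwell radii 10/20/30 are then small relative
to the arena, and each corner's nearest chest sits at 20·√2 blocks. All
geometry is configurable through the spec file.

## Metric definitions and edge cases

Per-step deviations `d_i = wrap(heading_i − reference_i)` are computed over
movement steps from spawn until the placement event, skipping stationary
transitions and the (measure-zero) case of a step taken from exactly the
true location. Two reference conventions are implemented:

* `instantaneous` (default): bearing from the current position to the true
  location. This is the only reading under which a straight walk to the
  target scores exactly 0° along the whole path.
* `fixed_start_line`: the fixed spawn→true bearing, for analyses that frame
  deviation relative to the best-fit starting line.

Header direction takes |mean(d_i)| (signed mean: opposite deviations
cancel); cumulative error takes Σ|d_i| (backtracking inflates it). The
always-true inequality `cumulative ≥ n_steps × header` is asserted by the
test suite. A `mean_abs` header mode is available but not the default.
Initial orientation restricts the signed mean to the first five movement
steps; trials with fewer than five are flagged. Trials with zero movement
(teleport-then-place) have undefined angle metrics: they are flagged,
excluded from angle aggregates, and retain their placement error.

Approach angle uses the *circular* mean (direction of the mean unit vector)
of the last k = 5 movement bearings before the anchor sample — terminal
placement for test trials, the first open-chest event within the 3-block
arrival radius for training. An arithmetic mean of wrapped angles would be
discontinuous at ±180°; the circular mean is not. Both k and the radius are
configurable; neither has a canonical published value. Two viewpoints are
"the same" within ±22.5°, half the 45° field of view.

Proximity dwell is the fraction of a trial's *samples* within each radius
(step counts, matching a step-sampled log); a seconds-weighted mode exists
for logs with nonuniform cadence.

Distinct-chest counting in training needs chest identity, which log rows do
not carry for open events; with an environment given, events are attributed
to the nearest chest — unambiguous whenever the detection radius is below
half the grid spacing, which the defaults respect. Re-opening a chest
counts toward the total but not the distinct count.

## The synthetic agent

The generator emulates the task's two phases with interpretable parameters:

* **Training** — a persistent random walk (heading held for a geometric run
  of mean `explore_persistence` = 25 steps, then redrawn uniformly) with
  specular wall reflection, plus *marker sight*: the floating marker over an
  unopened chest is visible within `sight_radius` = 30 blocks and steers
  the walk toward it; the chest opens within `detection_radius` = 2.5
  blocks. A pure diffusive walk finds only ~6–8 of the 12 chests inside the
  600 s cap; with sight, ~95 % of trainings find all 12 in ≈340 s, matching
  the intended experience that nearly every participant finds every chest.
  The phase ends at 12 distinct chests or the cap.
* **Test** — the believed location of each object is the true location plus
  isotropic Gaussian noise with per-axis SD `memory_sd` (default 4 blocks),
  clipped to the arena. Each step the agent faces the bearing to the
  believed spot plus von-Mises noise of concentration `heading_kappa`
  (default 8; ∞ disables noise exactly), holds each noise draw for a
  geometric run of mean `heading_persistence` = 8 steps, and walks
  `step_size` = 1 block. It places the chest upon reaching the believed
  spot (the final hop lands on it exactly) or wherever it stands at the
  180 s cap. One step equals one second, so both phase caps translate to
  step caps; real players can run as well as walk, a speed variation the
  simulator does not model.

Heading noise is *run-correlated* rather than white: navigators commit to a
(possibly wrong) direction for a stretch and re-orient periodically. White
per-step noise would average out of the signed-mean header direction over a
~100-step trial, leaving the directness metrics almost insensitive to κ;
run-correlation restores that sensitivity and is the behaviourally
plausible choice. Even so, header direction's cancellation property caps
how strongly any pure directness improvement can move it — its variance is
dominated by the memory-aim geometry (aiming at the believed rather than
the true location), which grows near the target. This ceiling is a property
of the metric's definition, and the effect-detection tests size the
simulated practice effect to a moderate empirical magnitude
(partial η² ≈ 0.16) rather than pretending the metric is more sensitive
than it is.

**Cohorts.** Per participant, a stable ability multiplier on `memory_sd`
(log-normal, SD of log = 0.2) and two sessions — sleep and wake — on
counterbalanced environments and condition orders. Within a session, each
object's memory noise splits into a shared map component
(`memory_shared_frac` = 0.6 of the variance) reused by both tests and an
independent per-test retrieval component; test-retest placement errors are
therefore positively correlated (r ≈ 0.5 item-level) without being
degenerate duplicates — exact sharing would zero the interaction error term
of the condition × test ANOVA. Condition effects enter as per-test
multipliers on the total memory SD (default design: wake ×1.3 at test 2,
sleep ×1.0 — retention declining over a waking day, maintained over sleep),
and per-test multipliers on κ model practice-driven directness gains shared
by both conditions. Everything derives from one master seed through
spawned per-participant streams, so cohorts are byte-reproducible.

A vectorized walk engine steps all trials of a cohort simultaneously; the
replicate-study fast path (`cohort_metric_table`) computes metrics directly
on the engine's arrays. The test suite asserts per-trial agreement between
that path and the sample-by-sample metric layer.

## Statistics

ANOVAs are explicit balanced sum-of-squares decompositions: fully-within
effects (any number of crossed factors, e.g. condition × radius × test) are
each tested against their own interaction with subjects; the mixed design
tests the between effect over subjects-within-groups and the within effects
over the within residual; effect size is partial η² =
SS_effect / (SS_effect + SS_error). Zero effect SS yields F = 0 by
convention (covers constant data); zero *error* SS with a nonzero effect
raises a degenerate-variance error, which the pipelines catch and record in
the run manifest. No sphericity correction is applied — every within factor
here has two levels except the three-level radius factor, for which the
degrees of freedom are reported so a correction could be layered on.
p-values come from the classical F distribution. The implementation is
cross-checked in the suite against independent textbook oracles and against
pingouin/scipy where those cover the design.

Correlation families use Pearson r with Bonferroni correction within the
family (corrected α = α/|family|, e.g. 0.05/6 ≈ 0.0083 for the four-measure
global family and the four-phase approach-angle family); zero-variance or
undersized pairs carry explicit markers instead of numbers.

Outlier filtering is single-pass: mean and *population* SD (ddof = 0) are
computed on the full input and applied once, with no recursion.
Participant-level exclusion is one-sided (only poor performers removed,
2.5 SDs above the mean error); item-level exclusion is two-sided (2.5 SDs
either way within condition × test), and items missing from one of a
session's two tests are dropped pairwise. Note that a lone spike in a small
sample can sit below 2.5 population SDs (in {1,1,1,1,100} the spike's z is
exactly 2.0) — the filter is deliberately not an "always remove the
extreme" rule.

## Pipelines and reproducibility

`run_study1` (between-subject environment validation) runs
training × environment mixed ANOVAs on training time and chests found and
one-way ANOVAs across environments on immediate-test time and placement
accuracy. `run_study2` (within-subject sleep/wake) runs condition × test
rmANOVAs per measure, the condition × radius × test dwell rmANOVA,
item-level ANOVAs treating each surviving (participant, object) pair as a
unit, correlation families at the global and item level per condition and
test, the approach-angle family per condition, and per-participant
difference scores (test 2 − test 1; placement error negated so positive
always means maintained/improved performance). Reports carry a manifest
(config hash, seed, versions, exclusion accounting — no participant is
dropped silently) and deterministic text artifacts: identical seeds yield
byte-identical logs, tables and manifests.

## Problem sizes

The shipped analyses favour sizes a laptop handles comfortably: calibration
studies use 1000 replicate 20-participant cohorts (type-I error of the
interaction lands at 0.05 ± 0.015), detection studies 200 replicate
29-participant cohorts, parameter recovery 2000–5000 trials per noise
level. The full test suite runs in a few minutes on one CPU.

## Known limitations

The agent is a stand-in, not a cognitive model: it does not search after
arriving (real dwell profiles include terminal search), walks at one speed,
explores without memory of covered ground beyond chest states, and its
training phases show no practice effect from training 1 to training 2 (the
empirical drop in training steps has no generator analogue). Passing tests
therefore certify the metric and statistical machinery and the generator's
stated properties — not that real participants behave like the agent.
Angle-heavy analyses treat wrapped degrees as linear quantities (as the
field does); correlations of angles near the ±180° boundary should be
interpreted with care.
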