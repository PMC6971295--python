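# Methods

## Model

The analysis container is a 3-way tensor **X** ∈ ℝ^(S×T×K): S channels
(joint angles in standardized units, or EMG envelopes scaled to a
per-subject maximum of 1), T = 200 time frames spanning one gait cycle
(right toe-off to the next right toe-off), and K tasks, each task being
locomotion by one subject at one belt speed (or 0.1 m/s speed bin).

CP decomposition approximates `X[i,j,k] ≈ Σ_r λ_r w[i,r] p[j,r] t[k,r]`
with unit-Euclidean-norm factor columns and λ_r ≥ 0 sorted descending.
`w_r` (spatial module) weights the channels, `p_r` (temporal module) is
the activation profile over the cycle, `t_r` (task-dependent modulation)
is the per-task recruitment gain.  Fit quality is the uncentered
coefficient of determination, vaf = 1 − ‖X−X̂‖²_F/‖X‖²_F; its complement
is the relative fitting error.  The identity vaf + error = 1 holds by
construction (same denominator ‖X‖²).

Two solvers minimise E = ½‖X−X̂‖²:

* **ALS** (unconstrained, joint angles): each sweep solves the three
  exact block least-squares problems through the matricized-tensor-times-
  Khatri-Rao system `A ← X₍ₙ₎ Kᵣ (G)⁻¹` with `G` the Hadamard product of
  the other factors' Gram matrices.  Rank-deficient systems fall back to
  a ridge-regularized solve with a warning.  After each sweep a
  line-search extrapolation along the sweep direction is tried with
  geometrically growing step and accepted only if it lowers the
  objective; this preserves per-sweep monotonicity while escaping the
  slow "swamps" plain ALS is known for.
* **Multiplicative updates** (non-negative, EMG): the Lee–Seung-type
  rule `A ← A ⊙ (X₍ₙ₎Kᵣ) / (A G)` with denominators floored at 1e−12;
  the objective is non-increasing per update and all factors stay ≥ 0.

Both use random restarts (standard-normal initialisation for ALS,
uniform(0.1, 1.1) for MU; default 10 restarts, best final objective
kept), a relative objective-change stopping tolerance (default 1e−8) and
an iteration cap (default 500 sweeps).  Restart seeds derive from a
single master seed through `numpy.random.SeedSequence`, so every fit is
reproducible.

**Sign gauge.** In unconstrained CP, flipping the signs of any two
factors of a component leaves the reconstruction unchanged.  Components
are reported in a fixed gauge: flip (w, p) so the temporal column's
largest-magnitude entry is positive, then flip (w, t) so the spatial
column's largest-magnitude entry is positive.  The two flips fix the
gauge completely, which makes concatenated-cosine congruence between
models well defined.  Applied flips are recorded on the model.

**Rank selection.** `select_rank` fits R = 1…R_max and returns the
smallest R whose vaf *strictly* exceeds the threshold (default 0.7, per
the "more than 70 %" rule; a vaf exactly at the threshold does not
qualify), together with the full vaf / fitting-error curves.  If no rank
qualifies, it raises an error reporting the best vaf reached.

**Degenerate fits.** For unconstrained CP, a best rank-R approximation
need not exist: on a positive-measure set of tensors two components
diverge while cancelling and the objective approaches an infimum that is
never attained.  The solvers then stop at the iteration cap with large,
near-collinear components; diagnostics report `converged = False` and
the objective history shows the slow tail.  Non-negative fits are immune
(the constraint set is closed).  The test suite checks solver optimality
against an independent direct-gradient minimizer strictly on instances
where the minimum is attained, and on degenerate instances verifies the
degeneracy signature and the proximity of the two truncations instead —
exact agreement between two truncations of a non-attained infimum is not
a well-posed requirement.

## Matrix baselines

`stack_tasks` lays the K task slices side by side, task-major, giving
Z ∈ ℝ^(S×(T·K)); `pca_modules` takes the leading left singular directions
of the *uncentered* Z (uncentered so the vaf definition matches the
tensor fits; a centered variant would change the baseline, not the CP
model), and `nnmf_modules` runs multiplicative-update NNMF with the same
restart defaults as the tensor solver.  At equal R the stacked model
spends (S + T·K)·R parameters against CP's (S + T + K)·R, so its fit is
at least as good — exactly so for PCA (Frobenius rank-R optimality),
and as a strong statistical tendency for NNMF.  Per-task temporal curves
come from reshaping a stacked temporal module into K rows.

## Walk/run contrast and ANOVA

`mode_discontinuity` computes, per component, |mean t over tasks at the
1.8 m/s walk reference − mean t over tasks at the 2.3 m/s run reference|
(averaging across subjects; with binned speeds the bin containing the
reference speed is used, and every subject must contribute both
references).  The top-2 components by this statistic are selected and
labeled walk- or run-dominant by the sign of the difference.  The
reference speeds sit inside the walk-to-run transition interval
(1.9–2.3 m/s), so below it everyone walks and above it everyone runs.

`rm_anova_two_way` is a classical two-factor within-subject ANOVA on
(subjects × muscles × 2 modes) spatial-module weights: each effect is
tested against its own effect-by-subject interaction term, giving the
interaction df ((M−1), (N−1)(M−1)) — (15, 225) for 16 muscles and 16
subjects.  No sphericity correction is applied by default (matching the
uncorrected df convention); the implementation is an explicit
sums-of-squares decomposition, cross-checked in the tests against
statsmodels' AnovaRM and a hand-computed worked example.  When the
interaction is significant, Tukey HSD contrasts compare walk vs run per
muscle using the interaction error mean square, with the studentized
range family spanning all 2M cell means; only the M per-muscle mode
contrasts are reported.  The exact per-contrast error term is a
convention choice — the interaction error term is assumed.

Component correspondence across fits (subject vs group models, estimate
vs ground truth) uses `match_components`: cosine similarity of
concatenated spatial+temporal columns (models in the package sign
gauge), maximized over one-to-one assignments by exhaustive permutation
(exact for R ≤ 8).  `recovery_score` is the mean matched congruence.

## Synthetic data

The generator plants a ground-truth CP model and adds noise, so every
downstream stage has a known answer:

* **Temporal modules**: Gaussian bumps in cycle phase, one peak per
  1/R-slot with ±0.2-slot jitter, width 0.03–0.06 cycle; 30 % of
  components get a second, smaller bump offset by 0.37 cycle
  (uni-/bimodal smooth profiles, as observed activation patterns are).
* **Spatial modules**: non-negative components get sparse channel groups
  (round-robin partition of channels with uniform(0.5, 1) weights plus a
  weak uniform(0, 0.08) background) — distinct dominant muscles per
  synergy; unconstrained components are standard normal, redrawn until
  no pair exceeds |cos| = 0.6, since in a 6-dimensional angle space
  unconstrained draws occasionally plant two nearly identical modules,
  which would contradict the distinct-modules premise of the designs.
* **Task modulations**: deterministic profiles over the task grid —
  `constant`, `speed_linear` (0.2 → 1.0 across the speed range),
  `walk_specific` / `run_specific` (plateau 1 in the preferred mode,
  1 − d in the other; default step d = 0.8).  Each synthetic subject's
  walk-to-run transition speed is drawn uniformly from 1.9–2.3 m/s.
* **Scales**: factor columns are unit-normalized first, then
  λ = 10·linspace(1.05, 0.95, R), so every component carries a
  comparable, mildly descending share of variance.
* **Noise**: i.i.d. Gaussian on every entry.  For non-negative models
  the noisy tensor is clipped at zero (envelopes cannot be negative);
  the pre-clip noise realization can be returned for oracle checks.
  Presets specify noise as a nominal pre-clip share of total energy and
  resolve the sd against the planted signal.

Two presets mirror the treadmill study designs.  The *joint-angle* study:
6 channels × 200 frames × (11 speeds × 15 subjects) = 165 tasks,
unconstrained, R = 3 planted components, noise share 0.25.  The *EMG*
study: 16 channels × 200 frames × (20 bins of 0.1 m/s over 0.5–2.5 m/s
× 8 subjects) = 160 tasks, non-negative, R = 6 planted components
including one walk-specific and one run-specific, noise share 0.48.
The EMG noise share was fixed once by pilot simulation so that the
70 %-variance rule lands on the planted rank (vaf(5) ≈ 0.67,
vaf(6) ≈ 0.72 across seeds); the speed range is narrower than the full
experimental ramp so the tensor stays small enough for replicated
single-CPU runs while still containing both the 1.8 m/s and 2.3 m/s
reference bins and walk and run tasks for every subject.

A second entry point synthesises *continuous* recordings: periodic
smooth channel templates warped to per-cycle durations (optionally
jittered), plus a vertical ground-reaction-force channel that is zero in
swing and a smooth double-hump pulse (peak ≈ 700 N) from foot contact to
the next toe-off, with the true contact/toe-off sample indices returned
for event-detection tests.

What the generator does *not* emulate: stride-to-stride waveform
variability beyond additive noise, EMG-specific noise structure
(rectified-noise floors, motion artifacts — the Gaussian-clip choice is
a stand-in, not an inference about real envelopes), inter-channel noise
correlation, and biomechanical consistency between the angle channels
and the GRF.  Passing tests therefore demonstrate correctness of the
algorithms under the planted model class, not robustness to every
real-data pathology.

## Preprocessing conventions

* Zero-lag filtering: Butterworth designed at the stated order (default
  4th, 15 Hz low-pass; EMG band-pass 20–450 Hz) applied forward and
  backward (`sosfiltfilt`), so the realized magnitude is |H(f)|².
* EMG envelope: full-wave rectification, then a zero-lag low-pass
  (default 4 Hz — the smoothing cutoff is a package default, stated
  here because the upstream convention specifies "smoothed" without a
  number) and a clip at zero to remove filter ringing.
* Gait events: vertical-GRF threshold crossings (default 20 N — also a
  package default) with a 50 ms minimum-phase debounce that removes
  chatter; detection equals a brute-force threshold scan on clean
  signals.
* Cycles are anchored right toe-off → next right toe-off (configurable
  to contact anchoring) and resampled to T = 200 frames by linear
  interpolation on a uniform phase grid including both endpoints —
  exact on linear signals, endpoints preserved.
* Joint angles: per (subject, angle), pooled mean 0 / SD 1 across all
  speeds and frames (idempotent).  EMG: per (subject, muscle), pooled
  maximum 1.  Stride averaging precedes standardization.
* Speed bins are half-open [lo, lo+width); a speed exactly at the upper
  range limit falls outside, which reproduces the 40-bin (0.3–4.3 m/s)
  and 47-bin (0.3–5.0 m/s) designs.  Empty bins warn and are recorded
  as missing tasks.

## Numerical choices and degenerate inputs

* vaf of a zero tensor is 1 for a zero model and an error otherwise.
* Zero factor columns get λ = 0, are kept as zeros and sort last.
* MU denominators floored at 1e−12; ALS mid-sweep column normalization
  for conditioning (scale re-absorbed by the next exact solve).
* select_rank ties break strictly (vaf must exceed the threshold).
* match_components with unequal ranks pairs the best min(R_a, R_b)
  components and reports the surplus unmatched.
* The ANOVA rejects incomplete designs rather than imputing.

## Problem sizes in the test suite

Replicated checks run on scaled designs chosen for single-CPU runs: the
EMG-like pipeline check uses the 16×200×160 preset with 20 replicates
(rank selection capped at R = 8, 2 restarts, 120 sweeps), solver-recovery
checks use K ≤ 48 task grids, the solver-vs-reference comparison uses
≤ 5×5×5 tensors, and the ANOVA null calibration uses 500 replicates of
the 16-subject × 16-muscle design.  `scripts/acceptance.py` re-runs the
same computations at 10 pipeline replicates.

## Known limitations

* Real joint-angle and EMG recordings are not distributed with the
  package; all quantitative claims are about the synthetic model class.
* Tucker decomposition, tri-factorisations, and smoothness-regularized
  CP are out of scope.
* The discontinuity statistic assumes every subject has tasks at (or
  binned to) both reference speeds; designs without them raise errors.
* Exhaustive component matching is exact but limited to R ≤ 8; larger
  models would need an assignment solver.
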