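# locomod

Spatiotemporal module extraction from human locomotion data by tensor
decomposition.

## The problem

During walking and running, the central nervous system appears to control
groups of joints and muscles together — *spatial modules* — each driven by
a *temporal module*, a stereotyped activation profile over the gait cycle.
How strongly each spatiotemporal module is recruited changes with the
movement task: belt speed, and whether the subject walks or runs.

Matrix decompositions (PCA, NNMF) of channels × time data can extract
spatial modules, but the task dimension is either flattened into the time
axis or analysed task by task, so spatial modules, temporal modules and
their task modulation cannot be separated in one model.  Arranging the
data as a 3-way tensor **X** ∈ ℝ^(S×T×K) — S channels (joint angles or
muscles), T = 200 time frames per normalized gait cycle, K tasks
(one per subject × speed) — and applying CP (CANDECOMP/PARAFAC)
decomposition gives all three at once:

```
X[i,j,k] ≈ Σ_r  λ_r · w[i,r] · p[j,r] · t[k,r],     r = 1 … R
```

with unit-norm factor columns (`wᵣᵀwᵣ = pᵣᵀpᵣ = tᵣᵀtᵣ = 1`), λ_r ≥ 0
carrying all scale.  `w_r` is the r-th spatial module, `p_r` its temporal
module and `t_r` its per-task recruitment gain.  Factors are fit by
minimising the squared error `E = ½ Σ (X − X̂)²`, unconstrained
(alternating least squares) for standardized joint angles or with
non-negativity constraints (multiplicative updates) for EMG envelopes.
Model order R is the smallest rank whose *variance accounted for*
(uncentered R², `1 − ‖X−X̂‖²/‖X‖²`) strictly exceeds 70 %.

The package is written for researchers in motor control / biomechanics
who want this analysis as a tested, reusable library rather than a
one-off script: it covers the preprocessing chain (zero-lag Butterworth
filtering, gait-event detection from vertical GRF, cycle segmentation,
200-frame time normalization, per-subject standardization/scaling,
0.1 m/s speed binning, tensor assembly), both CP solvers with restart
and rank-selection logic, PCA/NNMF matrix baselines on the task-stacked
S×(T·K) matrix, the walk-vs-run discontinuity statistic
`|t(1.8 m/s) − t(2.3 m/s)|` used to single out mode-specific modules, a
muscle × mode repeated-measures ANOVA with Tukey post-hoc contrasts, and
a synthetic-data generator that plants known modules so every stage is
testable end to end.

## Worked example

```python
import numpy as np
from locomod import (emg_study_spec, synthesize_study, select_rank,
                     CPOptions, mode_discontinuity, recovery_score)

# synthetic EMG-like study: 16 muscles x 200 frames x (20 speed bins x 8
# subjects), six planted modules incl. one walk- and one run-specific
truth, tensor = synthesize_study(emg_study_spec(seed=1))
print(tensor.shape)

opts = CPOptions(max_iter=150, tol=1e-7, n_restarts=2, seed=42)
R, curve = select_rank(tensor, threshold=0.7, R_max=8,
                       solver="nonneg", opts=opts)
print(R, np.round(curve["vaf"], 3))

model = curve["models"][R - 1]
contrast = mode_discontinuity(model, tensor.task_descriptors)
print(contrast.selected, contrast.dominance)
print(round(recovery_score(model, truth.model)[0], 3))
```

prints

```
(16, 200, 160)
6 [0.384 0.467 0.544 0.616 0.661 0.719 0.721 0.721]
(4, 3) {4: 'run', 3: 'walk'}
0.985
```

Six components are needed to exceed 70 % variance accounted for (the
planted rank); the two components whose task gains change most between
walking at 1.8 m/s and running at 2.3 m/s are the planted mode-specific
pair, labeled by which mode recruits them more; and the fitted factors
match the planted ones with mean congruence 0.985.

The same flow is available from the shell:

```bash
locomod simulate --seed 1 --out run/
locomod decompose --input run/tensor.h5 --auto --nonneg --out run/model.h5
locomod analyze --seed 1 --out run/        # full pipeline incl. ANOVA
locomod report --model run/model.h5 --tensor run/tensor.h5 --out run/fig.png
```

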