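"""Core containers shared across the pipeline.

The analysis operates on a 3-way data tensor ``X`` of shape
``(S channels, T time frames, K tasks)``: each frontal slice ``X[:, :, k]``
holds one task's channel-by-time matrix, where a "task" is locomotion at one
speed (or speed bin) for one subject.  A rank-R CP model approximates

    X[i, j, k] ~= sum_r  lambda_r * w[i, r] * p[j, r] * t[k, r]

with unit-norm factor columns, so all scale lives in ``lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

WALK = "walk"
RUN = "run"


@dataclass(frozen=True)
class TaskDescriptor:
    """One (subject, speed) locomotion condition.

    ``mode`` is ``"walk"`` below the subject's walk-to-run transition speed
    and ``"run"`` above it.  ``speed_bin_index`` is set when the speed axis
    has been discretised into fixed-width bins.
    """

    subject_id: int
    speed: float
    mode: str
    speed_bin_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError(f"speed must be positive, got {self.speed}")
        if self.mode not in (WALK, RUN):
            raise ValueError(f"mode must be 'walk' or 'run', got {self.mode!r}")


@dataclass
class DataTensor:
    """Labeled 3-way array (channels x frames x tasks)."""

    X: np.ndarray
    channel_labels: Sequence[str]
    task_descriptors: Sequence[TaskDescriptor]
    nonneg: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3:
            raise ValueError(f"tensor must be 3-way, got shape {self.X.shape}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("tensor contains non-finite values")
        S, _, K = self.X.shape
        if len(self.channel_labels) != S:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {S} channels"
            )
        if len(self.task_descriptors) != K:
            raise ValueError(
                f"{len(self.task_descriptors)} descriptors for {K} tasks"
            )
        if self.nonneg and self.X.min() < 0:
            raise ValueError("tensor flagged non-negative but has negative entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.X.shape

    def slice_task(self, k: int) -> np.ndarray:
        return self.X[:, :, k]


@dataclass
class CPModel:
    """Rank-R CP factorization with unit-norm columns.

    ``spatial`` (S x R) are the channel weightings ("spatial modules"),
    ``temporal`` (T x R) the activation profiles over the normalized gait
    cycle ("temporal modules"), ``task`` (K x R) the per-task recruitment
    gains ("task-dependent modulations").  ``weights`` are the non-negative
    component scales, sorted descending.  ``sign_flips`` records the
    reconstruction-invariant pairwise sign flips applied to resolve the sign
    indeterminacy of unconstrained fits.
    """

    weights: np.ndarray
    spatial: np.ndarray
    temporal: np.ndarray
    task: np.ndarray
    nonneg: bool = False
    sign_flips: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.spatial = np.asarray(self.spatial, dtype=float)
        self.temporal = np.asarray(self.temporal, dtype=float)
        self.task = np.asarray(self.task, dtype=float)
        R = self.weights.size
        for name, M in (("spatial", self.spatial),
                        ("temporal", self.temporal),
                        ("task", self.task)):
            if M.ndim != 2 or M.shape[1] != R:
                raise ValueError(f"{name} factor must have {R} columns, got {M.shape}")
        if np.any(self.weights < 0):
            raise ValueError("component weights must be non-negative")

    @property
    def R(self) -> int:
        return self.weights.size

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.spatial.shape[0], self.temporal.shape[0], self.task.shape[0])


@dataclass
class FitDiagnostics:
    """Convergence record of one CP fit (best restart)."""

    objective: float            # E = 1/2 ||X - Xhat||^2
    rel_fitting_error: float    # ||X - Xhat||^2 / ||X||^2
    vaf: float                  # 1 - rel_fitting_error (uncentered R^2)
    n_iter: int
    converged: bool
    n_restarts: int
    best_restart_seed: int
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class GroundTruthModel:
    """Planted CP factors plus the task design they were generated for."""

    model: CPModel
    task_descriptors: Sequence[TaskDescriptor]
    profiles: Sequence[str]
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.task_descriptors) != self.model.task.shape[0]:
            raise ValueError("descriptor count does not match task factor rows")
        if len(self.profiles) != self.model.R:
            raise ValueError("one modulation profile required per component")
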