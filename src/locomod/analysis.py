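"""Task-dependent modulation analysis of fitted CP models.

Covers the walk/run contrast on the task factors (which components change
discontinuously between walking at 1.8 m/s and running at 2.3 m/s),
component matching and recovery scoring against planted ground truth, and
the muscle x mode repeated-measures ANOVA with Tukey post-hoc contrasts on
the spatial-module weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .datatypes import RUN, WALK, CPModel, TaskDescriptor

__all__ = [
    "ModeContrast",
    "ComponentMatch",
    "AnovaEffect",
    "AnovaResult",
    "mode_discontinuity",
    "match_components",
    "recovery_score",
    "rm_anova_two_way",
]

WALK_REF_SPEED = 1.8  # m/s
RUN_REF_SPEED = 2.3   # m/s


@dataclass
class ModeContrast:
    """Per-component walk-run discontinuity and the top-2 selection."""

    discontinuity: np.ndarray          # |t(walk ref) - t(run ref)| per component
    ranked: np.ndarray                 # component indices, largest first
    selected: Tuple[int, int]          # top-2 component indices
    dominance: Dict[int, str]          # selected component -> 'walk' | 'run'
    walk_means: np.ndarray
    run_means: np.ndarray


@dataclass
class ComponentMatch:
    """One-to-one component assignment between two models."""

    assignment: np.ndarray   # assignment[i] = column of model_b matched to i of model_a
    congruences: np.ndarray  # cosine of concatenated matched factors, in [-1, 1]
    unmatched_a: List[int] = field(default_factory=list)
    unmatched_b: List[int] = field(default_factory=list)


@dataclass
class AnovaEffect:
    effect: str
    ss: float
    df1: int
    df2: int
    ms_error: float
    F: float
    p: float


@dataclass
class AnovaResult:
    """Two-factor within-subject ANOVA table plus per-muscle Tukey contrasts.

    ``posthoc`` rows are (muscle index, mean walk, mean run, adjusted p),
    computed against the interaction error term over the family of all
    muscle x mode cell means.
    """

    effects: Dict[str, AnovaEffect]
    posthoc: List[Tuple[int, float, float, float]]

    def __getitem__(self, effect: str) -> AnovaEffect:
        return self.effects[effect]


def _reference_tasks(descriptors: Sequence[TaskDescriptor], ref_speed: float,
                     bin_width: float = 0.1) -> np.ndarray:
    """Task indices whose speed matches (or whose bin contains) ``ref_speed``."""
    speeds = np.array([d.speed for d in descriptors])
    exact = np.nonzero(np.abs(speeds - ref_speed) < 1e-9)[0]
    if exact.size:
        return exact
    # binned speeds are represented by their bin centers; the bin
    # [ref, ref + width) contains the reference speed
    hits = np.nonzero((speeds - ref_speed >= 0) & (speeds - ref_speed < bin_width))[0]
    return hits


def mode_discontinuity(model: CPModel,
                       descriptors: Sequence[TaskDescriptor],
                       walk_ref: float = WALK_REF_SPEED,
                       run_ref: float = RUN_REF_SPEED,
                       bin_width: float = 0.1) -> ModeContrast:
    """Walk-run discontinuity statistic and top-2 component selection.

    For each component r the statistic is |mean_k t[k, r] over walk-reference
    tasks - mean over run-reference tasks|, averaging across subjects.  The
    two components with the largest statistic are selected; each is labeled
    walk-dominant if its walk-reference modulation exceeds the run-reference
    one, run-dominant otherwise.
    """
    if len(descriptors) != model.task.shape[0]:
        raise ValueError("descriptor count does not match task factor rows")
    walk_idx = _reference_tasks(descriptors, walk_ref, bin_width)
    run_idx = _reference_tasks(descriptors, run_ref, bin_width)
    subjects = {d.subject_id for d in descriptors}
    for s in sorted(subjects):
        if not any(descriptors[k].subject_id == s for k in walk_idx):
            raise ValueError(f"subject {s} has no task at walk reference "
                             f"speed {walk_ref} m/s")
        if not any(descriptors[k].subject_id == s for k in run_idx):
            raise ValueError(f"subject {s} has no task at run reference "
                             f"speed {run_ref} m/s")
    walk_means = model.task[walk_idx].mean(axis=0)
    run_means = model.task[run_idx].mean(axis=0)
    disc = np.abs(walk_means - run_means)
    ranked = np.argsort(-disc, kind="stable")
    if model.R < 2:
        raise ValueError("top-2 selection requires at least 2 components")
    selected = (int(ranked[0]), int(ranked[1]))
    dominance = {r: (WALK if walk_means[r] > run_means[r] else RUN)
                 for r in selected}
    return ModeContrast(discontinuity=disc, ranked=ranked, selected=selected,
                        dominance=dominance, walk_means=walk_means,
                        run_means=run_means)


def _congruence_matrix(model_a: CPModel, model_b: CPModel,
                       use_spatial: bool = True,
                       use_temporal: bool = True,
                       use_task: bool = False) -> np.ndarray:
    """Pairwise cosine similarity of concatenated (normalized) factor blocks."""
    blocks_a, blocks_b = [], []
    if use_spatial:
        blocks_a.append(model_a.spatial)
        blocks_b.append(model_b.spatial)
    if use_temporal:
        blocks_a.append(model_a.temporal)
        blocks_b.append(model_b.temporal)
    if use_task:
        blocks_a.append(model_a.task)
        blocks_b.append(model_b.task)
    if not blocks_a:
        raise ValueError("at least one factor block required for matching")
    A = np.vstack(blocks_a)
    B = np.vstack(blocks_b)
    na = np.maximum(np.linalg.norm(A, axis=0), 1e-300)
    nb = np.maximum(np.linalg.norm(B, axis=0), 1e-300)
    return (A / na).T @ (B / nb)


def match_components(model_a: CPModel, model_b: CPModel,
                     use_spatial: bool = True, use_temporal: bool = True,
                     use_task: bool = False) -> ComponentMatch:
    """Optimal one-to-one component assignment by exhaustive permutation.

    Maximizes the total congruence (cosine similarity of concatenated
    spatial+temporal factor columns; both models should carry the package
    sign convention).  Exhaustive search is exact for min(R_a, R_b) <= 8.
    When ranks differ, the min(R_a, R_b) best-matching components are
    paired and the surplus reported unmatched.
    """
    C = _congruence_matrix(model_a, model_b, use_spatial, use_temporal, use_task)
    Ra, Rb = C.shape
    n = min(Ra, Rb)
    if n > 8:
        raise ValueError("exhaustive matching supported for rank <= 8")
    rows = list(range(Ra))
    best_perm, best_total = None, -np.inf
    # choose which n rows participate when Ra > n, then the column order
    from itertools import combinations
    for rsel in (combinations(rows, n) if Ra > n else [tuple(rows)]):
        for csel in permutations(range(Rb), n):
            total = sum(C[r, c] for r, c in zip(rsel, csel))
            if total > best_total:
                best_total = total
                best_perm = (rsel, csel)
    rsel, csel = best_perm
    assignment = np.full(Ra, -1, dtype=int)
    cong = np.full(Ra, np.nan)
    for r, c in zip(rsel, csel):
        assignment[r] = c
        cong[r] = C[r, c]
    unmatched_a = [r for r in range(Ra) if assignment[r] < 0]
    unmatched_b = [c for c in range(Rb) if c not in set(csel)]
    return ComponentMatch(assignment=assignment, congruences=cong,
                          unmatched_a=unmatched_a, unmatched_b=unmatched_b)


def recovery_score(estimated: CPModel, truth: CPModel,
                   use_task: bool = False) -> Tuple[float, ComponentMatch]:
    """Mean matched congruence of an estimated model against ground truth."""
    match = match_components(estimated, truth, use_task=use_task)
    return float(np.nanmean(match.congruences)), match


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_two_way(weights: np.ndarray, alpha: float = 0.05,
                     run_posthoc: Optional[bool] = None) -> AnovaResult:
    """Two-factor within-subject ANOVA on (subjects x muscles x modes) weights.

    Both factors are within-subject; the design must be complete and
    balanced with one observation per cell (no imputation).  Each effect is
    tested against its own effect-by-subject interaction error term
    (classical sums-of-squares decomposition, no sphericity correction):

        F_muscle      = MS_muscle / MS_{muscle x subject}
        F_mode        = MS_mode / MS_{mode x subject}
        F_interaction = MS_{muscle x mode} / MS_{muscle x mode x subject}

    With M muscles, 2 modes and N subjects the interaction test has
    df = ((M-1), (N-1)(M-1)).  When the interaction is significant at
    ``alpha`` (or ``run_posthoc`` is forced), Tukey HSD contrasts compare
    walk vs run per muscle using the interaction error term, with the
    studentized-range family spanning all 2M cell means.
    """
    Y = np.asarray(weights, dtype=float)
    if Y.ndim != 3 or Y.shape[2] != 2:
        raise ValueError("weights must be (subjects, muscles, 2 modes)")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing or non-finite cells; the design must be complete")
    N, M, B = Y.shape
    if N < 2 or M < 2:
        raise ValueError("need at least 2 subjects and 2 muscles")

    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))     # subject means
    m_a = Y.mean(axis=(0, 2))     # muscle means
    m_b = Y.mean(axis=(0, 1))     # mode means
    m_ab = Y.mean(axis=0)         # muscle x mode cell means
    m_sa = Y.mean(axis=2)         # subject x muscle
    m_sb = Y.mean(axis=1)         # subject x mode

    ss_a = N * B * np.sum((m_a - grand) ** 2)
    ss_b = N * M * np.sum((m_b - grand) ** 2)
    ss_ab = N * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = B * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = M * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (Y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_abs = np.sum(resid ** 2)

    df_a, df_b, df_ab = M - 1, B - 1, (M - 1) * (B - 1)
    df_sa, df_sb, df_abs = (N - 1) * df_a, (N - 1) * df_b, (N - 1) * df_ab

    def effect(name, ss, df1, ss_err, df2):
        ms_err = ss_err / df2
        F = (ss / df1) / ms_err if ms_err > 0 else np.inf
        p = float(f_dist.sf(F, df1, df2))
        return AnovaEffect(effect=name, ss=float(ss), df1=df1, df2=df2,
                           ms_error=float(ms_err), F=float(F), p=p)

    effects = {
        "muscle": effect("muscle", ss_a, df_a, ss_sa, df_sa),
        "mode": effect("mode", ss_b, df_b, ss_sb, df_sb),
        "interaction": effect("interaction", ss_ab, df_ab, ss_abs, df_abs),
    }

    posthoc: List[Tuple[int, float, float, float]] = []
    inter = effects["interaction"]
    do_posthoc = inter.p < alpha if run_posthoc is None else run_posthoc
    if do_posthoc:
        se = np.sqrt(inter.ms_error / N)   # studentized-range scale per cell mean
        k_family = M * B
        for m in range(M):
            mw, mr = m_ab[m, 0], m_ab[m, 1]
            q = abs(mw - mr) / se if se > 0 else np.inf
            p_adj = float(studentized_range.sf(q, k_family, inter.df2))
            posthoc.append((m, float(mw), float(mr), p_adj))
    return AnovaResult(effects=effects, posthoc=posthoc)
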