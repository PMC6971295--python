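"""Synthetic locomotor data with planted ground truth.

Every downstream stage (preprocessing, CP fitting, module analysis) is
exercised against data whose generating factors are known exactly.  The
generator plants a rank-R CP model whose structure mimics treadmill
locomotion studies:

* temporal modules are smooth Gaussian bumps in gait-cycle phase
  (uni- or bimodal activation profiles over the 200-frame cycle);
* task-dependent modulations follow declared profiles — constant,
  linearly increasing with belt speed, walk-specific, or run-specific
  (a step discontinuity at each subject's walk-to-run transition);
* each synthetic subject's transition speed is drawn uniformly from a
  configured interval, 1.9–2.3 m/s by default.

All factor columns are unit-norm, so component scale lives entirely in
``lambda``.  A second entry point synthesises continuous multichannel
recordings with a vertical ground-reaction-force channel and known gait
event times, for testing the preprocessing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import (RUN, WALK, CPModel, DataTensor, GroundTruthModel,
                        TaskDescriptor)
from .cp import normalize_components, reconstruct

__all__ = [
    "SyntheticSpec",
    "RecordingSpec",
    "MotionRecording",
    "generate_ground_truth",
    "task_profile",
    "synthesize_tensor",
    "synthesize_raw_recording",
    "emg_study_spec",
    "joint_angle_study_spec",
]

PROFILES = ("constant", "speed_linear", "walk_specific", "run_specific")
TRANSITION_INTERVAL = (1.9, 2.3)  # m/s, walk-to-run


@dataclass
class SyntheticSpec:
    """Design of one synthetic tensor study.

    ``speeds`` is the ascending belt-speed grid (or bin centers); tasks are
    ordered subject-major, speed ascending, K = n_subjects * len(speeds).
    ``modulation_profiles`` names one task-modulation shape per component;
    ``discontinuity_size`` is the step (on the raw, pre-normalization
    profile whose plateau is 1) between the preferred and non-preferred
    mode of walk-/run-specific components.
    """

    n_channels: int
    n_subjects: int
    speeds: Sequence[float]
    R: int
    modulation_profiles: Sequence[str]
    n_frames: int = 200
    noise_sd: float = 0.0
    discontinuity_size: float = 0.8
    nonneg: bool = True
    seed: int = 0
    transition_interval: tuple = TRANSITION_INTERVAL

    def __post_init__(self) -> None:
        if min(self.n_channels, self.n_subjects, self.n_frames, self.R) < 1:
            raise ValueError("all dimensions must be positive")
        if len(self.speeds) < 1 or min(self.speeds) <= 0:
            raise ValueError("speeds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.modulation_profiles) != self.R:
            raise ValueError("one modulation profile per component required")
        for p in self.modulation_profiles:
            if p not in PROFILES:
                raise ValueError(f"unknown profile {p!r}; choose from {PROFILES}")
        if not (0 <= self.discontinuity_size <= 1):
            raise ValueError("discontinuity_size must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.n_subjects * len(self.speeds)


def _child_seeds(seed: int, n: int):
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def make_task_descriptors(spec: SyntheticSpec) -> list[TaskDescriptor]:
    """Subject-major, speed-ascending task list with per-subject transitions."""
    seed_t, = _child_seeds(spec.seed, 3)[:1]
    rng = np.random.default_rng(seed_t)
    lo, hi = spec.transition_interval
    transitions = rng.uniform(lo, hi, size=spec.n_subjects)
    speeds = sorted(spec.speeds)
    out = []
    for s in range(spec.n_subjects):
        for b, v in enumerate(speeds):
            mode = WALK if v < transitions[s] else RUN
            out.append(TaskDescriptor(subject_id=s, speed=float(v), mode=mode,
                                      speed_bin_index=b))
    return out


def task_profile(profile: str, descriptors: Sequence[TaskDescriptor],
                 discontinuity_size: float = 0.8) -> np.ndarray:
    """Raw (pre-normalization) task-modulation profile over the task list.

    constant      : 1 everywhere
    speed_linear  : 0.2 + 0.8 * (speed - min) / (max - min), increasing
    walk_specific : 1 on walk tasks, 1 - d on run tasks
    run_specific  : 1 on run tasks, 1 - d on walk tasks
    """
    speeds = np.array([d.speed for d in descriptors])
    is_run = np.array([d.mode == RUN for d in descriptors])
    if profile == "constant":
        return np.ones(len(descriptors))
    if profile == "speed_linear":
        span = speeds.max() - speeds.min()
        x = (speeds - speeds.min()) / span if span > 0 else np.zeros_like(speeds)
        return 0.2 + 0.8 * x
    if profile == "walk_specific":
        return np.where(is_run, 1.0 - discontinuity_size, 1.0)
    if profile == "run_specific":
        return np.where(is_run, 1.0, 1.0 - discontinuity_size)
    raise ValueError(f"unknown profile {profile!r}")


def _temporal_bumps(rng, T: int, R: int) -> np.ndarray:
    """Smooth unimodal/bimodal activation bumps with well-spread peaks."""
    phase = (np.arange(T) + 0.5) / T
    centers = (np.arange(R) + 0.5 + rng.uniform(-0.2, 0.2, R)) / R  # one peak per slot
    P = np.empty((T, R))
    for r in range(R):
        width = rng.uniform(0.03, 0.06)
        col = np.exp(-0.5 * ((phase - centers[r]) / width) ** 2)
        if rng.random() < 0.3:  # occasional bimodal profile
            c2 = (centers[r] + 0.37) % 1.0  # off the other components' slots
            col = col + rng.uniform(0.3, 0.6) * np.exp(
                -0.5 * ((phase - c2) / width) ** 2)
        P[:, r] = col
    return P


def _spatial_factors(rng, S: int, R: int, nonneg: bool) -> np.ndarray:
    if not nonneg:
        # distinct modules: redraw columns until no pair is near-collinear
        # (random Gaussians in low dimension, e.g. 6 joint angles, otherwise
        # occasionally plant two almost identical modules)
        W = rng.standard_normal((S, R))
        for _ in range(200):
            U = W / np.linalg.norm(W, axis=0)
            C = np.abs(U.T @ U) - np.eye(R)
            i, j = np.unravel_index(np.argmax(C), C.shape)
            if C[i, j] <= 0.6:
                break
            W[:, j] = rng.standard_normal(S)
        return W
    # sparse non-negative channel groups: each synergy has its own dominant
    # muscles (round-robin partition) plus a weak shared background, keeping
    # planted components well separated but not artificially orthogonal
    W = rng.uniform(0.0, 0.08, (S, R))
    perm = rng.permutation(S)
    for i, ch in enumerate(perm):
        W[ch, i % R] = rng.uniform(0.5, 1.0)
    return W


def generate_ground_truth(spec: SyntheticSpec) -> GroundTruthModel:
    """Plant a unit-norm-column CP model following ``spec``.

    Deterministic given ``spec.seed``.  Component scales are set mildly
    descending so every component carries a comparable share of variance.
    """
    seeds = _child_seeds(spec.seed, 3)
    rng = np.random.default_rng(seeds[1])
    descriptors = make_task_descriptors(spec)

    W = _spatial_factors(rng, spec.n_channels, spec.R, spec.nonneg)
    P = _temporal_bumps(rng, spec.n_frames, spec.R)
    Tk = np.column_stack([
        task_profile(p, descriptors, spec.discontinuity_size)
        for p in spec.modulation_profiles])
    # unit-normalize columns first so lambda alone sets each component's
    # share of variance (mildly descending, comparable contributions)
    for M in (W, P, Tk):
        M /= np.linalg.norm(M, axis=0)
    lam = 10.0 * np.linspace(1.05, 0.95, spec.R)
    model = normalize_components(W, P, Tk, weights=lam, nonneg=spec.nonneg)
    profiles = list(spec.modulation_profiles)  # lam already descending
    return GroundTruthModel(model=model, task_descriptors=descriptors,
                            profiles=profiles, noise_sd=spec.noise_sd,
                            seed=spec.seed)


def synthesize_tensor(truth: GroundTruthModel, noise_sd: Optional[float] = None,
                      seed: Optional[int] = None, return_noise: bool = False):
    """Evaluate the planted CP model and add i.i.d. Gaussian noise.

    For non-negative models the noisy tensor is clipped at zero (EMG
    envelopes cannot be negative); the pre-clip noise array is returned when
    ``return_noise`` so oracle checks can reconstruct the exact realization.
    At ``noise_sd = 0`` the tensor equals the exact CP reconstruction.
    """
    sd = truth.noise_sd if noise_sd is None else float(noise_sd)
    if sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if seed is None:
        seed = _child_seeds(truth.seed or 0, 3)[2]
    signal = reconstruct(truth.model)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd, size=signal.shape) if sd > 0 else np.zeros_like(signal)
    X = signal + noise
    if truth.model.nonneg:
        X = np.clip(X, 0.0, None)
    S = signal.shape[0]
    tensor = DataTensor(X=X, channel_labels=[f"ch{i}" for i in range(S)],
                        task_descriptors=list(truth.task_descriptors),
                        nonneg=truth.model.nonneg)
    return (tensor, noise) if return_noise else tensor


def noise_sd_for_energy_fraction(truth: GroundTruthModel, fraction: float) -> float:
    """Noise sd giving a nominal pre-clip noise-energy fraction of the total.

    Solves  f = E_noise / (E_signal + E_noise)  with  E_noise = sd^2 * S*T*K.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0:
        return 0.0
    signal = reconstruct(truth.model)
    e_sig = float(np.sum(signal ** 2))
    return float(np.sqrt(fraction / (1 - fraction) * e_sig / signal.size))


# ---------------------------------------------------------------------------
# study-condition presets
# ---------------------------------------------------------------------------

def bin_centers(lo: float, hi: float, width: float = 0.1) -> list[float]:
    n = int(round((hi - lo) / width))
    return [lo + width * (b + 0.5) for b in range(n)]


def joint_angle_study_spec(seed: int = 0,
                           noise_energy_fraction: float = 0.25) -> SyntheticSpec:
    """Joint-angle-like design: 6 angles, 200 frames, 11 speeds x 15 subjects.

    Six treadmill walking speeds and five running speeds, unconstrained
    (standardized angles are signed), R = 3 planted components.  The noise
    level is relative to the planted signal energy and resolved by
    :func:`synthesize_study`.
    """
    speeds = [0.56, 0.83, 1.11, 1.39, 1.67, 1.94, 2.22, 2.50, 2.78, 3.06, 3.33]
    spec = SyntheticSpec(
        n_channels=6, n_subjects=15, speeds=speeds, R=3,
        modulation_profiles=["speed_linear", "constant", "run_specific"],
        noise_sd=0.0, nonneg=False, seed=seed)
    spec._noise_energy_fraction = noise_energy_fraction
    return spec


def emg_study_spec(seed: int = 0, n_subjects: int = 8,
                   speed_range: tuple = (0.5, 2.5),
                   noise_energy_fraction: float = 0.48) -> SyntheticSpec:
    """EMG-like design: 16 muscles, 200 frames, 0.1 m/s speed bins.

    Six planted non-negative components: one walk-specific, one
    run-specific, and four speed-graded/constant distractors — the module
    mix the walk/run contrast analysis expects.  The default 0.5–2.5 m/s
    range gives 20 bins covering both the 1.8 m/s walk and 2.3 m/s run
    reference bins (so K = 160 at 8 subjects).  ``noise_energy_fraction``
    sets the nominal pre-clip noise energy share; ``noise_sd`` is resolved
    against the planted signal by :func:`synthesize_study`.
    """
    speeds = bin_centers(*speed_range)
    spec = SyntheticSpec(
        n_channels=16, n_subjects=n_subjects, speeds=speeds, R=6,
        modulation_profiles=["speed_linear", "run_specific", "constant",
                             "speed_linear", "walk_specific", "constant"],
        noise_sd=0.0, nonneg=True, seed=seed)
    spec._noise_energy_fraction = noise_energy_fraction  # resolved at synth time
    return spec


def synthesize_study(spec: SyntheticSpec):
    """Ground truth + noisy tensor in one call, resolving relative noise.

    If the spec carries a ``_noise_energy_fraction`` (study presets), the
    noise sd is derived from the planted signal energy; otherwise
    ``spec.noise_sd`` is used directly.
    """
    truth = generate_ground_truth(spec)
    frac = getattr(spec, "_noise_energy_fraction", None)
    sd = noise_sd_for_energy_fraction(truth, frac) if frac is not None else spec.noise_sd
    truth.noise_sd = sd
    tensor = synthesize_tensor(truth, noise_sd=sd)
    return truth, tensor


# ---------------------------------------------------------------------------
# continuous raw recordings
# ---------------------------------------------------------------------------

@dataclass
class RecordingSpec:
    """Continuous multichannel recording design with a vertical GRF channel."""

    n_cycles: int
    fs: float = 100.0
    n_channels: int = 6
    cycle_duration_s: float = 1.0
    cycle_duration_jitter: float = 0.0   # fractional sd of per-cycle duration
    stance_fraction: float = 0.6
    grf_peak_n: float = 700.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("at least one cycle required")
        if self.fs <= 0 or self.cycle_duration_s <= 0:
            raise ValueError("fs and cycle duration must be positive")
        if not (0 < self.stance_fraction < 1):
            raise ValueError("stance_fraction must lie in (0, 1)")


@dataclass
class MotionRecording:
    """Continuous signals (channels x samples) plus vertical GRF, sample-aligned."""

    signals: np.ndarray
    grf_z: np.ndarray
    fs: float
    channel_labels: Sequence[str] = field(default_factory=list)
    true_contacts: Optional[np.ndarray] = None
    true_toe_offs: Optional[np.ndarray] = None
    channel_templates: Optional[np.ndarray] = None  # channels x template length


def synthesize_raw_recording(spec: RecordingSpec) -> MotionRecording:
    """Continuous joint-angle-like channels with a pulsed GRF channel.

    Each gait cycle starts at toe-off; foot contact occurs a swing-phase
    later and the GRF carries a smooth double-hump stance pulse from contact
    to the next toe-off.  True contact and toe-off sample indices are
    returned for event-detection tests.  Channel waveforms are periodic
    smooth templates warped to each cycle's duration.
    """
    seeds = _child_seeds(spec.seed, 2)
    rng = np.random.default_rng(seeds[0])
    durations = np.full(spec.n_cycles, spec.cycle_duration_s)
    if spec.cycle_duration_jitter > 0:
        durations *= 1.0 + spec.cycle_duration_jitter * rng.standard_normal(spec.n_cycles)
        durations = np.clip(durations, 0.3 * spec.cycle_duration_s, None)
    n_per_cycle = np.maximum((durations * spec.fs).round().astype(int), 4)
    total = int(n_per_cycle.sum()) + 1

    t_template = np.linspace(0.0, 1.0, 512)
    rng_t = np.random.default_rng(seeds[1])
    templates = np.zeros((spec.n_channels, t_template.size))
    for c in range(spec.n_channels):
        a1, a2 = rng_t.uniform(5, 30, 2)
        ph1, ph2 = rng_t.uniform(0, 2 * np.pi, 2)
        templates[c] = (a1 * np.sin(2 * np.pi * t_template + ph1)
                        + a2 * 0.4 * np.sin(4 * np.pi * t_template + ph2))

    signals = np.zeros((spec.n_channels, total))
    grf = np.zeros(total)
    toe_offs = np.zeros(spec.n_cycles, dtype=int)
    contacts = np.zeros(spec.n_cycles, dtype=int)
    start = 0
    swing = 1.0 - spec.stance_fraction
    for i, n in enumerate(n_per_cycle):
        phase = np.arange(n) / n
        for c in range(spec.n_channels):
            signals[c, start:start + n] = np.interp(phase, t_template, templates[c])
        toe_offs[i] = start
        contact_off = int(round(swing * n))
        contacts[i] = start + contact_off
        stance_phase = (phase - swing) / spec.stance_fraction
        in_stance = (stance_phase >= 0) & (stance_phase < 1)
        hump = np.sin(np.pi * stance_phase[in_stance]) * (
            1.0 + 0.25 * np.sin(2 * np.pi * stance_phase[in_stance]))
        grf[start:start + n][in_stance] = spec.grf_peak_n * hump
        start += n
    signals[:, -1] = signals[:, 0]
    if spec.noise_sd > 0:
        signals = signals + rng.normal(0, spec.noise_sd, signals.shape)

    return MotionRecording(
        signals=signals, grf_z=grf, fs=spec.fs,
        channel_labels=[f"ch{c}" for c in range(spec.n_channels)],
        true_contacts=contacts, true_toe_offs=toe_offs,
        channel_templates=templates)
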