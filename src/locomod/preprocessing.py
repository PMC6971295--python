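"""From continuous recordings to the analysis tensor.

The chain mirrors standard treadmill-locomotion processing: zero-lag
Butterworth filtering, gait-event detection from the vertical ground
reaction force, cycle segmentation anchored at right-foot toe-off,
time-normalization of every cycle to 200 frames, per-subject
standardization (joint angles) or per-muscle max scaling (EMG),
0.1 m/s speed binning with within-bin averaging, and assembly of the
(channels x frames x tasks) tensor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .datatypes import DataTensor, TaskDescriptor

__all__ = [
    "GaitEvents",
    "CycleMatrix",
    "butterworth_zero_lag",
    "rectify_and_smooth",
    "detect_gait_events",
    "segment_cycles",
    "time_normalize",
    "standardize_joint_angles",
    "scale_emg",
    "bin_speeds",
    "assign_and_average",
    "assemble_tensor",
]

DEFAULT_FRAMES = 200
DEFAULT_GRF_THRESHOLD_N = 20.0
DEFAULT_MIN_PHASE_MS = 50.0


@dataclass
class GaitEvents:
    """Foot-contact and toe-off sample indices, each strictly increasing."""

    contacts: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)
        for name, idx in (("contacts", self.contacts), ("toe_offs", self.toe_offs)):
            if idx.size > 1 and np.any(np.diff(idx) <= 0):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass
class CycleMatrix:
    """One channels x frames cycle (or within-bin average of cycles)."""

    values: np.ndarray
    descriptor: TaskDescriptor

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("cycle matrix must be 2-D (channels x frames)")


def butterworth_zero_lag(x: np.ndarray, cutoff_hz, fs: float,
                         order: int = 4, band: str = "low") -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth filter.

    ``cutoff_hz`` is a scalar for low/high-pass or a (lo, hi) pair for
    band-pass.  The filter is designed at ``order`` and applied twice
    (filtfilt), so the magnitude response is |H(f)|^2 of the prototype.
    Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    wn = np.atleast_1d(np.asarray(cutoff_hz, dtype=float))
    if np.any(wn <= 0) or np.any(wn >= nyq):
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyq}) Hz")
    sos = sps.butter(order, wn / nyq if wn.size > 1 else wn[0] / nyq,
                     btype=band, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal of length {x.shape[-1]} too short for filter warm-up "
            f"(needs > {padlen} samples)")
    return sps.sosfiltfilt(sos, x, axis=-1)


def rectify_and_smooth(emg_raw: np.ndarray, fs: float,
                       smoothing_cutoff_hz: float = 4.0,
                       order: int = 4) -> np.ndarray:
    """Full-wave rectify then low-pass to an amplitude envelope.

    The zero-lag low-pass can ring slightly below zero near sharp bursts;
    the envelope is clipped at zero afterwards.
    """
    env = butterworth_zero_lag(np.abs(np.asarray(emg_raw, dtype=float)),
                               smoothing_cutoff_hz, fs, order=order, band="low")
    return np.clip(env, 0.0, None)


def detect_gait_events(grf_z: np.ndarray, fs: float,
                       threshold_n: float = DEFAULT_GRF_THRESHOLD_N,
                       min_phase_ms: float = DEFAULT_MIN_PHASE_MS) -> GaitEvents:
    """Threshold-crossing gait events from the vertical GRF.

    Foot contact is an upward crossing of ``threshold_n``; toe-off is the
    next downward crossing.  Stance or swing phases shorter than
    ``min_phase_ms`` are treated as chatter and merged away.  An empty
    event list (with a warning) is returned when the signal never crosses
    the threshold.
    """
    grf_z = np.asarray(grf_z, dtype=float)
    above = grf_z > threshold_n
    d = np.diff(above.astype(np.int8))
    contacts = list(np.nonzero(d == 1)[0] + 1)
    toe_offs = list(np.nonzero(d == -1)[0] + 1)
    if not contacts and not toe_offs:
        warnings.warn("GRF never crosses the event threshold; no gait events")
        return GaitEvents(np.empty(0, int), np.empty(0, int))

    min_samples = int(round(min_phase_ms * fs / 1000.0))
    # build the alternating event sequence, then remove short phases
    events: List[Tuple[int, str]] = sorted(
        [(i, "contact") for i in contacts] + [(i, "toe_off") for i in toe_offs])
    changed = True
    while changed:
        changed = False
        for j in range(len(events) - 1):
            if events[j + 1][0] - events[j][0] < min_samples:
                del events[j:j + 2]  # short phase: drop both bounding events
                changed = True
                break
    contacts = np.array([i for i, kind in events if kind == "contact"], dtype=int)
    toe_offs = np.array([i for i, kind in events if kind == "toe_off"], dtype=int)
    return GaitEvents(contacts, toe_offs)


def segment_cycles(signals: np.ndarray, events: GaitEvents,
                   anchor: str = "toe_off") -> List[np.ndarray]:
    """Split a channels x samples array into consecutive gait cycles.

    A cycle spans one anchoring event (right-foot toe-off by default) to the
    next occurrence of the same event, i.e. half-open sample intervals
    [a_i, a_{i+1}).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    anchors = {"toe_off": events.toe_offs, "contact": events.contacts}[anchor]
    if anchors.size < 2:
        raise ValueError("need at least two anchoring events for one full cycle")
    return [signals[:, a:b] for a, b in zip(anchors[:-1], anchors[1:])]


def time_normalize(cycle: np.ndarray, n_frames: int = DEFAULT_FRAMES) -> np.ndarray:
    """Linearly resample one cycle to ``n_frames`` points spanning it fully.

    The uniform phase grid includes both endpoints, so constant and linear
    signals are reproduced exactly and cycle endpoints are preserved.
    """
    cycle = np.atleast_2d(np.asarray(cycle, dtype=float))
    L = cycle.shape[1]
    if L < 2:
        raise ValueError("cycle must contain at least 2 samples")
    src = np.linspace(0.0, 1.0, L)
    dst = np.linspace(0.0, 1.0, n_frames)
    return np.vstack([np.interp(dst, src, ch) for ch in cycle])


SubjectCycles = Dict[int, List[CycleMatrix]]


def standardize_joint_angles(cycles_by_subject: SubjectCycles) -> SubjectCycles:
    """Per (subject, angle): pooled mean 0 and SD 1 across all speeds and frames.

    The pooled statistics are computed over the concatenation of all of the
    subject's cycle matrices, so comparisons across angles, speeds, and
    subjects are on a common scale.  Idempotent.
    """
    out: SubjectCycles = {}
    for subject, cycles in cycles_by_subject.items():
        pooled = np.concatenate([c.values for c in cycles], axis=1)
        mean = pooled.mean(axis=1)
        sd = pooled.std(axis=1)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            raise ValueError(
                f"subject {subject}: zero-variance channel(s) {zero.tolist()}")
        out[subject] = [
            CycleMatrix((c.values - mean[:, None]) / sd[:, None], c.descriptor)
            for c in cycles]
    return out


def scale_emg(cycles_by_subject: SubjectCycles) -> SubjectCycles:
    """Per (subject, muscle): maximum over all speeds and frames scaled to 1."""
    out: SubjectCycles = {}
    for subject, cycles in cycles_by_subject.items():
        pooled = np.concatenate([c.values for c in cycles], axis=1)
        if pooled.min() < 0:
            raise ValueError(f"subject {subject}: EMG envelopes must be >= 0")
        mx = pooled.max(axis=1)
        zero = np.nonzero(mx == 0)[0]
        if zero.size:
            raise ValueError(
                f"subject {subject}: all-zero muscle channel(s) {zero.tolist()}")
        out[subject] = [CycleMatrix(c.values / mx[:, None], c.descriptor)
                        for c in cycles]
    return out


def bin_speeds(speed_min: float, speed_max: float,
               width: float = 0.1) -> List[Tuple[float, float]]:
    """Half-open speed bins [lo, lo + width) covering [speed_min, speed_max)."""
    if speed_max <= speed_min or width <= 0:
        raise ValueError("need speed_max > speed_min and width > 0")
    n = int(round((speed_max - speed_min) / width))
    return [(speed_min + b * width, speed_min + (b + 1) * width) for b in range(n)]


def assign_and_average(cycles: Sequence[CycleMatrix],
                       bins: Sequence[Tuple[float, float]]) -> List[CycleMatrix]:
    """Frame-wise mean cycle per speed bin; empty bins are skipped with a warning.

    The averaged cycle's descriptor carries the bin center speed, the bin
    index, and the majority mode of the contributing cycles.
    """
    out: List[CycleMatrix] = []
    for b, (lo, hi) in enumerate(bins):
        members = [c for c in cycles if lo <= c.descriptor.speed < hi]
        if not members:
            warnings.warn(f"speed bin [{lo:.2f}, {hi:.2f}) m/s is empty; "
                          "task recorded as missing")
            continue
        mean = np.mean([c.values for c in members], axis=0)
        n_run = sum(c.descriptor.mode == "run" for c in members)
        mode = "run" if n_run * 2 > len(members) else "walk"
        d0 = members[0].descriptor
        out.append(CycleMatrix(mean, TaskDescriptor(
            subject_id=d0.subject_id, speed=(lo + hi) / 2.0, mode=mode,
            speed_bin_index=b)))
    return out


def assemble_tensor(cycle_matrices: Sequence[CycleMatrix],
                    channel_labels: Optional[Sequence[str]] = None,
                    nonneg: bool = False) -> DataTensor:
    """Stack per-task cycle matrices into the (S, T, K) analysis tensor.

    Tasks are ordered subject-major, speed ascending; the order is recorded
    in the tensor's descriptors and ``X[:, :, k]`` is bit-identical to the
    k-th input matrix.
    """
    if not cycle_matrices:
        raise ValueError("no cycle matrices to assemble")
    shapes = {c.values.shape for c in cycle_matrices}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent cycle shapes: {sorted(shapes)}")
    keys = [(c.descriptor.subject_id, c.descriptor.speed) for c in cycle_matrices]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (subject, speed) task descriptors")
    ordered = sorted(cycle_matrices,
                     key=lambda c: (c.descriptor.subject_id, c.descriptor.speed))
    X = np.stack([c.values for c in ordered], axis=2)
    S = X.shape[0]
    labels = list(channel_labels) if channel_labels is not None else [
        f"ch{i}" for i in range(S)]
    return DataTensor(X=X, channel_labels=labels,
                      task_descriptors=[c.descriptor for c in ordered],
                      nonneg=nonneg)
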