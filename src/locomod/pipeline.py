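"""End-to-end synthetic pipeline: simulate -> decompose -> analyze.

The analyze stage follows the per-subject aggregation scheme used for the
walk/run contrast: after rank selection on the all-subject tensor and
top-2 discontinuity selection, CP is refit per subject, each subject's
components are matched to the group model, and the muscle x mode
repeated-measures ANOVA runs on the matched spatial-module weights
(walk-dominant vs run-dominant component per subject).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import io as lio
from .analysis import (match_components, mode_discontinuity, recovery_score,
                       rm_anova_two_way)
from .config import PipelineConfig
from .cp import CPOptions, cp_als, cp_nonneg, select_rank
from .datatypes import WALK, DataTensor
from .synthetic import emg_study_spec, joint_angle_study_spec, synthesize_study

__all__ = ["run_pipeline", "simulate_stage", "decompose_stage", "analyze_stage"]


def _child_seed(seed: int, idx: int) -> int:
    return int(np.random.SeedSequence(seed).spawn(idx + 1)[idx].generate_state(1)[0]
               % (2**31))


def simulate_stage(config: PipelineConfig):
    syn = config.values["synthetic"]
    seed = _child_seed(config.values["seed"], 0)
    if syn["scenario"] == "emg":
        spec = emg_study_spec(seed=seed, n_subjects=syn["n_subjects"],
                              speed_range=tuple(syn["speed_range"]),
                              noise_energy_fraction=syn["noise_energy_fraction"])
    elif syn["scenario"] == "joint_angle":
        spec = joint_angle_study_spec(seed=seed)
    else:
        raise ValueError(f"unknown scenario {syn['scenario']!r}")
    return synthesize_study(spec)


def decompose_stage(config: PipelineConfig, tensor: DataTensor):
    dec = config.values["decompose"]
    seed = _child_seed(config.values["seed"], 1)
    opts = CPOptions(max_iter=dec["max_iter"], tol=dec["tol"],
                     n_restarts=dec["n_restarts"], seed=seed)
    solver = "nonneg" if dec["nonneg"] else "als"
    if dec["rank"] is not None:
        fit = cp_nonneg if dec["nonneg"] else cp_als
        model, diag = fit(tensor, dec["rank"], opts)
        curve = {"vaf": np.array([diag.vaf]),
                 "fitting_error": np.array([diag.rel_fitting_error])}
        return dec["rank"], model, diag, curve
    R_star, curve = select_rank(tensor, threshold=dec["threshold"],
                                R_max=dec["R_max"], solver=solver, opts=opts)
    model = curve["models"][R_star - 1]
    fit = cp_nonneg if dec["nonneg"] else cp_als
    return R_star, model, None, curve


def analyze_stage(config: PipelineConfig, tensor: DataTensor, model,
                  truth=None) -> Dict:
    ana = config.values["analyze"]
    dec = config.values["decompose"]
    contrast = mode_discontinuity(model, tensor.task_descriptors,
                                  walk_ref=ana["walk_ref_speed"],
                                  run_ref=ana["run_ref_speed"])
    report: Dict = {
        "discontinuity": contrast.discontinuity.tolist(),
        "selected_components": list(contrast.selected),
        "dominance": {str(k): v for k, v in contrast.dominance.items()},
    }

    # per-subject refits -> matched spatial weights -> muscle x mode rm-ANOVA
    labels = [contrast.dominance[r] for r in contrast.selected]
    if labels[0] == labels[1]:
        raise RuntimeError(
            "top-2 discontinuity components share the same dominance "
            f"({labels[0]}); no walk/run pair to contrast")
    walk_comp = next(r for r in contrast.selected
                     if contrast.dominance[r] == WALK)
    run_comp = next(r for r in contrast.selected
                    if contrast.dominance[r] != WALK)
    subjects = sorted({d.subject_id for d in tensor.task_descriptors})
    fit = cp_nonneg if dec["nonneg"] else cp_als
    seed = _child_seed(config.values["seed"], 2)
    weights = np.zeros((len(subjects), model.spatial.shape[0], 2))
    for i, s in enumerate(subjects):
        idx = [k for k, d in enumerate(tensor.task_descriptors)
               if d.subject_id == s]
        sub = DataTensor(X=tensor.X[:, :, idx],
                         channel_labels=tensor.channel_labels,
                         task_descriptors=[tensor.task_descriptors[k] for k in idx],
                         nonneg=tensor.nonneg)
        opts = CPOptions(max_iter=dec["max_iter"], tol=dec["tol"],
                         n_restarts=max(2, dec["n_restarts"] // 3),
                         seed=_child_seed(seed, i))
        sub_model, _ = fit(sub, model.R, opts)
        match = match_components(sub_model, model)
        inv = {int(c): r for r, c in enumerate(match.assignment) if c >= 0}
        weights[i, :, 0] = sub_model.spatial[:, inv[walk_comp]]
        weights[i, :, 1] = sub_model.spatial[:, inv[run_comp]]
    anova = rm_anova_two_way(weights, alpha=ana["alpha"])
    report["anova"] = {
        name: asdict(eff) for name, eff in anova.effects.items()}
    report["posthoc"] = [
        {"muscle": m, "mean_walk": w, "mean_run": r, "p_adj": p}
        for m, w, r, p in anova.posthoc]

    if truth is not None:
        score, match = recovery_score(model, truth.model)
        report["recovery"] = {
            "mean_congruence": score,
            "assignment": match.assignment.tolist(),
            "congruences": match.congruences.tolist(),
        }
    return report


def run_pipeline(config: PipelineConfig, outdir) -> Dict:
    """Run simulate -> decompose -> analyze, writing all artifacts to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.dump(outdir / "config.resolved.yaml")
    cfg_json = config.to_json()
    try:
        truth, tensor = simulate_stage(config)
        lio.save_ground_truth(outdir / "truth.h5", truth)
        lio.save_tensor(outdir / "tensor.h5", tensor,
                        seed=config.values["seed"], config_json=cfg_json)
    except Exception as e:
        raise RuntimeError(f"simulate stage failed: {e}") from e
    try:
        R_star, model, diag, curve = decompose_stage(config, tensor)
        lio.save_model(outdir / "model.h5", model, diag, config_json=cfg_json)
    except Exception as e:
        raise RuntimeError(f"decompose stage failed: {e}") from e
    try:
        report = analyze_stage(config, tensor, model, truth)
    except Exception as e:
        raise RuntimeError(f"analyze stage failed: {e}") from e
    report["selected_rank"] = int(R_star)
    report["vaf_curve"] = np.asarray(curve["vaf"]).tolist()
    report["config_digest"] = config.digest()
    report["seed"] = config.values["seed"]
    (outdir / "analysis.json").write_text(json.dumps(report, indent=2))
    return report
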