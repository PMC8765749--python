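"""End-to-end orchestration: simulate -> stabilize -> heartbeat -> extract
-> analyze-neural -> analyze-behavior, with a JSON run report.

The stage order is part of the contract; callers cannot reorder it.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SessionConfig
from .synth import Session, generate_session, blank_condition_id
from . import stabilization, heartbeat, extraction, neural, behavior

log = logging.getLogger("optomask")

__all__ = ["preprocess_session", "run_pipeline", "PreprocessResult"]


@dataclass
class PreprocessResult:
    samples: pd.DataFrame          # trial table + R (scalar) + z columns
    roi: extraction.Roi
    traces: list
    motion_coeffs: stabilization.MotionCoeffMap
    hb_model: heartbeat.HeartbeatModel
    detrend: extraction.DetrendResult
    blank_mean: float
    blank_sd: float
    dff_stacks: np.ndarray | None = None


def preprocess_session(session: Session, keep_stacks: bool = False,
                       skip_stabilize: bool = False) -> PreprocessResult:
    """Run the fixed preprocessing chain on one session's stacks."""
    if session.stacks is None:
        raise ValueError("session has no image stacks")
    cfg = session.config
    tl = session.timeline
    table = session.trial_table.reset_index(drop=True)
    prestim = tl.prestim_frames()
    baseline = tl.baseline_frames(cfg.n_baseline_frames)
    resp_frames = tl.response_frames(tuple(cfg.response_window_ms))
    blanks = (table["condition_id"] == blank_condition_id()).to_numpy()
    log.info("preprocess: %d trials (%d blanks)", len(table), int(blanks.sum()))

    # 1. stabilization (motion regression on raw intensities)
    if skip_stabilize:
        stacks = np.asarray(session.stacks, dtype=float)
        traces, coeffs = [], stabilization.MotionCoeffMap(
            np.zeros((2, cfg.ny, cfg.nx)))
    else:
        stacks, traces, coeffs = stabilization.stabilize_session(
            np.asarray(session.stacks, dtype=float), prestim, blanks)

    # 2. optional spatial downsampling
    if cfg.downsample > 1:
        stacks = np.stack([extraction.downsample_stack(s, cfg.downsample)
                           for s in stacks])

    # 3. dF/F
    dff = np.stack([extraction.compute_dff(s, baseline) for s in stacks])

    # 4. heartbeat removal (per pixel, per frame index)
    hb_model, _ = heartbeat.fit_heartbeat_model(dff, table)
    dff = heartbeat.remove_heartbeat(dff, hb_model, table)

    # 5. ROI on the visual-only response map
    vis_present = ((table["opto_power"] == 0) &
                   (table["target_contrast"] > 0)).to_numpy()
    if not vis_present.any():
        raise ValueError("no visual-only target-present trials for ROI selection")
    score_map = dff[vis_present][:, resp_frames].mean(axis=(0, 1))
    ds = cfg.downsample
    roi = extraction.select_roi(score_map, cfg.roi_mm, cfg.mm_per_px * ds)

    # 6. timecourses, anchoring/detrend, windowed scalar, z-score
    tc = extraction.roi_timecourses(dff, roi)
    sacc_ms = table["saccade_time_ms"].to_numpy(dtype=float)
    frame_rel_ms = tl.frame_times_ms - tl.target_onset_abs_ms
    valid = np.ones_like(tc, dtype=bool)
    has_sacc = np.isfinite(sacc_ms)
    valid[has_sacc] = frame_rel_ms[None, :] < sacc_ms[has_sacc, None]
    det = extraction.detrend(tc, table["condition_id"].to_numpy(), prestim,
                             valid_masks=valid,
                             frame_times_s=tl.frame_times_ms / 1000.0)
    R = extraction.summarize_response(det.timecourses, resp_frames)
    z, mu_b, sd_b = extraction.zscore_responses(R, blanks)

    samples = table.copy()
    samples["R"] = R
    samples["z"] = z
    return PreprocessResult(samples=samples, roi=roi, traces=traces,
                            motion_coeffs=coeffs, hb_model=hb_model,
                            detrend=det, blank_mean=mu_b, blank_sd=sd_b,
                            dff_stacks=dff if keep_stacks else None)


def analyze_neural(samples: pd.DataFrame, n_boot: int, seed: int) -> dict:
    """Contrast-response fits and bootstrapped rho per optostim power."""
    boot = neural.bootstrap_neural(samples, n_boot=n_boot, seed=seed)
    vis = samples[(samples["opto_power"] == 0) & (samples["target_contrast"] > 0)]
    g = vis.groupby("target_contrast")["z"].agg(["mean", "count"])
    nr_vis = neural.fit_naka_rushton(g.index.to_numpy(), g["mean"].to_numpy(),
                                     g["count"].to_numpy())
    out = {"naka_rushton_vis": {"z_max": nr_vis.z_max, "n": nr_vis.n,
                                "c50": nr_vis.c50, "rss": nr_vis.rss},
           "powers": {}}
    for power, res in boot.results.items():
        nr_sub = neural.fit_naka_rushton(res.contrasts, res.z_optosub, res.weights)
        out["powers"][f"{power:g}"] = {
            "rho": res.rho, "rho_sd": res.bootstrap_sd, "p": res.p_value,
            "out_of_range": bool(res.out_of_range),
            "z_optobase_mean": res.z_optobase_mean,
            "z_optobase_sd": res.z_optobase_sd,
            "contrasts": res.contrasts.tolist(),
            "z_vis": res.z_vis.tolist(),
            "z_optosub": res.z_optosub.tolist(),
            "naka_rushton_optosub": {"z_max": nr_sub.z_max, "n": nr_sub.n,
                                     "c50": nr_sub.c50},
        }
    return out


def analyze_behavior(table: pd.DataFrame, n_boot: int, seed: int) -> dict:
    summary = behavior.bootstrap_behavior(table, n_boot=n_boot, seed=seed)
    fit = summary.fit
    return {
        "beta": fit.beta,
        "blocks": {b: {"alpha": fit.alpha[b], "alpha_sd": summary.alpha_sd[b],
                       "delta": fit.delta[b], "delta_sd": summary.criterion_sd[b]}
                   for b in fit.alpha},
        "rho_behavior": {b: {"value": summary.rho_behavior[b],
                             "sd": summary.rho_behavior_sd[b],
                             "p": summary.rho_p[b],
                             "criterion_p": summary.criterion_p[b]}
                         for b in summary.rho_behavior},
        "nll": fit.nll,
    }


def _curve_tables(neural_report: dict, behavior_report: dict):
    cs = np.geomspace(0.01, 1.0, 50)
    nr = neural_report["naka_rushton_vis"]
    rows = [{"contrast": c,
             "z_vis_fit": float(neural.naka_rushton(c, nr["z_max"], nr["n"], nr["c50"]))}
            for c in cs]
    contrast_tbl = pd.DataFrame(rows)
    prows = []
    for b, info in behavior_report["blocks"].items():
        for c in cs:
            pc = behavior.bias_corrected_percent_correct(
                info["alpha"], behavior_report["beta"], c)
            prows.append({"block_id": b, "contrast": c, "percent_correct": float(pc)})
    return contrast_tbl, pd.DataFrame(prows)


def run_pipeline(config: SessionConfig, outdir, seed: int | None = None,
                 session: Session | None = None, write_inputs: bool = False) -> dict:
    """Execute the full pipeline and persist a run report.

    Any stage failure halts with the stage name; partial outputs written so
    far are left in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.seed
    report = {
        "versions": {"optomask": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "python": platform.python_version()},
        "seed": int(seed),
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "stages": {},
    }
    stage = "simulate"
    try:
        if session is None:
            session = generate_session(config, seed=seed)
            if write_inputs:
                from .session_io import write_session
                write_session(session, outdir / "session")
        report["stages"]["simulate"] = {"n_trials": len(session.trial_table)}

        stage = "preprocess"
        pre = preprocess_session(session)
        report["stages"]["preprocess"] = {
            "n_trials": len(pre.samples),
            "n_blanks": int((pre.samples["condition_id"] == blank_condition_id()).sum()),
            "roi": {"x0": pre.roi.x0, "y0": pre.roi.y0,
                    "width_px": pre.roi.width_px, "height_px": pre.roi.height_px},
            "blank_sd": pre.blank_sd,
            "hb_warnings": list(pre.hb_model.warnings_),
        }
        pre.samples.to_csv(outdir / "samples.csv", index=False)

        stage = "analyze-neural"
        report["neural"] = analyze_neural(pre.samples, config.n_boot, seed)

        stage = "analyze-behavior"
        report["behavior"] = analyze_behavior(session.trial_table,
                                              config.n_boot, seed)

        stage = "report"
        ct, pt = _curve_tables(report["neural"], report["behavior"])
        ct.to_csv(outdir / "contrast_response_curves.csv", index=False)
        pt.to_csv(outdir / "psychometric_curves.csv", index=False)
        if session.ground_truth is not None:
            report["ground_truth_rho"] = session.ground_truth.rho_true
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return report
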