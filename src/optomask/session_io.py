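"""Readers/writers for session artifacts.

Layouts
-------
HDF5: one file ``stacks.h5`` with groups ``/trials/<id>/frames`` (float32)
and the trial-record fields as group attributes.
TIFF: one ImageJ-compatible multi-page file per trial, ``trial_<id>.tif``.
Trial table: ``trials.csv`` (UTF-8, header row, '.' decimal).
Config: ``config.yaml``; ground truth: ``ground_truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .config import SessionConfig
from .synth import GroundTruth, Session

__all__ = ["write_session", "read_session", "SchemaError",
           "REQUIRED_TRIAL_COLUMNS"]

REQUIRED_TRIAL_COLUMNS = (
    "trial_id", "block_id", "condition_id", "condition_contrast",
    "target_present", "target_contrast", "opto_power", "heart_rate",
    "choice", "outcome", "saccade_time_ms",
)


class SchemaError(ValueError):
    pass


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trials.csv missing column(s): {missing}")
    if table["heart_rate"].isna().any():
        rows = table.index[table["heart_rate"].isna()].tolist()
        raise SchemaError(f"heart_rate missing at row(s) {rows}")
    bad = table["target_present"] != (table["target_contrast"] > 0)
    if bad.any():
        raise SchemaError(
            f"target_contrast must be 0 iff target_present is false; "
            f"violated at row(s) {table.index[bad].tolist()[:10]}")
    return table


def write_session(session: Session, outdir, fmt: str = "hdf5") -> Path:
    """Write stacks + trial table + config + ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = session.trial_table
    table.to_csv(outdir / "trials.csv", index=False)
    session.config.to_file(outdir / "config.yaml")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(session.ground_truth.to_jsonable(), fh, indent=1)

    if session.stacks is not None:
        ids = table["trial_id"].to_numpy()
        if fmt == "hdf5":
            with h5py.File(outdir / "stacks.h5", "w") as f:
                g = f.create_group("trials")
                for i, tid in enumerate(ids):
                    tg = g.create_group(str(int(tid)))
                    tg.create_dataset("frames", data=session.stacks[i].astype(np.float32))
                    for col in REQUIRED_TRIAL_COLUMNS:
                        v = table.iloc[i][col]
                        if isinstance(v, float) and np.isnan(v):
                            v = "nan"
                        tg.attrs[col] = v
        elif fmt == "tiff":
            for i, tid in enumerate(ids):
                tifffile.imwrite(outdir / f"trial_{int(tid):05d}.tif",
                                 session.stacks[i].astype(np.float32),
                                 imagej=True)
        else:
            raise ValueError(f"unknown stack format {fmt!r}")
    return outdir


def read_session(path) -> Session:
    """Load a session directory (auto-detects HDF5 vs TIFF stacks)."""
    path = Path(path)
    trials_csv = path / "trials.csv"
    if not trials_csv.exists():
        raise SchemaError(f"{trials_csv} not found")
    table = _validate_table(pd.read_csv(trials_csv))
    config = SessionConfig.from_file(path / "config.yaml") \
        if (path / "config.yaml").exists() else SessionConfig()
    gt = None
    gt_path = path / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            gt = GroundTruth.from_jsonable(json.load(fh))

    timeline = config.make_timeline()
    stacks = None
    h5 = path / "stacks.h5"
    tiffs = sorted(path.glob("trial_*.tif"))
    ids = table["trial_id"].to_numpy()
    if h5.exists():
        with h5py.File(h5, "r") as f:
            stacks = np.stack([f[f"trials/{int(tid)}/frames"][...] for tid in ids])
    elif tiffs:
        by_id = {int(p.stem.split("_")[1]): p for p in tiffs}
        missing = [int(t) for t in ids if int(t) not in by_id]
        if missing:
            raise SchemaError(f"missing TIFF stack(s) for trial(s) {missing[:10]}")
        stacks = np.stack([tifffile.imread(by_id[int(tid)]) for tid in ids])
    if stacks is not None:
        if stacks.shape[1] != timeline.n_frames:
            raise SchemaError(
                f"stack has {stacks.shape[1]} frames but config timeline "
                f"expects {timeline.n_frames}")
        if stacks.shape[2:] != (config.ny, config.nx):
            raise SchemaError(
                f"stack frames are {stacks.shape[2:]} but config expects "
                f"{(config.ny, config.nx)}")
    return Session(stacks=stacks, trial_table=table, ground_truth=gt,
                   timeline=timeline, config=config)
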