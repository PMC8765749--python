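"""Heart-rate-polynomial artifact removal.

Acquisition starts on an EKG upstroke, so the heartbeat artifact stretches
or compresses in time with the per-trial heart rate; the pixel intensity at
a fixed frame index therefore varies predictably with heart rate. For each
(pixel, frame-index) the model

    I[x, y, t, k] = S[x, y, t, s(k)] + f[x, y, t](HR[k])

is solved jointly by least squares, with ``S`` the heart-rate-free response
of stimulus condition ``s`` and ``f`` a fourth-order polynomial of heart
rate with no constant term. HR is standardized before building the
polynomial columns (raw HR^4..HR columns are catastrophically collinear)
and each column is centered over trials, so the fitted artifact has zero
trial mean by construction and the condition indicators absorb the
intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HeartbeatModel", "ConditionResponse", "fit_heartbeat_model",
           "remove_heartbeat", "hr_design_columns"]

POLY_ORDER = 4


@dataclass
class HeartbeatModel:
    """Per-(pixel, frame) polynomial-of-heart-rate coefficients."""

    coeffs: np.ndarray        # (POLY_ORDER, T, ny, nx); index j = power j+1
    hr_center: float
    hr_scale: float
    col_center: np.ndarray    # (POLY_ORDER,) trial means of the raw columns
    warnings_: tuple = ()

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 4 or self.coeffs.shape[0] != POLY_ORDER:
            raise ValueError("coeffs must have shape (4, T, ny, nx)")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")
        self.col_center = np.asarray(self.col_center, dtype=float)

    def artifact(self, heart_rate: float) -> np.ndarray:
        """Fitted artifact stack (T, ny, nx) for one trial's heart rate."""
        h = (heart_rate - self.hr_center) / self.hr_scale
        cols = np.array([h ** (j + 1) for j in range(POLY_ORDER)]) - self.col_center
        return np.tensordot(cols, self.coeffs, axes=(0, 0))


@dataclass
class ConditionResponse:
    """Fitted heart-rate-free mean stack per stimulus condition."""

    means: dict               # condition_id -> (T, ny, nx)
    n_trials: dict = field(default_factory=dict)
    flagged: tuple = ()       # conditions with a single trial


def hr_design_columns(heart_rates: np.ndarray, hr_center: float,
                      hr_scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered standardized-HR polynomial columns and their raw trial means."""
    h = (np.asarray(heart_rates, dtype=float) - hr_center) / hr_scale
    raw = np.stack([h ** (j + 1) for j in range(POLY_ORDER)], axis=1)  # (K, 4)
    col_center = raw.mean(axis=0)
    return raw - col_center, col_center


def fit_heartbeat_model(stacks, trial_table, hr_var_tol: float = 1e-8):
    """Jointly fit condition means and the heart-rate polynomial.

    Parameters
    ----------
    stacks : (K, T, ny, nx) array
        One stack per trial, any intensity scale (raw or dF/F).
    trial_table : DataFrame with ``condition_id`` and ``heart_rate`` columns.

    Returns
    -------
    (HeartbeatModel, ConditionResponse)
    """
    stacks = np.asarray(stacks, dtype=float)
    if stacks.ndim != 4:
        raise ValueError("stacks must be (K, T, ny, nx)")
    K, T, ny, nx = stacks.shape
    if len(trial_table) != K:
        raise ValueError("trial table length does not match number of stacks")
    hr = trial_table["heart_rate"].to_numpy(dtype=float)
    if np.isnan(hr).any():
        bad = trial_table.loc[np.isnan(hr), "trial_id"].tolist()
        raise ValueError(f"heart_rate missing for trial(s) {bad}")
    cond = trial_table["condition_id"].to_numpy()
    cond_levels, cond_idx = np.unique(cond, return_inverse=True)
    counts = np.bincount(cond_idx)
    flagged = tuple(cond_levels[counts == 1])
    notes = []
    if flagged:
        notes.append(f"condition(s) with a single trial: {list(flagged)}")

    hr_center = float(hr.mean())
    hr_scale = float(hr.std())
    Y = stacks.reshape(K, -1)

    if hr_scale < hr_var_tol:
        warnings.warn("heart-rate variance below tolerance; heartbeat model is a no-op")
        model = HeartbeatModel(np.zeros((POLY_ORDER, T, ny, nx)), hr_center, 1.0,
                               np.zeros(POLY_ORDER),
                               warnings_=("zero heart-rate variance",))
        ind = np.zeros((K, len(cond_levels)))
        ind[np.arange(K), cond_idx] = 1.0
        beta, *_ = np.linalg.lstsq(ind, Y, rcond=None)
        means = {c: beta[i].reshape(T, ny, nx) for i, c in enumerate(cond_levels)}
        resp = ConditionResponse(means, dict(zip(cond_levels, counts.tolist())), flagged)
        return model, resp

    cols, col_center = hr_design_columns(hr, hr_center, hr_scale)
    ind = np.zeros((K, len(cond_levels)))
    ind[np.arange(K), cond_idx] = 1.0
    X = np.hstack([ind, cols])                       # (K, n_cond + 4)
    # one shared design for all (pixel, frame) targets; minimum-norm on
    # rank deficiency
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        notes.append(f"rank-deficient design (rank {rank} of {X.shape[1]}); "
                     "minimum-norm solution")
    n_cond = len(cond_levels)
    means = {c: beta[i].reshape(T, ny, nx) for i, c in enumerate(cond_levels)}
    coeffs = beta[n_cond:].reshape(POLY_ORDER, T, ny, nx)
    model = HeartbeatModel(coeffs, hr_center, hr_scale, col_center,
                           warnings_=tuple(notes))
    resp = ConditionResponse(means, dict(zip(cond_levels, counts.tolist())), flagged)
    return model, resp


def remove_heartbeat(stacks, model: HeartbeatModel, trial_table) -> np.ndarray:
    """Subtract the fitted heart-rate component from every trial.

    Because the polynomial columns are centered over the fitting trials,
    the subtracted component averages to ~0 across trials and the
    differences between fitted condition means are untouched.
    """
    stacks = np.asarray(stacks, dtype=float)
    K = stacks.shape[0]
    if len(trial_table) != K:
        raise ValueError("trial table length does not match number of stacks")
    hr = trial_table["heart_rate"].to_numpy(dtype=float)
    if np.isnan(hr).any():
        bad = trial_table.loc[np.isnan(hr), "trial_id"].tolist()
        raise ValueError(f"heart_rate missing for trial(s) {bad}")
    out = np.empty_like(stacks)
    for k in range(K):
        out[k] = stacks[k] - model.artifact(hr[k])
    return out
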