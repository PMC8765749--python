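"""Motion-regression image stabilization.

The pixel intensity across time is modelled as a motion-free component
plus a per-pixel linear term in the global frame translation:

    I[t, y, x] = I0[t, y, x] + a[y, x] . v[t]

One translation vector per frame is estimated from the central quarter of
the image by subpixel cross-correlation against the trial-median frame;
the per-pixel coefficient vectors ``a`` are then obtained by least squares
on frames where the stimulus-driven component is constant (pre-stimulus
frames of every trial plus all frames of blank trials, pooled across the
session), and the fitted motion term is subtracted everywhere.

Vectors are stored in array order ``(dy, dx)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionTrace",
    "MotionCoeffMap",
    "estimate_motion",
    "fit_motion_coefficients",
    "stabilize",
]


@dataclass
class MotionTrace:
    """Per-frame global translation ``v[t] = (dy, dx)`` in pixels."""

    v: np.ndarray                      # (T, 2)
    reference: str = "trial_median"
    degenerate: bool = False           # zero-variance crop, trace forced to 0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 2 or self.v.shape[1] != 2:
            raise ValueError("motion trace must have shape (T, 2)")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("motion trace must be finite")


@dataclass
class MotionCoeffMap:
    """Per-pixel regression coefficients of intensity on (dy, dx)."""

    a: np.ndarray                      # (2, ny, nx)
    dropped_axes: tuple = ()           # axes removed for collinearity/degeneracy
    mode: str = "session"              # "session" or "trial" fitting mode

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 3 or self.a.shape[0] != 2:
            raise ValueError("coefficient map must have shape (2, ny, nx)")
        if not np.all(np.isfinite(self.a)):
            raise ValueError("coefficient map must be finite")


def _center_crop(stack: np.ndarray) -> np.ndarray:
    """Central crop of half the width and half the height (1/4 of the area)."""
    _, ny, nx = stack.shape
    hy, hx = ny // 4, nx // 4
    return stack[:, hy:hy + ny // 2, hx:hx + nx // 2]


def _ncc_score_grid(ref: np.ndarray, img: np.ndarray, m: int) -> np.ndarray:
    """Overlap-normalized correlation of img against ref for integer shifts
    in [-m, m]^2. Score[i, j] pairs ref[y, x] with img[y+sy, x+sx]."""
    H, W = ref.shape
    scores = np.full((2 * m + 1, 2 * m + 1), -np.inf)
    for i, sy in enumerate(range(-m, m + 1)):
        for j, sx in enumerate(range(-m, m + 1)):
            a = ref[max(0, -sy):H - max(0, sy), max(0, -sx):W - max(0, sx)]
            b = img[max(0, sy):H - max(0, -sy), max(0, sx):W - max(0, -sx)]
            av = a - a.mean()
            bv = b - b.mean()
            denom = np.sqrt((av * av).sum() * (bv * bv).sum())
            if denom > 0:
                scores[i, j] = (av * bv).sum() / denom
    return scores


def _parabolic(sm1: float, s0: float, sp1: float) -> float:
    denom = sm1 - 2 * s0 + sp1
    return 0.0 if denom >= 0 else 0.5 * (sm1 - sp1) / denom


def estimate_motion(stack: np.ndarray, max_shift: int = 6) -> MotionTrace:
    """Estimate the per-frame translation of the central image quarter.

    Each frame is matched against the pixelwise median frame of the crop
    by overlap-normalized cross-correlation over integer shifts up to
    ``max_shift``, with parabolic interpolation of the correlation peak for
    subpixel resolution (plain FFT phase correlation is badly biased on
    smooth widefield images). The trace is median-centered so the
    reference frame sits at (0, 0) by construction. A constant
    (zero-variance) crop yields an all-zero trace with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (T, ny, nx) with at least 2 frames")
    crop = _center_crop(stack)
    ref = np.median(crop, axis=0)
    if np.ptp(ref) == 0 and np.allclose(crop, crop[0]):
        warnings.warn("zero-variance center crop; returning all-zero motion trace")
        return MotionTrace(np.zeros((stack.shape[0], 2)), degenerate=True)
    m = min(max_shift, min(crop.shape[1:]) // 4)
    v = np.empty((stack.shape[0], 2))
    for t in range(stack.shape[0]):
        s = _ncc_score_grid(ref, crop[t], m)
        iy, jx = np.unravel_index(np.argmax(s), s.shape)
        dy, dx = float(iy - m), float(jx - m)
        if 0 < iy < 2 * m:
            dy += _parabolic(s[iy - 1, jx], s[iy, jx], s[iy + 1, jx])
        if 0 < jx < 2 * m:
            dx += _parabolic(s[iy, jx - 1], s[iy, jx], s[iy, jx + 1])
        v[t] = (dy, dx)
    v -= np.median(v, axis=0)
    return MotionTrace(v)


def _fit_frames_mask(n_frames: int, prestim_frames: np.ndarray,
                     is_blank: bool) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    if is_blank:
        mask[:] = True
    else:
        mask[prestim_frames] = True
    return mask


def fit_motion_coefficients(stacks, traces, prestim_frames=None,
                            blank_flags=None, var_tol: float = 1e-12) -> MotionCoeffMap:
    """Least-squares per-pixel coefficients of intensity on the motion trace.

    Parameters
    ----------
    stacks, traces
        Sequences of (T, ny, nx) stacks and matching :class:`MotionTrace`
        (or (T, 2) arrays), pooled into a single regression.
    prestim_frames
        Frame indices with constant expected signal (pre-stimulus); used
        for non-blank trials. ``None`` pools every frame.
    blank_flags
        Per-trial booleans; blank trials contribute all frames.

    An intercept per pooled regression is included and discarded. A motion
    axis with variance below ``var_tol`` (or collinear with the other) is
    dropped and its coefficients set to zero.
    """
    stacks = [np.asarray(s, dtype=float) for s in stacks]
    vs = [t.v if isinstance(t, MotionTrace) else np.asarray(t, dtype=float)
          for t in traces]
    if len(stacks) != len(vs):
        raise ValueError("stacks and traces must have equal length")
    if blank_flags is None:
        blank_flags = [prestim_frames is None] * len(stacks)

    rows_v, rows_y = [], []
    for s, v, blank in zip(stacks, vs, blank_flags):
        if v.shape[0] != s.shape[0]:
            raise ValueError("trace length must equal n_frames")
        mask = (_fit_frames_mask(s.shape[0], np.asarray(prestim_frames), blank)
                if prestim_frames is not None else np.ones(s.shape[0], bool))
        rows_v.append(v[mask])
        rows_y.append(s[mask].reshape(mask.sum(), -1))
    V = np.concatenate(rows_v)            # (N, 2)
    Y = np.concatenate(rows_y)            # (N, P)
    if V.shape[0] < 3:
        raise ValueError("need at least 3 pooled frames to fit coefficients")
    ny, nx = stacks[0].shape[1:]

    keep = [i for i in range(2) if V[:, i].var() > var_tol]
    dropped = tuple(i for i in range(2) if i not in keep)
    a = np.zeros((2, ny, nx))
    if keep:
        X = np.column_stack([V[:, keep], np.ones(V.shape[0])])
        if len(keep) == 2:
            # drop one axis if the two are numerically collinear
            c = np.corrcoef(V[:, 0], V[:, 1])[0, 1]
            if abs(c) > 1 - 1e-10:
                keep = [0]
                dropped = (1,)
                X = np.column_stack([V[:, keep], np.ones(V.shape[0])])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        for j, i in enumerate(keep):
            a[i] = beta[j].reshape(ny, nx)
    else:
        warnings.warn("motion trace has no variance on either axis; zero coefficients")
    return MotionCoeffMap(a, dropped_axes=dropped)


def stabilize(stack: np.ndarray, trace, coeffs: MotionCoeffMap) -> np.ndarray:
    """Subtract the fitted motion component: ``I0 = I - a . v_t``."""
    stack = np.asarray(stack, dtype=float)
    v = trace.v if isinstance(trace, MotionTrace) else np.asarray(trace, dtype=float)
    if v.shape[0] != stack.shape[0]:
        raise ValueError("trace length must equal n_frames")
    if coeffs.a.shape[1:] != stack.shape[1:]:
        raise ValueError("coefficient map shape does not match frames")
    motion_term = np.tensordot(v, coeffs.a, axes=(1, 0))  # (T, ny, nx)
    out = stack - motion_term
    if not np.all(np.isfinite(out)):
        raise ValueError("stabilized stack is not finite")
    return out


def stabilize_session(stacks: np.ndarray, prestim_frames: np.ndarray,
                      blank_flags) -> tuple[np.ndarray, list, MotionCoeffMap]:
    """Convenience wrapper: estimate per-trial traces, fit session-pooled
    coefficients, and stabilize every stack."""
    traces = [estimate_motion(s) for s in stacks]
    coeffs = fit_motion_coefficients(stacks, traces, prestim_frames=prestim_frames,
                                     blank_flags=list(blank_flags))
    out = np.stack([stabilize(s, tr, coeffs) for s, tr in zip(stacks, traces)])
    return out, traces, coeffs
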