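"""From cleaned stacks to per-trial scalar responses and z-scores.

Stage order is fixed: stabilize -> downsample -> dF/F -> heartbeat removal
-> pre-stimulus anchoring / detrend -> windowed scalar -> z-score. The
functions here implement the dF/F and later stages; the pipeline module
enforces the ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Roi", "compute_dff", "downsample_stack", "select_roi",
           "roi_timecourses", "detrend", "summarize_response",
           "zscore_responses", "DetrendResult"]


@dataclass(frozen=True)
class Roi:
    """Rectangular analysis window, in pixels, with its physical size."""

    x0: int
    y0: int
    width_px: int
    height_px: int
    mm_per_px: float

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("ROI must be at least 1 px on each side")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")

    @property
    def size_mm(self) -> tuple[float, float]:
        return (self.width_px * self.mm_per_px, self.height_px * self.mm_per_px)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.height_px),
                slice(self.x0, self.x0 + self.width_px))


def compute_dff(stack: np.ndarray, baseline_frames) -> np.ndarray:
    """Fractional fluorescence change ``(F(t) - F0) / F0`` per pixel.

    ``F0`` is the pixelwise mean over ``baseline_frames`` (by default the
    three frames immediately preceding stimulus onset, labels F5-F7 at
    20 Hz with onset at F8).
    """
    stack = np.asarray(stack, dtype=float)
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size == 0:
        raise ValueError("baseline_frames is empty")
    f0 = stack[baseline_frames].mean(axis=0)
    n_bad = int(np.count_nonzero(f0 <= 0))
    if n_bad:
        raise ValueError(f"F0 <= 0 at {n_bad} pixel(s); cannot divide")
    return (stack - f0[None]) / f0[None]


def downsample_stack(stack: np.ndarray, factor: int) -> np.ndarray:
    """Spatially bin each frame by ``factor`` (block mean)."""
    if factor == 1:
        return stack
    T, ny, nx = stack.shape
    if ny % factor or nx % factor:
        raise ValueError("downsample factor must divide image dimensions")
    return (stack.reshape(T, ny // factor, factor, nx // factor, factor)
            .mean(axis=(2, 4)))


def select_roi(score_map: np.ndarray, roi_mm: float, mm_per_px: float) -> Roi:
    """Place the ROI maximizing the window-mean of ``score_map``.

    Exhaustive sliding-window search over every admissible origin (via an
    integral image); ties broken by the smallest (y0, x0) lexicographically.
    ``score_map`` should be the visual-only condition-mean response over
    the response window.
    """
    score_map = np.asarray(score_map, dtype=float)
    ny, nx = score_map.shape
    w = max(1, int(round(roi_mm / mm_per_px)))
    if w > ny or w > nx:
        raise ValueError(f"ROI of {w} px exceeds image dimensions {(ny, nx)}")
    ii = np.zeros((ny + 1, nx + 1))
    ii[1:, 1:] = score_map.cumsum(axis=0).cumsum(axis=1)
    sums = (ii[w:, w:] - ii[:-w, w:] - ii[w:, :-w] + ii[:-w, :-w])
    # tie-break at float tolerance: first (smallest y0, then x0) window
    # whose mean is within rounding of the maximum
    m = sums.max()
    tol = 1e-9 * max(1.0, abs(m))
    ties = np.argwhere(sums >= m - tol)
    y0, x0 = (int(v) for v in ties[0])
    return Roi(x0=x0, y0=y0, width_px=w, height_px=w, mm_per_px=mm_per_px)


def roi_timecourses(stacks: np.ndarray, roi: Roi) -> np.ndarray:
    """Mean over ROI pixels per frame: (K, T, ny, nx) -> (K, T)."""
    sy, sx = roi.slices()
    stacks = np.asarray(stacks, dtype=float)
    if roi.y0 + roi.height_px > stacks.shape[2] or roi.x0 + roi.width_px > stacks.shape[3]:
        raise ValueError("ROI extends outside image bounds")
    return stacks[:, :, sy, sx].mean(axis=(2, 3))


@dataclass
class DetrendResult:
    timecourses: np.ndarray          # (K, T) detrended
    m_s: dict                        # condition -> (intercept, slope) removed
    m_k: np.ndarray                  # (K,) per-trial slopes removed
    flagged_trials: tuple = ()       # trials with <2 valid frames (m_k = 0)


def _line_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS intercept and slope of y on t."""
    A = np.column_stack([np.ones_like(t), t])
    (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(a), float(b)


def detrend(timecourses: np.ndarray, condition_ids, prestim_frames,
            valid_masks=None, frame_times_s: np.ndarray | None = None) -> DetrendResult:
    """Remove shared (per-condition) and private (per-trial) linear trends.

    The trial time course is modelled as the condition response plus a
    linear trend shared within the condition plus an additional linear
    trend private to the trial. Steps:

    1. anchor: subtract each trial's pre-stimulus mean;
    2. per condition, fit a line to the pre-stimulus part of the condition
       mean and subtract it (extended over all frames) from each member
       trial, constraining condition means to a flat zero pre-stimulus
       baseline;
    3. per trial, fit a line to (trial - condition mean) over the valid
       frames (up to the saccade) and subtract it.

    ``valid_masks`` is (K, T) boolean; a trial with fewer than two valid
    frames keeps its private trend (slope 0) and is flagged.
    """
    R = np.asarray(timecourses, dtype=float).copy()
    K, T = R.shape
    cond = np.asarray(condition_ids)
    prestim = np.asarray(prestim_frames, dtype=int)
    if prestim.size < 2:
        raise ValueError("need at least 2 pre-stimulus frames to fit the shared trend")
    t = (np.arange(T, dtype=float) if frame_times_s is None
         else np.asarray(frame_times_s, dtype=float))
    if valid_masks is None:
        valid = np.ones((K, T), dtype=bool)
    else:
        valid = np.asarray(valid_masks, dtype=bool)

    # 1. pre-stimulus anchoring
    R -= R[:, prestim].mean(axis=1, keepdims=True)

    # 2. shared trend from pre-stimulus condition means
    m_s = {}
    for c in np.unique(cond):
        sel = cond == c
        cm = R[sel].mean(axis=0)
        a, b = _line_fit(t[prestim], cm[prestim])
        R[sel] -= (a + b * t)[None]
        m_s[c] = (a, b)

    # 3. private trends on residuals from the condition mean
    m_k = np.zeros(K)
    flagged = []
    cond_means = {c: R[cond == c].mean(axis=0) for c in np.unique(cond)}
    for k in range(K):
        vm = valid[k]
        if vm.sum() < 2:
            flagged.append(k)
            continue
        resid = R[k] - cond_means[cond[k]]
        a, b = _line_fit(t[vm], resid[vm])
        R[k] -= a + b * t
        m_k[k] = b
    return DetrendResult(R, m_s, m_k, tuple(flagged))


def summarize_response(timecourse: np.ndarray, response_frames) -> float:
    """Mean over the response-window frames (50-200 ms post-stimulus by
    default, i.e. three frames at 20 Hz)."""
    timecourse = np.asarray(timecourse, dtype=float)
    idx = np.asarray(response_frames, dtype=int)
    if idx.size == 0:
        raise ValueError("response window contains no frame")
    return float(timecourse[..., idx].mean(axis=-1)) if timecourse.ndim == 1 \
        else timecourse[:, idx].mean(axis=1)


def zscore_responses(responses: np.ndarray, blank_mask) -> tuple[np.ndarray, float, float]:
    """z-score each scalar response against the blank-trial distribution.

    ``z = (R - mean_blank) / sd_blank`` with the unbiased (n-1) SD
    estimator; blanks are the no-visual, no-optostim trials of the same
    experiment. Returns (z, mean_blank, sd_blank).
    """
    responses = np.asarray(responses, dtype=float)
    blank_mask = np.asarray(blank_mask, dtype=bool)
    n_blank = int(blank_mask.sum())
    if n_blank < 2:
        raise ValueError("need at least 2 blank trials for z-scoring")
    mu = float(responses[blank_mask].mean())
    sd = float(responses[blank_mask].std(ddof=1))
    if sd == 0:
        raise ValueError("blank-trial standard deviation is zero")
    return (responses - mu) / sd, mu, sd
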