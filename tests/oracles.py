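"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they are checking.
"""

import numpy as np


def bruteforce_shift(ref: np.ndarray, img: np.ndarray, max_shift: int = 4):
    """Exhaustive integer-shift correlation + parabolic subpixel refinement.

    Returns the estimated content displacement (dy, dx) of ``img`` relative
    to ``ref``: the shift s maximizing corr(ref[y, x], img[y+sy, x+sx]).
    """
    m = max_shift
    H, W = ref.shape
    scores = np.full((2 * m + 1, 2 * m + 1), -np.inf)
    for i, sy in enumerate(range(-m, m + 1)):
        for j, sx in enumerate(range(-m, m + 1)):
            a = ref[max(0, -sy):H - max(0, sy), max(0, -sx):W - max(0, sx)]
            b = img[max(0, sy):H - max(0, -sy), max(0, sx):W - max(0, -sx)]
            av = a - a.mean()
            bv = b - b.mean()
            denom = np.sqrt((av ** 2).sum() * (bv ** 2).sum())
            scores[i, j] = (av * bv).sum() / denom if denom > 0 else -np.inf
    iy, jx = np.unravel_index(np.argmax(scores), scores.shape)

    def parab(s_m1, s_0, s_p1):
        denom = s_m1 - 2 * s_0 + s_p1
        return 0.0 if denom >= 0 or denom == 0 else 0.5 * (s_m1 - s_p1) / denom

    dy = iy - m
    dx = jx - m
    if 0 < iy < 2 * m:
        dy = dy + parab(scores[iy - 1, jx], scores[iy, jx], scores[iy + 1, jx])
    if 0 < jx < 2 * m:
        dx = dx + parab(scores[iy, jx - 1], scores[iy, jx], scores[iy, jx + 1])
    return np.array([dy, dx])


def bruteforce_rho(z_vis, z_optosub, weights=None, lo=-1.0, hi=2.0, step=1e-5):
    """Grid minimization of sum w (z_optosub - (1-rho) z_vis)^2 over rho."""
    zv = np.asarray(z_vis, dtype=float)
    zo = np.asarray(z_optosub, dtype=float)
    w = np.ones_like(zv) if weights is None else np.asarray(weights, dtype=float)
    rhos = np.arange(lo, hi + step, step)
    costs = ((w * (zo[None, :] - (1 - rhos[:, None]) * zv[None, :]) ** 2)
             .sum(axis=1))
    return float(rhos[np.argmin(costs)])


def bruteforce_roi(score_map: np.ndarray, w: int):
    """Exhaustive loop over every window origin; first max in (y0, x0) order."""
    ny, nx = score_map.shape
    best = (-np.inf, None)
    for y0 in range(ny - w + 1):
        for x0 in range(nx - w + 1):
            s = score_map[y0:y0 + w, x0:x0 + w].sum()
            if s > best[0] + 1e-12 * max(1.0, abs(s)):
                best = (s, (y0, x0))
    return best[1]


def fwl_heartbeat_fit(stacks, cond_idx, hr_cols):
    """Frisch-Waugh-Lovell two-step oracle for the joint heartbeat fit.

    Residualize both the data and the HR polynomial columns on the
    condition indicators (i.e. remove within-condition means), then
    regress. Returns the polynomial coefficients, shape (4, ...).
    """
    K = stacks.shape[0]
    Y = stacks.reshape(K, -1).astype(float)
    X = np.asarray(hr_cols, dtype=float).copy()
    for c in np.unique(cond_idx):
        sel = cond_idx == c
        Y[sel] -= Y[sel].mean(axis=0)
        X[sel] -= X[sel].mean(axis=0)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return beta.reshape((X.shape[1],) + stacks.shape[1:])


def slope_oracle(t, y):
    """Closed-form simple-regression slope."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tc = t - t.mean()
    return float((tc * (y - y.mean())).sum() / (tc ** 2).sum())
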