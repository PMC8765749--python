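"""Contrast-response fitting and the proportional-reduction statistic.

``rho`` quantifies how much of the visual-evoked z-scored response
survives simultaneous optostim: ``Z_optosub(c) ~= (1 - rho) * Z_vis(c)``
in the weighted least-squares sense across target contrasts, where
``Z_optosub`` is the simultaneous response minus the mean optostim-only
baseline. Uncertainty comes from resampling trials with replacement
within each stimulus condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synth import naka_rushton

__all__ = ["NakaRushtonFit", "ReductionResult", "fit_naka_rushton",
           "subtract_optostim_baseline", "compute_reduction",
           "bootstrap_neural", "NeuralBootstrap"]


@dataclass
class NakaRushtonFit:
    z_max: float
    n: float
    c50: float
    rss: float
    weights: np.ndarray
    contrasts: np.ndarray
    flat: bool = False     # all responses <= 0; degenerate flat fit

    def __call__(self, c):
        return naka_rushton(c, self.z_max, self.n, self.c50)


@dataclass
class ReductionResult:
    rho: float
    z_vis: np.ndarray
    z_optosub: np.ndarray
    contrasts: np.ndarray
    weights: np.ndarray
    z_optobase_mean: float
    z_optobase_sd: float
    out_of_range: bool = False    # rho outside [0, 1] (reported unclipped)
    bootstrap_sd: float | None = None
    p_value: float | None = None


def fit_naka_rushton(contrasts, z_means, weights=None,
                     n_bounds=(0.3, 8.0), c50_bounds=(1e-3, 3.0),
                     n_starts: int = 6) -> NakaRushtonFit:
    """Weighted least-squares Naka-Rushton fit with multi-start.

    Starts are laid on a log grid of c50 crossed with a small set of
    exponents; for each (n, c50) start the amplitude initializes at the
    weighted projection. Deterministic: the start grid is fixed.
    """
    c = np.asarray(contrasts, dtype=float)
    y = np.asarray(z_means, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 contrast levels")
    if np.all(y <= 0):
        warnings.warn("all responses <= 0; returning flat Naka-Rushton fit")
        return NakaRushtonFit(0.0, 1.0, float(np.sqrt(c50_bounds[0] * c50_bounds[1])),
                              float(np.sum(w * y**2)), w, c, flat=True)
    sw = np.sqrt(w)

    def resid(theta):
        z_max, ln_n, ln_c50 = theta
        return sw * (naka_rushton(c, z_max, np.exp(ln_n), np.exp(ln_c50)) - y)

    pos = c[c > 0]
    c50_grid = np.geomspace(max(pos.min(), c50_bounds[0] * 1.01),
                            min(pos.max() * 2, c50_bounds[1] * 0.99),
                            max(2, n_starts // 3))
    best = None
    for n0 in (1.0, 2.0, 4.0):
        for c50_0 in c50_grid:
            g = naka_rushton(c, 1.0, n0, c50_0)
            denom = np.sum(w * g * g)
            z0 = float(np.sum(w * g * y) / denom) if denom > 0 else y.max()
            z0 = max(z0, 1e-6)
            try:
                sol = least_squares(
                    resid, x0=[z0, np.log(n0), np.log(c50_0)],
                    bounds=([0.0, np.log(n_bounds[0]), np.log(c50_bounds[0])],
                            [np.inf, np.log(n_bounds[1]), np.log(c50_bounds[1])]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError("Naka-Rushton fit failed from every start")
    rss, (z_max, ln_n, ln_c50) = best
    return NakaRushtonFit(float(z_max), float(np.exp(ln_n)), float(np.exp(ln_c50)),
                          rss, w, c)


def subtract_optostim_baseline(z_optovis_by_contrast: dict,
                               z_optobase_trials) -> tuple[dict, float, float]:
    """Visual contribution under optostim: mean simultaneous response minus
    the mean optostim-only baseline.

    Returns ({contrast: Z_optosub}, baseline mean, baseline SD).
    """
    base = np.asarray(z_optobase_trials, dtype=float)
    if base.size == 0:
        raise ValueError("no optostim-only baseline trials")
    mu = float(base.mean())
    sd = float(base.std(ddof=1)) if base.size > 1 else 0.0
    out = {float(c): float(np.mean(z)) - mu for c, z in z_optovis_by_contrast.items()}
    return out, mu, sd


def compute_reduction(z_vis_means, z_optosub_means, weights=None) -> float:
    """Closed-form weighted least-squares proportional reduction.

    Minimizes ``sum_c w_c (Z_optosub,c - (1 - rho) Z_vis,c)^2``, giving
    ``rho = 1 - sum(w Z_vis Z_optosub) / sum(w Z_vis^2)``. Reported
    unclipped; values outside [0, 1] are flagged by the caller.
    """
    zv = np.asarray(z_vis_means, dtype=float)
    zo = np.asarray(z_optosub_means, dtype=float)
    w = np.ones_like(zv) if weights is None else np.asarray(weights, dtype=float)
    denom = float(np.sum(w * zv * zv))
    if denom == 0:
        raise ValueError("sum of weighted squared visual responses is zero; "
                         "rho undefined")
    return 1.0 - float(np.sum(w * zv * zo)) / denom


def _condition_tables(samples: pd.DataFrame):
    """Split a z-sample table into per-power views and the visual block."""
    vis = samples[(samples["opto_power"] == 0) & (samples["target_contrast"] > 0)]
    powers = sorted(p for p in samples["opto_power"].unique() if p > 0)
    return vis, powers


def reduction_from_samples(samples: pd.DataFrame, power: float,
                           weight_by_trials: bool = True) -> ReductionResult:
    """Point estimate of rho for one optostim power from a z-sample table.

    ``samples`` needs columns target_contrast, opto_power, z. Contrast
    levels are matched between the visual-only and optostim blocks
    (primary path); weights default to per-contrast trial counts.
    """
    vis, _ = _condition_tables(samples)
    opto = samples[samples["opto_power"] == power]
    base_trials = opto.loc[opto["target_contrast"] == 0, "z"].to_numpy()
    if base_trials.size == 0:
        raise ValueError(f"no optostim-only baseline trials at power {power:g}")
    vis_means = vis.groupby("target_contrast")["z"].agg(["mean", "count"])
    opto_vis = opto[opto["target_contrast"] > 0]
    common = sorted(set(vis_means.index) & set(opto_vis["target_contrast"].unique()))
    if not common:
        raise ValueError("no matched contrast levels between blocks")
    z_optovis = {c: opto_vis.loc[opto_vis["target_contrast"] == c, "z"].to_numpy()
                 for c in common}
    z_optosub, mu_b, sd_b = subtract_optostim_baseline(z_optovis, base_trials)
    zv = vis_means.loc[common, "mean"].to_numpy()
    zo = np.array([z_optosub[c] for c in common])
    if weight_by_trials:
        n_vis = vis_means.loc[common, "count"].to_numpy()
        n_opt = np.array([len(z_optovis[c]) for c in common])
        w = 2.0 / (1.0 / n_vis + 1.0 / n_opt)   # harmonic-mean trial count
    else:
        w = np.ones(len(common))
    rho = compute_reduction(zv, zo, w)
    return ReductionResult(rho=rho, z_vis=zv, z_optosub=zo,
                           contrasts=np.asarray(common, dtype=float), weights=w,
                           z_optobase_mean=mu_b, z_optobase_sd=sd_b,
                           out_of_range=not (0.0 <= rho <= 1.0))


@dataclass
class NeuralBootstrap:
    results: dict                  # power -> ReductionResult (with sd, p filled)
    n_boot: int
    seed: int
    replicates: dict = field(default_factory=dict)   # power -> (n_boot,) rho


def bootstrap_neural(samples: pd.DataFrame, n_boot: int = 1000,
                     seed: int = 0, weight_by_trials: bool = True) -> NeuralBootstrap:
    """Bootstrap rho per optostim power.

    Trials are resampled with replacement within each stimulus condition
    (target contrast x optostim level); the SD over replicates is the
    reported error bar and the p-value is the proportion of replicates
    agreeing with the null rho <= 0 (no reduction, one-sided), Bonferroni-
    adjusted across power levels.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    _, powers = _condition_tables(samples)
    groups = {cid: df.index.to_numpy() for cid, df in samples.groupby("condition_id")}
    results, reps = {}, {}
    for power in powers:
        point = reduction_from_samples(samples, power, weight_by_trials)
        rhos = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate([rng.choice(ix, size=ix.size, replace=True)
                                  for ix in groups.values()])
            rhos[b] = reduction_from_samples(samples.loc[idx], power,
                                             weight_by_trials).rho
        point.bootstrap_sd = float(rhos.std(ddof=1))
        p_raw = float(np.mean(rhos <= 0.0))
        point.p_value = min(1.0, p_raw * len(powers))
        results[power] = point
        reps[power] = rhos
    return NeuralBootstrap(results, n_boot, seed, reps)
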