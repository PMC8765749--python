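"""Signal-detection psychometric analysis of the detection task.

Discriminability grows with target contrast as ``d'(c) = (c/alpha)^beta``;
the observer places a criterion ``delta`` (in d' units, positive = bias
toward reporting target absent), giving

    P(hit) = Phi(d'(c)/2 - delta),   P(cr) = Phi(d'(c)/2 + delta).

Observed proportions are rescaled to [0.005, 0.995] before fitting so the
likelihood stays defined at 0/1 proportions; visual-only and optostim
blocks are fitted jointly with block-specific thresholds and biases but a
shared steepness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

__all__ = ["PerformanceTable", "PsychFit", "BehaviorSummary",
           "rescale_proportion", "tabulate_performance",
           "psychometric_probability", "fit_psychometric_joint",
           "bias_corrected_percent_correct", "normalized_threshold",
           "bootstrap_behavior"]

RESCALE_OFFSET = 0.005
RESCALE_SLOPE = 0.99


def rescale_proportion(p, offset: float = RESCALE_OFFSET,
                       slope: float = RESCALE_SLOPE):
    """Affine shrink of proportions into [offset, offset + slope]."""
    return offset + slope * np.asarray(p, dtype=float)


def psychometric_probability(c, alpha: float, beta: float, delta: float):
    """Model (P_hit, P_cr) at contrast ``c``."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("contrast must be non-negative")
    d = (c / alpha) ** beta
    return ndtr(0.5 * d - delta), ndtr(0.5 * d + delta)


def bias_corrected_percent_correct(alpha: float, beta: float, c):
    """Percent correct with the criterion set to zero: 100*Phi((c/alpha)^beta / 2)."""
    p_hit, _ = psychometric_probability(c, alpha, beta, 0.0)
    return 100.0 * p_hit


@dataclass
class PerformanceTable:
    """Per-(block, contrast) counts and (rescaled) proportions."""

    table: pd.DataFrame   # block_id, contrast, n_present, n_hits, n_absent,
                          # n_cr, p_hit, p_cr, p_hit_hat, p_cr_hat

    def blocks(self) -> list:
        return list(dict.fromkeys(self.table["block_id"]))


def tabulate_performance(trial_table: pd.DataFrame,
                         offset: float = RESCALE_OFFSET,
                         slope: float = RESCALE_SLOPE) -> PerformanceTable:
    """Count hits and correct rejections per (block, contrast) cell.

    Target-absent trials carry the block's target contrast
    (``condition_contrast``) so the d' model knows what the target would
    have been.
    """
    rows = []
    for (block, c), cell in trial_table.groupby(["block_id", "condition_contrast"]):
        present = cell["target_present"].to_numpy(bool)
        n_present = int(present.sum())
        n_absent = int((~present).sum())
        if n_absent == 0:
            raise ValueError(f"block {block!r} contrast {c:g} has no target-absent "
                             "trials; criterion is unidentifiable")
        n_hits = int((cell["outcome"] == "hit").sum())
        n_cr = int((cell["outcome"] == "correct_rejection").sum())
        p_hit = n_hits / n_present if n_present else np.nan
        p_cr = n_cr / n_absent
        rows.append({"block_id": block, "contrast": float(c),
                     "n_present": n_present, "n_hits": n_hits,
                     "n_absent": n_absent, "n_cr": n_cr,
                     "p_hit": p_hit, "p_cr": p_cr,
                     "p_hit_hat": rescale_proportion(p_hit, offset, slope),
                     "p_cr_hat": rescale_proportion(p_cr, offset, slope)})
    return PerformanceTable(pd.DataFrame(rows))


@dataclass
class PsychFit:
    """Joint fit: per-block threshold/bias with a shared steepness."""

    alpha: dict               # block -> threshold contrast at d' = 1
    delta: dict               # block -> criterion (d' units)
    beta: float               # shared steepness
    nll: float
    converged: bool
    n_starts_tried: int = 0

    def params_for(self, block) -> tuple[float, float, float]:
        return self.alpha[block], self.beta, self.delta[block]


def _joint_nll(theta: np.ndarray, blocks: list, perf: pd.DataFrame) -> float:
    nb = len(blocks)
    log_beta = theta[0]
    beta = np.exp(log_beta)
    nll = 0.0
    for i, block in enumerate(blocks):
        alpha = np.exp(theta[1 + i])
        delta = theta[1 + nb + i]
        sub = perf[perf["block_id"] == block]
        c = sub["contrast"].to_numpy()
        with np.errstate(over="ignore"):  # huge d' saturates Phi; harmless
            d = (c / alpha) ** beta
        for p_obs, n, sign in ((sub["p_hit_hat"].to_numpy(), sub["n_present"].to_numpy(), -1.0),
                               (sub["p_cr_hat"].to_numpy(), sub["n_absent"].to_numpy(), +1.0)):
            p = np.clip(ndtr(0.5 * d + sign * delta), 1e-12, 1 - 1e-12)
            ok = n > 0
            nll -= np.sum(n[ok] * (p_obs[ok] * np.log(p[ok])
                                   + (1 - p_obs[ok]) * np.log(1 - p[ok])))
    return float(nll)


def fit_psychometric_joint(perf: PerformanceTable, n_starts: int = 8,
                           tol: float = 1e-9) -> PsychFit:
    """Maximize the rescaled-proportion binomial cross-entropy jointly.

    Parameters are optimized as (log beta, log alpha per block, delta per
    block) so positivity is structural; a fixed grid of starts makes the
    result deterministic. Works for a single block as well.
    """
    table = perf.table if isinstance(perf, PerformanceTable) else perf
    blocks = list(dict.fromkeys(table["block_id"]))
    for block in blocks:
        sub = table[table["block_id"] == block]
        if (sub["n_present"] > 0).sum() < 2:
            raise ValueError(f"block {block!r} needs >= 2 contrasts with present trials")
    c_all = table.loc[table["contrast"] > 0, "contrast"].to_numpy()
    alpha_grid = np.quantile(c_all, [0.25, 0.75])
    beta_grid = (1.0, 2.5)
    starts = []
    for b0 in beta_grid:
        for a0 in alpha_grid:
            for d0 in (0.0, 0.5):
                starts.append(np.concatenate([[np.log(b0)],
                                              np.full(len(blocks), np.log(a0)),
                                              np.full(len(blocks), d0)]))
    starts = starts[:max(n_starts, 1)]

    best = None
    n_tried = 0
    for x0 in starts:
        n_tried += 1
        res = minimize(_joint_nll, x0, args=(blocks, table), method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": tol, "gtol": 1e-10})
        if best is None or (res.fun < best.fun - 1e-12):
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"joint psychometric fit failed after {n_tried} starts")
    nb = len(blocks)
    beta = float(np.exp(best.x[0]))
    alpha = {b: float(np.exp(best.x[1 + i])) for i, b in enumerate(blocks)}
    delta = {b: float(best.x[1 + nb + i]) for i, b in enumerate(blocks)}
    return PsychFit(alpha=alpha, delta=delta, beta=beta, nll=float(best.fun),
                    converged=bool(best.success), n_starts_tried=n_tried)


def normalized_threshold(fit: PsychFit, opto_block, vis_block="vis") -> float:
    """Threshold ratio rho_behavior = alpha_optovis / alpha_vis."""
    a_vis = fit.alpha[vis_block]
    if a_vis <= 0:
        raise ValueError("visual-only threshold must be positive")
    return fit.alpha[opto_block] / a_vis


@dataclass
class BehaviorSummary:
    fit: PsychFit
    rho_behavior: dict          # opto block -> threshold ratio
    rho_behavior_sd: dict       # SD of replicate ratios (normalized by mean
                                # visual threshold over replicates)
    rho_p: dict                 # Bonferroni-adjusted, null: no increase
    criterion: dict             # block -> delta
    criterion_sd: dict
    criterion_p: dict           # opto blocks vs visual, null: no change
    alpha_sd: dict
    n_boot: int = 0
    seed: int = 0
    replicates: dict = field(default_factory=dict)


def _resample_counts(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Resample trials with replacement within (block x contrast x presence).

    Stratified resampling of Bernoulli outcomes is equivalent to drawing
    binomial counts at the observed proportions.
    """
    out = table.copy()
    n_hits = rng.binomial(out["n_present"].to_numpy(),
                          out["p_hit"].fillna(0.0).to_numpy())
    n_cr = rng.binomial(out["n_absent"].to_numpy(), out["p_cr"].to_numpy())
    out["n_hits"], out["n_cr"] = n_hits, n_cr
    with np.errstate(invalid="ignore"):
        out["p_hit"] = n_hits / out["n_present"].to_numpy()
    out["p_cr"] = n_cr / out["n_absent"].to_numpy()
    out["p_hit_hat"] = rescale_proportion(out["p_hit"])
    out["p_cr_hat"] = rescale_proportion(out["p_cr"])
    return out


def bootstrap_behavior(trial_table: pd.DataFrame, n_boot: int = 1000,
                       seed: int = 0, vis_block: str = "vis",
                       n_starts_point: int = 8) -> BehaviorSummary:
    """Refit the joint model to stratified resamples of the decisions.

    Error bars are replicate SDs; threshold SDs and ratios are normalized
    by the mean visual-only threshold across replicates. p-values are the
    proportion of replicates agreeing with the null (threshold ratio <= 1;
    criterion change sign opposite to the observed), Bonferroni-adjusted
    across optostim power levels.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    perf = tabulate_performance(trial_table)
    fit = fit_psychometric_joint(perf, n_starts=n_starts_point)
    blocks = perf.blocks()
    opto_blocks = [b for b in blocks if b != vis_block]

    alphas = {b: np.empty(n_boot) for b in blocks}
    deltas = {b: np.empty(n_boot) for b in blocks}
    warm = np.concatenate([[np.log(fit.beta)],
                           np.log([fit.alpha[b] for b in blocks]),
                           [fit.delta[b] for b in blocks]])
    for i in range(n_boot):
        rep = _resample_counts(perf.table, rng)
        res = minimize(_joint_nll, warm, args=(blocks, rep), method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-9, "gtol": 1e-10})
        nb = len(blocks)
        for j, b in enumerate(blocks):
            alphas[b][i] = np.exp(res.x[1 + j])
            deltas[b][i] = res.x[1 + nb + j]

    mean_vis = float(alphas[vis_block].mean())
    n_tests = max(1, len(opto_blocks))
    rho, rho_sd, rho_p = {}, {}, {}
    crit_sd, crit_p = {b: float(deltas[b].std(ddof=1)) for b in blocks}, {}
    for b in opto_blocks:
        ratios = alphas[b] / mean_vis
        rho[b] = normalized_threshold(fit, b, vis_block)
        rho_sd[b] = float(ratios.std(ddof=1))
        rho_p[b] = min(1.0, float(np.mean(alphas[b] <= alphas[vis_block])) * n_tests)
        ddiff = deltas[b] - deltas[vis_block]
        obs = fit.delta[b] - fit.delta[vis_block]
        agree = np.mean(ddiff <= 0.0) if obs > 0 else np.mean(ddiff >= 0.0)
        crit_p[b] = min(1.0, float(agree) * n_tests)
    return BehaviorSummary(
        fit=fit, rho_behavior=rho, rho_behavior_sd=rho_sd, rho_p=rho_p,
        criterion={b: fit.delta[b] for b in blocks}, criterion_sd=crit_sd,
        criterion_p=crit_p,
        alpha_sd={b: float(alphas[b].std(ddof=1)) for b in blocks},
        n_boot=n_boot, seed=seed,
        replicates={"alpha": alphas, "delta": deltas})
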