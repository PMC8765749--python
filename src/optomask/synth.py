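"""Synthetic-session generator.

Produces trial-organized image stacks, a behavioral trial table and a
ground-truth sidecar with the statistical structure the analysis pipeline
assumes: two Gaussian expression sites, Naka-Rushton visual responses,
optostim responses at one site only, a configurable sublinear interaction
(the visual-evoked component is scaled by ``1 - rho_true`` whenever
optostim is on), a heart-rate-dependent periodic artifact, global
translational micro-motion, linear drift, sensor noise, and choices drawn
from the d-prime psychometric model.

Every stochastic element derives from one root seed: trial ``k`` is
rendered from ``SeedSequence(seed, spawn_key=(k,))`` and session-level
draws (heart rates, choices, drift slopes, artifact map) use
``spawn_key=(SESSION_KEY,)``, so single trials can be re-rendered in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .config import SessionConfig
from .timeline import Timeline

__all__ = [
    "PsychParams",
    "GroundTruth",
    "Session",
    "naka_rushton",
    "trial_rng",
    "simulate_choices",
    "render_trial_stack",
    "generate_session",
    "blank_condition_id",
    "condition_id",
]

SESSION_KEY = 0xFFFFFFFF  # reserved spawn key for session-level randomness

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def trial_rng(seed: int, key: int) -> np.random.Generator:
    """Child generator for trial ``key`` under the stated counter scheme."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def naka_rushton(c, z_max: float, n: float, c50: float):
    """Saturating contrast-response function ``z_max * c^n / (c^n + c50^n)``."""
    c = np.asarray(c, dtype=float)
    cn = np.power(c, n)
    return z_max * cn / (cn + c50**n)


@dataclass(frozen=True)
class PsychParams:
    """d-prime psychometric parameters for one block."""

    alpha: float
    beta: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def condition_id(target_contrast: float, opto_power: float) -> str:
    """Physical stimulus-condition label (contrast x optostim power)."""
    return f"c{target_contrast:g}_p{opto_power:g}"


def blank_condition_id() -> str:
    return condition_id(0.0, 0.0)


@dataclass
class GroundTruth:
    """Generator parameters; the reference against which recovery is tested."""

    # behavior, per block label
    psych_params: dict = field(default_factory=dict)

    # neural response (dF/F amplitude at the C1V1 site)
    nr_amp_max: float = 0.06
    nr_n: float = 2.0
    nr_c50: float = 0.15
    crosstalk_site2: float = 0.25    # visual gain at the GCaMP-only site
    opto_amplitude: dict = field(default_factory=lambda: {0.6: 0.04})
    rho_true: float = 0.5

    # artifacts
    heartbeat_amplitude: float = 0.0   # intensity units, scales the map
    heartbeat_poly: tuple = (1.0, 0.3, 0.1, 0.05)  # coeffs of hr_z^1..hr_z^4
    heartbeat_freq_hz: float = 2.5
    heartbeat_phase_mode: str = "locked"  # "locked" | "beat_phase" (model mismatch)
    hr_mean: float = 180.0
    hr_sd: float = 12.0
    motion_sd_px: float = 0.0   # random-walk step SD
    drift_ms_sd: float = 0.0    # per-condition slope SD, dF/F per second
    drift_mk_sd: float = 0.0    # per-trial slope SD, dF/F per second
    noise_sd: float = 0.0       # additive sensor noise, intensity units

    # geometry of the forward model
    baseline_level: float = 100.0
    site_centers_px: tuple = ((32.0, 20.0), (32.0, 44.0))  # (y, x) pairs
    site_fwhm_px: float = 16.0
    response_rise_ms: float = 60.0
    response_decay_ms: float = 150.0

    # filled in by generate_session
    heartbeat_map: np.ndarray | None = None
    drift_m_s: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_true <= 1.0:
            raise ValueError("rho_true must lie in [0, 1]")
        for v in (self.nr_amp_max, self.hr_mean, self.hr_sd):
            if not np.isfinite(v):
                raise ValueError("ground-truth amplitudes must be finite")
        if self.heartbeat_phase_mode not in ("locked", "beat_phase"):
            raise ValueError("heartbeat_phase_mode must be 'locked' or 'beat_phase'")

    # -- forward-model pieces ----------------------------------------------

    def site_maps(self, ny: int, nx: int) -> tuple[np.ndarray, np.ndarray]:
        """Unit-peak Gaussian expression maps for the two sites."""
        yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
        sig = self.site_fwhm_px * FWHM_TO_SIGMA
        maps = []
        for cy, cx in self.site_centers_px:
            maps.append(np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)))
        return maps[0], maps[1]

    def baseline_map(self, ny: int, nx: int) -> np.ndarray:
        g1, g2 = self.site_maps(ny, nx)
        return self.baseline_level * (1.0 + 0.5 * (g1 + g2))

    def visual_amplitude(self, contrast: float) -> float:
        return float(naka_rushton(contrast, self.nr_amp_max, self.nr_n, self.nr_c50))

    def response_profile(self, timeline: Timeline) -> np.ndarray:
        """Temporal envelope shared by visual- and optostim-evoked responses.

        Responses begin at optostim onset (the visual response carries a
        latency equal to the configured optostim delay, which is the point
        of the delayed optostim design) and decay after target offset.
        """
        t = timeline.frame_times_ms + 0.5 * timeline.frame_period_ms  # midpoints
        t_on = timeline.optostim_onset_abs_ms
        t_off = timeline.target_onset_abs_ms + timeline.target_max_duration_ms
        prof = np.clip((t - t_on) / self.response_rise_ms, 0.0, 1.0)
        tail = t > t_off
        prof[tail] = prof[tail] * np.exp(-(t[tail] - t_off) / self.response_decay_ms)
        return prof

    def heartbeat_waveform(self, timeline: Timeline) -> np.ndarray:
        t_s = timeline.frame_times_ms / 1000.0
        return np.cos(2 * np.pi * self.heartbeat_freq_hz * t_s)

    def heartbeat_scale(self, heart_rate: float) -> float:
        """Polynomial-in-standardized-HR amplitude (no constant term)."""
        h = (heart_rate - self.hr_mean) / self.hr_sd
        return float(sum(c * h ** (i + 1) for i, c in enumerate(self.heartbeat_poly)))

    def make_heartbeat_map(self, ny: int, nx: int, rng: np.random.Generator) -> np.ndarray:
        """Smooth random spatial map, unit peak magnitude."""
        raw = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma=6.0)
        peak = np.abs(raw).max()
        return raw / peak if peak > 0 else raw

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["opto_amplitude"] = {f"{k:g}": v for k, v in self.opto_amplitude.items()}
        d["psych_params"] = {k: asdict(v) if isinstance(v, PsychParams) else v
                             for k, v in self.psych_params.items()}
        if self.heartbeat_map is not None:
            d["heartbeat_map"] = np.asarray(self.heartbeat_map).tolist()
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["opto_amplitude"] = {float(k): v for k, v in d.get("opto_amplitude", {}).items()}
        d["psych_params"] = {k: PsychParams(**v) for k, v in d.get("psych_params", {}).items()}
        if d.get("heartbeat_map") is not None:
            d["heartbeat_map"] = np.asarray(d["heartbeat_map"], dtype=float)
        for k in ("heartbeat_poly", "site_centers_px"):
            if k in d:
                d[k] = tuple(tuple(x) if isinstance(x, list) else x for x in d[k]) \
                    if k == "site_centers_px" else tuple(d[k])
        return cls(**d)


def default_ground_truth(config: SessionConfig) -> GroundTruth:
    """Ground truth with per-block psychometric parameters and per-power
    optostim amplitudes filled in, then overridden by ``config.ground_truth``."""
    overrides = dict(config.ground_truth)
    psych = overrides.pop("psych_params", None)
    opto_amp = overrides.pop("opto_amplitude", None)
    gt = GroundTruth(**overrides)
    if opto_amp is None:
        opto_amp = {p: 0.04 for p in config.opto_powers}
    gt.opto_amplitude = {float(k): float(v) for k, v in opto_amp.items()}
    if psych is None:
        alpha_vis = 0.1
        psych = {"vis": PsychParams(alpha=alpha_vis, beta=1.5, delta=0.1)}
        for p in config.opto_powers:
            psych[f"opto{p:g}"] = PsychParams(alpha=1.35 * alpha_vis, beta=1.5, delta=0.3)
    else:
        psych = {k: v if isinstance(v, PsychParams) else PsychParams(**v)
                 for k, v in psych.items()}
    gt.psych_params = psych
    return gt


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_choices(trial_table: pd.DataFrame, psych_params: dict,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Draw choices/outcomes from the d-prime model.

    Target-present trials saccade with probability
    ``Phi(0.5*(c/alpha)^beta - delta)``; target-absent trials stay with
    probability ``Phi(0.5*(c_block/alpha)^beta + delta)`` where ``c_block``
    is the block's target contrast (the blocked design makes the absent-
    trial discriminability depend on what the target would have been).
    """
    out = trial_table.copy()
    n = len(out)
    missing = ~out["block_id"].isin(psych_params.keys())
    if missing.any():
        raise ValueError(f"no psychometric parameters for block(s) "
                         f"{sorted(out.loc[missing, 'block_id'].unique())}")
    p_correct = np.empty(n)
    for block, pp in psych_params.items():
        if not isinstance(pp, PsychParams):
            pp = PsychParams(**pp)
        m = (out["block_id"] == block).to_numpy()
        if not m.any():
            continue
        present = out.loc[m, "target_present"].to_numpy(bool)
        c = out.loc[m, "target_contrast"].to_numpy(float)
        c_block = out.loc[m, "condition_contrast"].to_numpy(float)
        dprime_p = (c / pp.alpha) ** pp.beta
        dprime_a = (c_block / pp.alpha) ** pp.beta
        p = np.where(present,
                     ndtr(0.5 * dprime_p - pp.delta),
                     ndtr(0.5 * dprime_a + pp.delta))
        p_correct[m] = p
    correct = rng.random(n) < p_correct
    present = out["target_present"].to_numpy(bool)
    saccade = np.where(present, correct, ~correct)
    out["choice"] = np.where(saccade, "saccade", "stay")
    out["outcome"] = np.select(
        [present & saccade, present & ~saccade, ~present & saccade],
        ["hit", "miss", "false_alarm"], default="correct_rejection")
    return out


# ---------------------------------------------------------------------------
# imaging forward model
# ---------------------------------------------------------------------------

def render_trial_stack(gt: GroundTruth, trial, timeline: Timeline,
                       rng: np.random.Generator, ny: int = 64, nx: int = 64,
                       drift_slope: float = 0.0, keep_clean: bool = False):
    """Render one trial's image stack ``[t, y, x]`` plus a ground-truth sidecar.

    stack = shift(baseline * (1 + response_dff + drift_dff), v_t)
            + heartbeat + noise
    """
    if ny < 1 or nx < 1:
        raise ValueError("image dimensions must be positive")
    T = timeline.n_frames
    g1, g2 = gt.site_maps(ny, nx)
    base = gt.baseline_map(ny, nx)

    contrast = float(trial["target_contrast"])
    power = float(trial["opto_power"])
    vis = gt.visual_amplitude(contrast) if contrast > 0 else 0.0
    opto = gt.opto_amplitude.get(power, 0.0) if power > 0 else 0.0
    amp1 = vis * (1.0 - gt.rho_true if power > 0 else 1.0) + opto
    amp2 = gt.crosstalk_site2 * vis

    prof = gt.response_profile(timeline)
    t_s = (timeline.frame_times_ms - timeline.cue_time_ms) / 1000.0
    drift = drift_slope * t_s

    dff = prof[:, None, None] * (amp1 * g1 + amp2 * g2) + drift[:, None, None]
    clean = base[None] * (1.0 + dff)

    # micro-motion: median-centered random walk, whole-frame spline shift
    if gt.motion_sd_px > 0:
        v = np.cumsum(rng.normal(0.0, gt.motion_sd_px, size=(T, 2)), axis=0)
        v -= np.median(v, axis=0)
        moved = np.stack([ndimage.shift(clean[t], v[t], order=3, mode="nearest")
                          for t in range(T)])
    else:
        v = np.zeros((T, 2))
        moved = clean.copy()

    hr = float(trial["heart_rate"])
    if gt.heartbeat_amplitude != 0.0 and gt.heartbeat_map is not None:
        if gt.heartbeat_phase_mode == "locked":
            w = gt.heartbeat_waveform(timeline)
            hb_scale = gt.heartbeat_scale(hr)
            hb = (gt.heartbeat_amplitude * hb_scale) * w[:, None, None] * gt.heartbeat_map[None]
        else:  # beat_phase: sinusoid in cardiac phase, a model-mismatch mode
            phase = 2 * np.pi * (hr / 60.0) * (timeline.frame_times_ms / 1000.0)
            hb_scale = 1.0
            hb = gt.heartbeat_amplitude * np.sin(phase)[:, None, None] * gt.heartbeat_map[None]
        moved = moved + hb
    else:
        hb_scale = 0.0

    if gt.noise_sd > 0:
        moved = moved + rng.normal(0.0, gt.noise_sd, size=moved.shape)

    sidecar = {
        "motion": v,
        "resp_amp_site1": amp1,
        "resp_amp_site2": amp2,
        "profile": prof,
        "drift_slope": drift_slope,
        "drift_dff": drift,
        "hb_scale": hb_scale,
    }
    if keep_clean:
        sidecar["clean"] = clean
    return moved, sidecar


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

@dataclass
class Session:
    stacks: np.ndarray            # (K, T, ny, nx) float32
    trial_table: pd.DataFrame
    ground_truth: GroundTruth
    timeline: Timeline
    config: SessionConfig
    sidecars: list = field(default_factory=list)


def _build_trial_table(config: SessionConfig, rng: np.random.Generator):
    rows = []
    blocks = [("vis", 0.0)] + [(f"opto{p:g}", p) for p in config.opto_powers]
    tid = 0
    for block, power in blocks:
        for c in config.contrasts:
            for _ in range(config.trials_per_cell):
                present = bool(rng.random() < config.target_present_fraction)
                tc = c if present else 0.0
                rows.append({
                    "trial_id": tid,
                    "block_id": block,
                    "condition_contrast": c,
                    "target_present": present,
                    "target_contrast": tc,
                    "opto_power": power,
                    "condition_id": condition_id(tc, power),
                })
                tid += 1
    table = pd.DataFrame(rows)
    hr = rng.normal(0.0, 1.0, size=len(table))
    return table, hr


def generate_session(config: SessionConfig, seed: int | None = None,
                     render: bool = True, keep_clean: bool = False) -> Session:
    """Generate a full synthetic session.

    Blocks are emitted separately (visual-only, then one block per optostim
    power); each cell is 50% target-present by default, so the visual-only
    absent trials double as the blank (no visual, no optostim) reference
    needed for z-scoring. With ``render=False`` only the trial table and
    ground truth are produced (cheap, for behavior-only studies).
    """
    if seed is None:
        seed = config.seed
    timeline = config.make_timeline()
    gt = default_ground_truth(config)
    srng = trial_rng(seed, SESSION_KEY)

    table, hr_z = _build_trial_table(config, srng)
    table["heart_rate"] = np.maximum(gt.hr_mean + gt.hr_sd * hr_z, 1.0)
    if not (table["condition_id"] == blank_condition_id()).any():
        raise ValueError("configuration produced no blank trials; "
                         "z-scoring requires blanks (target_present_fraction too high?)")

    table = simulate_choices(table, gt.psych_params, srng)
    sacc = table["choice"] == "saccade"
    rt = srng.uniform(*config.rt_range_ms, size=len(table))
    table["saccade_time_ms"] = np.where(sacc, rt, np.nan)

    # drift slopes: shared per condition + private per trial
    gt.drift_m_s = {cid: (srng.normal(0.0, gt.drift_ms_sd) if gt.drift_ms_sd > 0 else 0.0)
                    for cid in sorted(table["condition_id"].unique())}
    m_k = (srng.normal(0.0, gt.drift_mk_sd, size=len(table))
           if gt.drift_mk_sd > 0 else np.zeros(len(table)))

    if gt.heartbeat_amplitude != 0.0:
        gt.heartbeat_map = gt.make_heartbeat_map(config.ny, config.nx, srng)

    stacks = None
    sidecars = []
    if render:
        stacks = np.empty((len(table), timeline.n_frames, config.ny, config.nx),
                          dtype=np.float32)
        for i, (_, trial) in enumerate(table.iterrows()):
            rng_k = trial_rng(seed, int(trial["trial_id"]))
            slope = gt.drift_m_s[trial["condition_id"]] + m_k[i]
            stack, sc = render_trial_stack(gt, trial, timeline, rng_k,
                                           ny=config.ny, nx=config.nx,
                                           drift_slope=slope, keep_clean=keep_clean)
            stacks[i] = stack
            sidecars.append(sc)
    return Session(stacks=stacks, trial_table=table, ground_truth=gt,
                   timeline=timeline, config=config, sidecars=sidecars)
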