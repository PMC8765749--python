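"""Trial timeline and visual-stimulus definitions.

All event times are in milliseconds. ``cue_time_ms`` is measured from
acquisition start (frame 0); every other event time is relative to the cue.
Frames are indexed 0-based internally; user-facing labels such as "F5"
are 1-based, so internal index ``i`` corresponds to label ``F{i+1}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["TimelineError", "Timeline", "StimulusSpec", "build_timeline"]


class TimelineError(ValueError):
    """Raised when timeline fields are inconsistent; message names the field."""


@dataclass(frozen=True)
class Timeline:
    """Acquisition and stimulus-event schedule for one trial.

    Defaults describe a 20 Hz, 24-frame (1.2 s) acquisition with the
    target appearing 250 ms after the cue and pulsed optogenetic
    stimulation starting 40 ms later.
    """

    frame_rate_hz: float = 20.0
    n_frames: int = 24
    cue_time_ms: float = 100.0
    target_onset_ms: float = 250.0
    optostim_onset_ms: float = 290.0
    target_max_duration_ms: float = 250.0
    optostim_max_duration_ms: float = 210.0
    pulse_width_ms: float = 5.0
    pulse_period_ms: float = 22.5

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise TimelineError("frame_rate_hz must be positive")
        if self.n_frames < 1:
            raise TimelineError("n_frames must be >= 1")
        if self.target_max_duration_ms <= 0:
            raise TimelineError(
                "target_max_duration_ms: target ends before it starts"
            )
        if self.optostim_max_duration_ms <= 0:
            raise TimelineError(
                "optostim_max_duration_ms: optostim ends before it starts"
            )
        if self.pulse_width_ms <= 0:
            raise TimelineError("pulse_width_ms must be positive")
        if self.pulse_width_ms > self.pulse_period_ms:
            raise TimelineError(
                "pulse_width_ms exceeds pulse_period_ms"
            )
        total_ms = self.n_frames * self.frame_period_ms
        opto_end = self.cue_time_ms + self.optostim_onset_ms + self.optostim_max_duration_ms
        if total_ms + 1e-9 < opto_end:
            raise TimelineError(
                "n_frames: acquisition ends before optostim_max_duration_ms elapses"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def duty_cycle(self) -> float:
        """Fraction of time the optostim light is on during the pulse train."""
        return self.pulse_width_ms / self.pulse_period_ms

    @property
    def pulse_rate_hz(self) -> float:
        return 1000.0 / self.pulse_period_ms

    @property
    def optostim_delay_ms(self) -> float:
        """Optostim onset relative to visual-target onset."""
        return self.optostim_onset_ms - self.target_onset_ms

    @property
    def frame_times_ms(self) -> np.ndarray:
        """Start time of each frame on the acquisition clock."""
        return np.arange(self.n_frames) * self.frame_period_ms

    @property
    def target_onset_abs_ms(self) -> float:
        """Target onset on the acquisition clock."""
        return self.cue_time_ms + self.target_onset_ms

    @property
    def optostim_onset_abs_ms(self) -> float:
        return self.cue_time_ms + self.optostim_onset_ms

    def pulse_onsets_ms(self) -> np.ndarray:
        """Onset times of optostim pulses relative to optostim onset."""
        n = math.ceil(self.optostim_max_duration_ms / self.pulse_period_ms - 1e-12)
        return np.arange(n) * self.pulse_period_ms

    def baseline_frames(self, n: int = 3) -> np.ndarray:
        """Indices of the ``n`` frames immediately preceding target onset.

        With the defaults these are indices 4-6, i.e. 1-based labels F5-F7,
        covering 0-150 ms before stimulus onset.
        """
        onset_frame = int(round(self.target_onset_abs_ms / self.frame_period_ms))
        if onset_frame - n < 0:
            raise TimelineError("cue_time_ms: not enough pre-stimulus frames for baseline")
        return np.arange(onset_frame - n, onset_frame)

    def prestim_frames(self) -> np.ndarray:
        """All frames strictly before target onset."""
        onset_frame = int(round(self.target_onset_abs_ms / self.frame_period_ms))
        return np.arange(onset_frame)

    def response_frames(self, window_ms: tuple[float, float] = (50.0, 200.0)) -> np.ndarray:
        """Frames whose start times lie in [onset+lo, onset+hi) post-stimulus."""
        lo, hi = window_ms
        if hi <= lo:
            raise TimelineError("response window: upper bound must exceed lower bound")
        if lo < 0:
            raise TimelineError("response window starts before stimulus onset")
        t = self.frame_times_ms - self.target_onset_abs_ms
        idx = np.flatnonzero((t >= lo - 1e-9) & (t < hi - 1e-9))
        if idx.size == 0:
            raise TimelineError("response window: no whole frame inside window")
        return idx

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StimulusSpec:
    """Visual target definition in Weber-contrast terms.

    ``weber_contrast`` is ``(L_max - L_background) / L_background``. If both
    luminances are supplied the stated contrast must match to 1e-12.
    """

    weber_contrast: float
    background_luminance: float | None = None
    target_peak_luminance: float | None = None
    target_fwhm_deg: float = 0.33
    site_centers_px: tuple[tuple[float, float], tuple[float, float]] = ((20.0, 32.0), (44.0, 32.0))
    site_fwhm_px: float = 12.0

    def __post_init__(self) -> None:
        if self.weber_contrast < 0:
            raise ValueError("weber_contrast must be >= 0")
        if self.target_fwhm_deg <= 0 or self.site_fwhm_px <= 0:
            raise ValueError("fwhm must be positive")
        if self.background_luminance is not None and self.target_peak_luminance is not None:
            if self.background_luminance <= 0:
                raise ValueError("background_luminance must be positive")
            c = (self.target_peak_luminance - self.background_luminance) / self.background_luminance
            if abs(c - self.weber_contrast) > 1e-12:
                raise ValueError(
                    f"weber_contrast {self.weber_contrast} inconsistent with "
                    f"luminances (implied {c})"
                )

    @staticmethod
    def from_luminance(l_max: float, l_background: float, **kw) -> "StimulusSpec":
        c = (l_max - l_background) / l_background
        return StimulusSpec(
            weber_contrast=c,
            background_luminance=l_background,
            target_peak_luminance=l_max,
            **kw,
        )


def build_timeline(config: dict | None = None, **kwargs) -> Timeline:
    """Construct a validated :class:`Timeline` from a config mapping.

    Unknown keys raise ``TimelineError``. Defaults reproduce the reference
    acquisition (20 Hz, target 250 ms and optostim 290 ms post-cue, 210 ms
    optostim train of 5 ms pulses every 22.5 ms).
    """
    params = dict(config or {})
    params.update(kwargs)
    valid = set(Timeline.__dataclass_fields__)
    unknown = set(params) - valid
    if unknown:
        raise TimelineError(f"unknown timeline field(s): {sorted(unknown)}")
    return Timeline(**params)
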