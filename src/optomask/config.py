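"""Session configuration schema.

A :class:`SessionConfig` collects the geometry, timeline, block design and
analysis constants for one simulated or recorded session. Defaults
reproduce the reference protocol: 20 Hz acquisition, three baseline frames
immediately before target onset (labels F5-F7), a 50-200 ms response
window, a 1 x 1 mm ROI, proportion rescaling to [0.005, 0.995] and 1000
bootstrap resamples.

Conventions (stated once, used everywhere): pixels are (x right, y down),
arrays are indexed [t, y, x], 0-based; times are in ms from the cue unless
a name says otherwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .timeline import Timeline, build_timeline

__all__ = ["SessionConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class SessionConfig:
    # geometry
    nx: int = 64
    ny: int = 64
    mm_per_px: float = 0.125  # 8 mm field over 64 px
    downsample: int = 1       # spatial binning factor applied before dF/F

    # timeline overrides (keys of Timeline)
    timeline: dict = field(default_factory=dict)

    # block design
    contrasts: tuple = (0.05, 0.1, 0.2, 0.4)
    opto_powers: tuple = (0.6,)
    trials_per_cell: int = 50
    target_present_fraction: float = 0.5
    rt_range_ms: tuple = (250.0, 500.0)

    # analysis constants
    roi_mm: float = 1.0
    n_baseline_frames: int = 3
    response_window_ms: tuple = (50.0, 200.0)
    rescale_offset: float = 0.005
    rescale_slope: float = 0.99
    n_boot: int = 1000
    seed: int = 0

    # generator overrides (keys of synth.GroundTruth)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ConfigError("image dimensions must be positive")
        if self.mm_per_px <= 0:
            raise ConfigError("mm_per_px must be positive")
        if self.downsample < 1 or self.nx % self.downsample or self.ny % self.downsample:
            raise ConfigError("downsample must divide both image dimensions")
        if not 0.0 < self.target_present_fraction < 1.0:
            raise ConfigError("target_present_fraction must be in (0, 1)")
        if self.trials_per_cell < 1:
            raise ConfigError("trials_per_cell must be >= 1")
        if len(self.contrasts) == 0:
            raise ConfigError("at least one contrast level required")
        if any(c <= 0 for c in self.contrasts):
            raise ConfigError("contrast levels must be positive (blanks are implicit)")
        tl = self.make_timeline()
        total_ms = tl.n_frames * tl.frame_period_ms
        lo, hi = self.response_window_ms
        if tl.target_onset_abs_ms + hi > total_ms + 1e-9:
            raise ConfigError("response_window_ms extends past the last frame")
        tl.baseline_frames(self.n_baseline_frames)  # raises if infeasible
        self.contrasts = tuple(float(c) for c in self.contrasts)
        self.opto_powers = tuple(float(p) for p in self.opto_powers)

    def make_timeline(self) -> Timeline:
        return build_timeline(self.timeline)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("contrasts", "opto_powers", "response_window_ms", "rt_range_ms"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for k in ("contrasts", "opto_powers", "response_window_ms", "rt_range_ms"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SessionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON form, for run-report traceability."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
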