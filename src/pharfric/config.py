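"""Central defaults for every stage of the pipeline, loadable from YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULT_FS = 44100
DEFAULT_N_FRAMES = 10


@dataclass
class PharfricConfig:
    """All tunable defaults in one place.

    The shipped values reproduce the reference pipeline: 1024-point FFT,
    689/344 Hz spectrum segmentation with a Hamming window, order-10
    Butterworth band split, 10 analysis frames, 43 one-third-octave bands
    and a 30-tree bagged ensemble evaluated with 10x10-fold CV.
    """

    fft_size: int = 1024
    seg_win_hz: float = 689.0
    seg_hop_hz: float = 344.0
    segment_window: str = "hamming"  # hamming | rect
    alpha: float = 0.01
    significance_method: str = "welch"  # welch | mannwhitney
    her_side: str = "low"  # low | high
    butter_order: int = 10
    n_frames: int = DEFAULT_N_FRAMES
    n_octave_bands: int = 43
    octave_scale: str = "db"  # db | linear
    peak_mode: str = "global_max"  # global_max | max_prominence
    floor_db: float = -120.0
    n_trees: int = 30
    cv_folds: int = 10
    cv_repeats: int = 10

    def __post_init__(self) -> None:
        if self.segment_window not in ("hamming", "rect"):
            raise ConfigError(f"segment_window: {self.segment_window!r}")
        if self.her_side not in ("low", "high"):
            raise ConfigError(f"her_side: {self.her_side!r}")
        if self.significance_method not in ("welch", "mannwhitney"):
            raise ConfigError(f"significance_method: {self.significance_method!r}")
        if self.octave_scale not in ("db", "linear"):
            raise ConfigError(f"octave_scale: {self.octave_scale!r}")
        if self.peak_mode not in ("global_max", "max_prominence"):
            raise ConfigError(f"peak_mode: {self.peak_mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PharfricConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
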