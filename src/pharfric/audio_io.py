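"""WAV token I/O, dataset manifests, and shared non-overlapping framing."""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .config import DEFAULT_FS, DEFAULT_N_FRAMES
from .errors import (
    EmptyInputError,
    FormatError,
    InvalidFramingError,
    SchemaError,
)

log = logging.getLogger(__name__)

CONSONANTS = ("c", "ch", "q", "s", "sh", "x")
LABELS = ("PF", "NS")

_PCM_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
    np.dtype(np.uint8): 2.0**7,  # offset binary
}


@dataclass
class SpeechToken:
    """One pre-segmented initial consonant.

    ``samples`` are dimensionless amplitudes in [-1, 1]; no further
    normalization is applied because both downstream features (per-frame
    correlation and regression-normalized octave peak) are gain-invariant.
    """

    samples: np.ndarray
    fs: int = DEFAULT_FS
    consonant: str = "s"
    label: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2 * DEFAULT_N_FRAMES:
            raise EmptyInputError(
                f"token has {self.samples.size} samples; "
                f"need at least {2 * DEFAULT_N_FRAMES}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.consonant not in CONSONANTS:
            raise ValueError(f"unknown consonant code {self.consonant!r}")
        if self.label not in LABELS + ("unknown",):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class ManifestRecord:
    path: str
    consonant: str
    label: str


@dataclass
class Manifest:
    records: list[ManifestRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)


def read_wav(
    path: str | Path,
    consonant: str = "s",
    label: str = "unknown",
    target_fs: int = DEFAULT_FS,
) -> SpeechToken:
    """Read a PCM WAV file into a :class:`SpeechToken`.

    Multichannel audio is averaged to mono, integer PCM is scaled to
    [-1, 1], and any sampling rate other than ``target_fs`` is resampled
    (with a logged warning, since the band geometry assumes 44.1 kHz).
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise FormatError(f"cannot read {path} as PCM WAV: {exc}") from exc
    if data.size == 0:
        raise EmptyInputError(f"{path} holds zero-length audio")

    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        x = data.astype(np.float64)
        if data.dtype == np.dtype(np.uint8):
            x -= 128.0
        x /= scale
    else:  # float WAV already in [-1, 1]
        x = data.astype(np.float64)

    if x.ndim == 2:
        x = x.mean(axis=1)

    if fs != target_fs:
        log.warning(
            "%s sampled at %d Hz; resampling to %d Hz (band geometry assumes "
            "a 22050 Hz Nyquist)", path, fs, target_fs
        )
        g = math.gcd(int(fs), target_fs)
        x = resample_poly(x, target_fs // g, int(fs) // g)
        fs = target_fs

    return SpeechToken(x, int(fs), consonant=consonant, label=label,
                       source_id=str(path))


def write_wav(token: SpeechToken, path: str | Path) -> None:
    """Write a token as 16-bit PCM WAV."""
    scaled = np.round(np.clip(token.samples, -1.0, 1.0) * 32768.0)
    wavfile.write(str(path), token.fs,
                  np.clip(scaled, -32768, 32767).astype(np.int16))


def frame_signal(x: np.ndarray, n_frames: int) -> np.ndarray:
    """Split ``x`` into ``n_frames`` contiguous non-overlapping frames.

    Every frame has length ``floor(len(x) / n_frames)``; trailing remainder
    samples are discarded so frames stay equal-length and pairable.
    Returns an array of shape ``(n_frames, frame_len)``.
    """
    x = np.asarray(x)
    if n_frames < 1:
        raise InvalidFramingError(f"n_frames must be >= 1, got {n_frames}")
    if n_frames > x.size:
        raise InvalidFramingError(
            f"cannot cut {x.size} samples into {n_frames} frames"
        )
    flen = x.size // n_frames
    return x[: flen * n_frames].reshape(n_frames, flen)


def load_manifest(path: str | Path) -> Manifest:
    """Read a ``path,consonant,label`` CSV manifest."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = {"path", "consonant", "label"} - set(cols)
        if missing:
            raise SchemaError(f"manifest {path} missing columns {sorted(missing)}")
        records = []
        seen: set[str] = set()
        for row in reader:
            if row["consonant"] not in CONSONANTS:
                raise SchemaError(f"unknown consonant code {row['consonant']!r}")
            if row["label"] not in LABELS:
                raise SchemaError(f"unknown label {row['label']!r}")
            if row["path"] in seen:
                raise SchemaError(f"duplicate path {row['path']!r}")
            seen.add(row["path"])
            records.append(ManifestRecord(row["path"], row["consonant"], row["label"]))
    return Manifest(records=records, provenance=str(path))


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "consonant", "label"])
        for rec in manifest.records:
            writer.writerow([rec.path, rec.consonant, rec.label])
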