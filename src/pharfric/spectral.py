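"""Magnitude spectrum, segmented variance envelope, and regression slopes.

The variance envelope summarizes amplitude fluctuation across overlapping
Hamming-weighted windows of the spectrum; the slope matrix holds, for every
starting segment c, the least-squares slope of the envelope tail from c to
the end.  Both feed the adaptive high/low-energy cut-off search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_io import SpeechToken
from .errors import ConfigError, InsufficientDataError


@dataclass
class Spectrum:
    """Single magnitude spectrum over bins 0 .. fs/2 (exclusive)."""

    amplitudes: np.ndarray  # (fft_size // 2,) non-negative magnitudes
    freqs: np.ndarray  # bin center frequencies, Hz
    fft_size: int

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class SpectrumSegments:
    """Sliding windows over spectrum bins, already window-weighted."""

    segments: np.ndarray  # (N, win_bins)
    seg_freqs: np.ndarray  # (N,) mean bin frequency per segment, Hz
    win_bins: int
    hop_bins: int
    window: str = "hamming"

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


@dataclass
class VarianceEnvelope:
    M: np.ndarray  # (N,) per-segment population variances

    @property
    def n_segments(self) -> int:
        return self.M.size


@dataclass
class SlopeMatrix:
    R: np.ndarray  # (N - 1,) tail-fit slopes, R[c-1] fits segments c..N


def _chunked_magnitude(x: np.ndarray, fft_size: int) -> np.ndarray:
    """Magnitude spectrum of ``x``: average of whole ``fft_size`` chunks,
    or a single zero-padded FFT when ``x`` is shorter than ``fft_size``."""
    x = np.asarray(x, dtype=np.float64)
    n_chunks = x.size // fft_size
    if n_chunks == 0:
        return np.abs(np.fft.rfft(x, fft_size))[: fft_size // 2]
    chunks = x[: n_chunks * fft_size].reshape(n_chunks, fft_size)
    return np.abs(np.fft.rfft(chunks, axis=1))[:, : fft_size // 2].mean(axis=0)


def magnitude_spectrum(token: SpeechToken, fft_size: int = 1024) -> Spectrum:
    """Whole-token magnitude spectrum.

    Tokens longer than ``fft_size`` are cut into ``fft_size`` chunks whose
    magnitude spectra are averaged; shorter tokens are zero-padded.  This
    yields one deterministic spectrum per token regardless of its length.
    """
    if fft_size < 2 or fft_size & (fft_size - 1):
        raise ConfigError(f"fft_size must be a power of two, got {fft_size}")
    amps = _chunked_magnitude(token.samples, fft_size)
    freqs = np.arange(fft_size // 2) * (token.fs / fft_size)
    return Spectrum(amplitudes=amps, freqs=freqs, fft_size=fft_size)


def segment_spectrum(
    spec: Spectrum,
    win_hz: float = 689.0,
    hop_hz: float = 344.0,
    window: str = "hamming",
) -> SpectrumSegments:
    """Cut the spectrum into overlapping window-weighted segments.

    The nominal Hz sizes are converted to whole bins by rounding; at
    fs = 44100 / fft 1024 the defaults give exactly 16- and 8-bin windows.
    """
    if not win_hz > hop_hz > 0:
        raise ConfigError(f"need win_hz > hop_hz > 0, got {win_hz}, {hop_hz}")
    if window not in ("hamming", "rect"):
        raise ConfigError(f"unknown segment window {window!r}")
    bw = spec.bin_width
    win_bins = round(win_hz / bw)
    hop_bins = round(hop_hz / bw)
    n_bins = spec.amplitudes.size
    if win_bins > n_bins:
        raise ConfigError(
            f"window of {win_bins} bins exceeds the {n_bins}-bin spectrum"
        )
    w = np.hamming(win_bins) if window == "hamming" else np.ones(win_bins)
    n_seg = (n_bins - win_bins) // hop_bins + 1
    starts = np.arange(n_seg) * hop_bins
    idx = starts[:, None] + np.arange(win_bins)[None, :]
    return SpectrumSegments(
        segments=spec.amplitudes[idx] * w,
        seg_freqs=spec.freqs[idx].mean(axis=1),
        win_bins=win_bins,
        hop_bins=hop_bins,
        window=window,
    )


def variance_envelope(segs: SpectrumSegments) -> VarianceEnvelope:
    """Population variance of each (window-weighted) segment."""
    if segs.n_segments == 0:
        raise InsufficientDataError("no spectrum segments")
    return VarianceEnvelope(M=segs.segments.var(axis=1))


def slope_matrix(env: VarianceEnvelope) -> SlopeMatrix:
    """Least-squares slope of {(v, M_v) : v = c..N} for every c = 1..N-1.

    Computed in closed form from suffix sums, so it is O(N) and independent
    of any generic regression routine.
    """
    M = env.M
    N = M.size
    if N < 2:
        raise InsufficientDataError(f"need >= 2 envelope points, got {N}")
    v = np.arange(1, N + 1, dtype=np.float64)
    # suffix sums over v = c..N for every c
    n = N - v + 1
    s_v = np.cumsum(v[::-1])[::-1]
    s_m = np.cumsum(M[::-1])[::-1]
    s_vv = np.cumsum((v * v)[::-1])[::-1]
    s_vm = np.cumsum((v * M)[::-1])[::-1]
    denom = n * s_vv - s_v**2
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = (n * s_vm - s_v * s_m) / denom
    return SlopeMatrix(R=slopes[: N - 1])


def envelope_frame(
    segs: SpectrumSegments, env: VarianceEnvelope, slopes: SlopeMatrix
) -> pd.DataFrame:
    """Tabulate (seg_freq, M, R) for plotting or CSV export."""
    R = np.append(slopes.R, np.nan)
    return pd.DataFrame(
        {"seg_freq_hz": segs.seg_freqs, "variance": env.M, "tail_slope": R}
    )
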