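"""One-third-octave prominent-peak excess over a regression baseline (OSPP).

Per frame: magnitude spectrum -> 43-band one-third-octave spectral lines in
dB -> least-squares line over band index -> excess of the most prominent
line over the fitted baseline.  The baseline absorbs both overall gain and
any linear-in-index spectral tilt, leaving a pure peak-prominence measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .audio_io import SpeechToken, frame_signal
from .errors import DegenerateSpectrumError
from .spectral import _chunked_magnitude


@dataclass
class OctaveBandSet:
    """43 contiguous one-third-octave bands, top-anchored at fs/2.

    ``f1``/``fc``/``f2`` keep the exact geometric relations
    f2/f1 = 2^(1/3), fc = sqrt(f1*f2).  For bin assignment the lowest
    band's reach is extended down to 0 Hz so the bands jointly cover
    [0, fs/2]; the stored f1 of band 1 stays geometric.
    """

    f1: np.ndarray
    fc: np.ndarray
    f2: np.ndarray
    fs: int

    @property
    def n_bands(self) -> int:
        return self.f1.size

    @property
    def edges(self) -> np.ndarray:
        """Bin-assignment edges: [0, f2_1, ..., f2_43]."""
        return np.concatenate(([0.0], self.f2))


@dataclass
class OctaveSpectrum:
    E: np.ndarray  # (43,) spectral lines, dB (or linear, per config)
    floor: float  # value assigned to empty/zero bands

    @property
    def band_index(self) -> np.ndarray:
        return np.arange(1, self.E.size + 1)


@dataclass
class RegressionLine:
    slope: float
    intercept: float

    def value(self, band_index) -> np.ndarray:
        return self.slope * np.asarray(band_index, dtype=np.float64) + self.intercept


@dataclass
class OsppVector:
    DF: np.ndarray  # (n_frames,) differential values, dB
    n_frames: int


def octave_bands(fs: int = 44100, n_bands: int = 43) -> OctaveBandSet:
    """Construct the band set, anchored so the top band ends at fs/2."""
    k = np.arange(n_bands, dtype=np.float64)
    f2 = (fs / 2) * 2.0 ** ((k - (n_bands - 1)) / 3.0)
    f1 = f2 / 2.0 ** (1.0 / 3.0)
    fc = f1 * 2.0 ** (1.0 / 6.0)
    return OctaveBandSet(f1=f1, fc=fc, f2=f2, fs=fs)


def octave_spectrum(
    frame: np.ndarray,
    fs: int,
    bands: OctaveBandSet,
    fft_size: int = 1024,
    floor_db: float = -120.0,
    scale: str = "db",
) -> OctaveSpectrum:
    """Mean band magnitude per one-third-octave band, in dB.

    E_i = 20*log10(mean magnitude of bins whose center lies in the band);
    bands holding no bins (the many narrow bottom bands at this FFT
    resolution) or zero magnitude are clamped to ``floor_db``.  The DC bin
    is excluded from band assignment.
    """
    amps = _chunked_magnitude(np.asarray(frame, dtype=np.float64), fft_size)
    freqs = np.arange(amps.size) * (fs / fft_size)
    which = np.digitize(freqs[1:], bands.edges) - 1  # skip DC bin
    vals = amps[1:]
    nb = bands.n_bands
    sums = np.bincount(which, weights=vals, minlength=nb + 1)[:nb]
    counts = np.bincount(which, minlength=nb + 1)[:nb]
    mean = np.divide(sums, counts, out=np.zeros(nb), where=counts > 0)
    floor = floor_db if scale == "db" else 10.0 ** (floor_db / 20.0)
    E = np.full(nb, float(floor))
    ok = mean > 0
    if scale == "db":
        E[ok] = 20.0 * np.log10(mean[ok])
    else:
        E[ok] = mean[ok]
    return OctaveSpectrum(E=E, floor=float(floor))


def octave_regression(os: OctaveSpectrum) -> RegressionLine:
    """OLS of E_i on band index i (1..43), floor-clamped bands excluded."""
    use = os.E > os.floor
    if use.sum() < 2:
        raise DegenerateSpectrumError("fewer than 2 usable octave bands")
    i = os.band_index[use].astype(np.float64)
    e = os.E[use]
    n = i.size
    denom = n * np.sum(i * i) - np.sum(i) ** 2
    slope = (n * np.sum(i * e) - np.sum(i) * np.sum(e)) / denom
    intercept = (np.sum(e) - slope * np.sum(i)) / n
    return RegressionLine(slope=float(slope), intercept=float(intercept))


def _peak_band(E: np.ndarray, mode: str) -> int:
    if mode == "max_prominence":
        peaks, props = _signal.find_peaks(E, prominence=0)
        if peaks.size:
            return int(peaks[np.argmax(props["prominences"])])
    return int(np.argmax(E))


def ospp_frame(
    os: OctaveSpectrum, line: RegressionLine, peak_mode: str = "global_max"
) -> float:
    """Excess of the most prominent spectral line over the fitted baseline."""
    b = _peak_band(os.E, peak_mode)
    return float(os.E[b] - line.value(b + 1))


def ospp_feature(
    token: SpeechToken,
    n_frames: int = 10,
    fft_size: int = 1024,
    n_bands: int = 43,
    floor_db: float = -120.0,
    scale: str = "db",
    peak_mode: str = "global_max",
) -> OsppVector:
    """Per-frame prominent-peak excess for one token."""
    bands = octave_bands(fs=token.fs, n_bands=n_bands)
    frames = frame_signal(token.samples, n_frames)
    dfs = np.empty(n_frames)
    for k, fr in enumerate(frames):
        os = octave_spectrum(fr, token.fs, bands, fft_size=fft_size,
                             floor_db=floor_db, scale=scale)
        line = octave_regression(os)
        dfs[k] = ospp_frame(os, line, peak_mode=peak_mode)
    return OsppVector(DF=dfs, n_frames=n_frames)
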