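"""The matching filter: adaptive HER/LER cut-off, Butterworth split, DSCS.

The cut-off search walks the slope matrix back to front.  At each candidate
segment c it tests whether the variance envelope ahead of c significantly
exceeds the tail behind it, whether the candidate segment itself stands out
from that tail, and whether the tail-fit slope magnitude grows across c.
The first (highest-frequency) candidate passing all three gates becomes the
cut-off; its mean segment frequency is c_f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal, stats

from .audio_io import SpeechToken
from .errors import InsufficientDataError, InvalidCutoffError
from .spectral import (
    SlopeMatrix,
    SpectrumSegments,
    VarianceEnvelope,
    magnitude_spectrum,
    segment_spectrum,
    slope_matrix,
    variance_envelope,
)

log = logging.getLogger(__name__)

#: the candidate segment must exceed the tail mean by this many tail SDs
_BOUNDARY_SD = 3.0


@dataclass
class CutoffResult:
    c_f: float  # cut-off frequency, Hz
    segment_index: int  # 1-based segment c at which the search fired
    fallback_used: bool

    def to_dict(self) -> dict:
        return {
            "c_f": self.c_f,
            "segment_index": self.segment_index,
            "fallback_used": self.fallback_used,
        }


@dataclass
class BandSplit:
    """Time-domain high/low-energy band signals, optionally DSCS-translated."""

    X_H: np.ndarray
    X_L: np.ndarray
    c_f: float
    NX_H: Optional[np.ndarray] = None
    NX_L: Optional[np.ndarray] = None
    Trans_H: Optional[float] = None
    Trans_L: Optional[float] = None


def significance_flag(
    a,
    b,
    alpha: float = 0.01,
    method: str = "welch",
    alternative: str = "two-sided",
) -> int:
    """H = 1 iff the two samples differ significantly at level ``alpha``.

    Welch's unequal-variance t-test by default; Mann-Whitney U as the
    distribution-free alternative.  Degenerate inputs (zero variance in
    both groups, identical values) yield H = 0, never an error.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    else:
        raise ValueError(f"unknown significance method {method!r}")
    p = res.pvalue
    return int(np.isfinite(p) and p < alpha)


def detect_cutoff(
    segs: SpectrumSegments,
    env: VarianceEnvelope,
    slopes: SlopeMatrix,
    alpha: float = 0.01,
    method: str = "welch",
) -> CutoffResult:
    """Locate the HER/LER boundary by a back-to-front scan of segments.

    Scanning c = N-2 .. 4 (1-based), segment c is declared the boundary when

    * the variances of segments {max(1, c-3) .. c-1} significantly exceed
      those of segments {c+1 .. N} (one-sided test at ``alpha``),
    * M_c itself stands out from the tail (> tail mean + 3 tail SD), and
    * |R_{c-1}| > |R_{c+1}|.

    c_f is the mean bin frequency of segment c.  If no segment qualifies,
    the segment maximizing |R_{c-1} - R_{c+1}| is used and
    ``fallback_used`` is set.
    """
    M = env.M
    R = slopes.R
    N = M.size
    if N < 8:
        raise InsufficientDataError(f"need >= 8 segments, got {N}")
    for c in range(N - 2, 3, -1):  # 1-based c
        i = c - 1
        front = M[max(0, i - 3): i]
        back = M[i + 1:]
        if significance_flag(front, back, alpha=alpha, method=method,
                             alternative="greater") != 1:
            continue
        tail_sd = back.std(ddof=1)
        if M[i] <= back.mean() + _BOUNDARY_SD * tail_sd:
            continue
        if not abs(R[i - 1]) > abs(R[i + 1]):
            continue
        return CutoffResult(c_f=float(segs.seg_freqs[i]), segment_index=c,
                            fallback_used=False)
    cand = np.arange(4, N - 1)  # 1-based candidates with valid R neighbours
    jumps = np.abs(R[cand - 2] - R[cand])
    c = int(cand[np.argmax(jumps)])
    log.warning("no significant HER/LER boundary; falling back to the "
                "maximal slope-change segment c=%d", c)
    return CutoffResult(c_f=float(segs.seg_freqs[c - 1]), segment_index=c,
                        fallback_used=True)


def matching_filter(
    token: SpeechToken,
    fft_size: int = 1024,
    win_hz: float = 689.0,
    hop_hz: float = 344.0,
    window: str = "hamming",
    alpha: float = 0.01,
    method: str = "welch",
) -> CutoffResult:
    """Full adaptive cut-off pipeline for one token."""
    spec = magnitude_spectrum(token, fft_size=fft_size)
    segs = segment_spectrum(spec, win_hz=win_hz, hop_hz=hop_hz, window=window)
    env = variance_envelope(segs)
    slopes = slope_matrix(env)
    return detect_cutoff(segs, env, slopes, alpha=alpha, method=method)


def butterworth_split(
    token: SpeechToken,
    c_f: float,
    order: int = 10,
    her_side: str = "low",
) -> BandSplit:
    """Split the token at ``c_f`` with zero-phase order-``order`` Butterworth
    low-/high-pass filters.

    With ``her_side="low"`` (default) the high-energy region is the band
    below the cut-off, so X_H is the low-pass output.  Zero-phase filtering
    keeps the two outputs time-aligned for paired per-frame correlation.
    """
    if not 0 < c_f < token.fs / 2:
        raise InvalidCutoffError(f"c_f={c_f} outside (0, {token.fs / 2})")
    sos_lo = signal.butter(order, c_f, btype="lowpass", fs=token.fs, output="sos")
    sos_hi = signal.butter(order, c_f, btype="highpass", fs=token.fs, output="sos")
    low = signal.sosfiltfilt(sos_lo, token.samples)
    high = signal.sosfiltfilt(sos_hi, token.samples)
    if her_side == "low":
        return BandSplit(X_H=low, X_L=high, c_f=float(c_f))
    return BandSplit(X_H=high, X_L=low, c_f=float(c_f))


def dscs_transform(split: BandSplit) -> BandSplit:
    """Translate the two band signals for joint display: the HER comes down
    by its maximum, the LER up by its minimum.  Correlation is unaffected."""
    trans_h = float(np.max(split.X_H))
    trans_l = float(np.min(split.X_L))
    return replace(
        split,
        NX_H=split.X_H - trans_h,
        NX_L=split.X_L - trans_l,
        Trans_H=trans_h,
        Trans_L=trans_l,
    )
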