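"""Per-frame correlation between the split band signals (the CSIFs feature)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .audio_io import SpeechToken, frame_signal
from .bandsplit import BandSplit, butterworth_split, dscs_transform, matching_filter
from .errors import InvalidPairError

log = logging.getLogger(__name__)


@dataclass
class CsifsVector:
    p: np.ndarray  # (n_frames,) correlations in [-1, 1]
    n_frames: int
    c_f: float  # cut-off used for the split (provenance)
    fallback_used: bool = False


def pcc(x, y) -> float:
    """Pearson correlation from raw population moments.

    p = (E[xy] - E[x]E[y]) / (sqrt(E[x^2] - E[x]^2) * sqrt(E[y^2] - E[y]^2)).
    A zero-variance input makes the ratio undefined; such degenerate frames
    (silence, hard clipping) are reported as 0 -- uncorrelated -- with a
    logged warning rather than raising.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise InvalidPairError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise InvalidPairError("need at least 2 samples per frame")
    ex, ey = x.mean(), y.mean()
    vx = np.mean(x * x) - ex * ex
    vy = np.mean(y * y) - ey * ey
    if vx <= 0 or vy <= 0:
        log.warning("zero-variance frame in PCC; returning 0")
        return 0.0
    num = np.mean(x * y) - ex * ey
    return float(np.clip(num / np.sqrt(vx * vy), -1.0, 1.0))


def csifs_from_split(split: BandSplit, n_frames: int = 10) -> CsifsVector:
    """Frame the band signals and correlate frame pairs.

    Correlation is exactly invariant to the DSCS translation (it only
    shifts each signal by a constant), so the untranslated X_H/X_L are used
    directly: this keeps the output bit-identical whether or not
    :func:`~pharfric.bandsplit.dscs_transform` was applied, which a
    translated-then-correlated computation cannot guarantee in floating
    point.
    """
    h, l = split.X_H, split.X_L
    fh = frame_signal(h, n_frames)
    fl = frame_signal(l, n_frames)
    p = np.array([pcc(a, b) for a, b in zip(fh, fl)])
    return CsifsVector(p=p, n_frames=n_frames, c_f=split.c_f)


def csifs_feature(
    token: SpeechToken,
    n_frames: int = 10,
    fft_size: int = 1024,
    win_hz: float = 689.0,
    hop_hz: float = 344.0,
    window: str = "hamming",
    alpha: float = 0.01,
    method: str = "welch",
    order: int = 10,
    her_side: str = "low",
) -> CsifsVector:
    """Full pipeline: matching filter -> Butterworth split -> DSCS ->
    paired framing -> per-frame correlation."""
    cut = matching_filter(token, fft_size=fft_size, win_hz=win_hz,
                          hop_hz=hop_hz, window=window, alpha=alpha,
                          method=method)
    split = dscs_transform(
        butterworth_split(token, cut.c_f, order=order, her_side=her_side)
    )
    vec = csifs_from_split(split, n_frames=n_frames)
    vec.fallback_used = cut.fallback_used
    return vec
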