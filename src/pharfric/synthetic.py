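"""Two-class filtered-noise token generator.

Tokens are Gaussian noise shaped by zero-phase Butterworth filters into a
high-energy band plus a quieter out-of-band floor, a narrow resonance peak,
and -- controlled by ``coupling`` -- a shared narrowband component that
straddles the band edge.  Because the downstream split filters both pass
the straddling region, that shared component is the one mechanism that can
make the split band signals genuinely correlate sample-by-sample (signals
confined to disjoint bands are uncorrelated at lag zero regardless of any
envelope coupling).

The class presets encode only qualitative contrasts: the normal-speech (NS)
preset has a wider, higher high-energy band, stronger in/out contrast, no
coupling and a prominent resonance; the pharyngeal-fricative (PF) preset
sits lower, with weaker contrast, strong band-edge coupling and a flattened
resonance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .audio_io import CONSONANTS, Manifest, ManifestRecord, SpeechToken, write_wav
from .errors import ConfigError

log = logging.getLogger(__name__)

#: amplitude of the band-edge shared component at coupling = 1,
#: relative to the unit-RMS in-band noise
_SHARED_GAIN = 1.5
#: the resonance peak sits at peak_gain_db above this reference (dB re in-band)
_PEAK_REF_DB = -20.0
#: half-width of the shared component band, octaves around her_high
_SHARED_HALF_OCT = 1.0 / 6.0
#: half-width of the resonance band, octaves around peak_fc
_PEAK_HALF_OCT = 1.0 / 12.0


@dataclass
class SynthParams:
    fs: int = 44100
    duration_s: float = 0.25
    her_low: float = 3000.0
    her_high: float = 14000.0
    contrast_db: float = 25.0
    coupling: float = 0.0  # rho: band-edge shared-noise fraction
    peak_fc: float = 6000.0
    peak_gain_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.her_low < self.her_high < self.fs / 2:
            raise ConfigError(
                f"need 0 < her_low < her_high < fs/2, got "
                f"({self.her_low}, {self.her_high}) at fs={self.fs}"
            )
        if not 0 <= self.coupling <= 1:
            raise ConfigError(f"coupling must lie in [0, 1], got {self.coupling}")
        if not 0 < self.peak_fc < self.fs / 2:
            raise ConfigError(f"peak_fc outside (0, fs/2): {self.peak_fc}")
        if self.duration_s * self.fs < 10 * 2:
            raise ConfigError("token too short for 10-frame analysis")


@dataclass
class ClassPreset:
    name: str  # "NS" or "PF"
    params: SynthParams


def class_preset(name: str) -> ClassPreset:
    """Default generator settings per class (see module docstring)."""
    if name == "NS":
        return ClassPreset("NS", SynthParams(
            her_low=3000.0, her_high=14000.0, contrast_db=25.0,
            coupling=0.0, peak_fc=6000.0, peak_gain_db=20.0))
    if name == "PF":
        return ClassPreset("PF", SynthParams(
            her_low=400.0, her_high=4000.0, contrast_db=8.0,
            coupling=0.85, peak_fc=1200.0, peak_gain_db=4.0))
    raise ConfigError(f"unknown preset {name!r}")


def _sosfilt(x, wn, btype, fs, order=6):
    sos = signal.butter(order, wn, btype=btype, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _rms(x) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) + 1e-300


def synth_components(params: SynthParams) -> dict[str, np.ndarray]:
    """The four additive parts of a token, before summation.

    ``inband``   unit-RMS noise band-passed to [her_low, her_high];
    ``outband``  complementary-band noise at -contrast_db;
    ``shared``   noise in a one-third-octave band straddling her_high,
                 RMS = coupling * 1.5 (the correlation carrier);
    ``peak``     narrow resonance at peak_fc, peak_gain_db above -20 dB.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    fs = params.fs

    inband = _sosfilt(rng.standard_normal(n), [params.her_low, params.her_high],
                      "bandpass", fs)
    inband /= _rms(inband)

    out = (_sosfilt(rng.standard_normal(n), params.her_low, "lowpass", fs, order=10)
           + _sosfilt(rng.standard_normal(n), params.her_high, "highpass", fs, order=10))
    out = out / _rms(out) * 10.0 ** (-params.contrast_db / 20.0)

    edge_hi = min(params.her_high * 2.0**_SHARED_HALF_OCT, 0.98 * fs / 2)
    shared = _sosfilt(rng.standard_normal(n),
                      [params.her_high / 2.0**_SHARED_HALF_OCT, edge_hi],
                      "bandpass", fs)
    shared = shared / _rms(shared) * params.coupling * _SHARED_GAIN

    pk_hi = min(params.peak_fc * 2.0**_PEAK_HALF_OCT, 0.98 * fs / 2)
    peak = _sosfilt(rng.standard_normal(n),
                    [params.peak_fc / 2.0**_PEAK_HALF_OCT, pk_hi],
                    "bandpass", fs)
    peak = peak / _rms(peak) * 10.0 ** ((_PEAK_REF_DB + params.peak_gain_db) / 20.0)

    return {"inband": inband, "outband": out, "shared": shared, "peak": peak}


def synth_token(
    params: SynthParams,
    consonant: str = "s",
    label: str = "unknown",
    source_id: str = "",
) -> SpeechToken:
    """One deterministic token (same params + seed => bit-identical samples)."""
    parts = synth_components(params)
    x = parts["inband"] + parts["outband"] + parts["shared"] + parts["peak"]
    x = x / (np.max(np.abs(x)) + 1e-300) * 0.5
    return SpeechToken(x, params.fs, consonant=consonant, label=label,
                       source_id=source_id)


def perturb(params: SynthParams, rng: np.random.Generator) -> SynthParams:
    """Per-token natural variation: band edges jittered by up to 0.15 octave,
    gains by a few dB, coupling by +/-0.15 (never leaving [0, 1])."""
    coupling = params.coupling
    if coupling > 0:
        coupling = float(np.clip(coupling + rng.uniform(-0.15, 0.15), 0.0, 1.0))
    return replace(
        params,
        her_low=params.her_low * 2.0 ** rng.uniform(-0.15, 0.15),
        her_high=params.her_high * 2.0 ** rng.uniform(-0.15, 0.15),
        contrast_db=params.contrast_db + rng.uniform(-2.0, 2.0),
        coupling=coupling,
        peak_fc=params.peak_fc * 2.0 ** rng.uniform(-0.2, 0.2),
        peak_gain_db=params.peak_gain_db + rng.uniform(-3.0, 3.0),
    )


def synth_dataset(
    n_per_class: int,
    out_dir: str | Path,
    seed: int = 0,
    presets: tuple[ClassPreset, ClassPreset] | None = None,
    jitter: bool = True,
    duration_s: float | None = None,
) -> Manifest:
    """Balanced two-class WAV dataset with consonant codes cycled.

    Writes ``n_per_class`` tokens per class under ``out_dir`` together with
    a ``manifest.csv`` and a ``params.json`` provenance record.  All
    randomness derives from ``seed``; regenerating is byte-identical.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    presets = presets or (class_preset("PF"), class_preset("NS"))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    records = []
    provenance = {"seed": seed, "n_per_class": n_per_class, "jitter": jitter,
                  "presets": {}}
    for preset in presets:
        base = preset.params
        if duration_s is not None:
            base = replace(base, duration_s=duration_s)
        provenance["presets"][preset.name] = asdict(base)
        for i in range(n_per_class):
            p = perturb(base, rng) if jitter else base
            p = replace(p, seed=int(rng.integers(2**31)))
            consonant = CONSONANTS[i % len(CONSONANTS)]
            name = f"{preset.name}_{consonant}_{i:04d}.wav"
            token = synth_token(p, consonant=consonant, label=preset.name,
                                source_id=name)
            write_wav(token, out_dir / name)
            records.append(ManifestRecord(name, consonant, preset.name))

    manifest = Manifest(records=records, provenance=f"synthetic seed={seed}")
    from .audio_io import save_manifest

    save_manifest(manifest, out_dir / "manifest.csv")
    with open(out_dir / "params.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    log.info("wrote %d tokens to %s", len(records), out_dir)
    return manifest
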