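import numpy as np
import pytest

import pharfric as pf

FS = 44100


def make_tone(freq, duration=0.1, amp=0.5, fs=FS, **kw):
    t = np.arange(int(duration * fs)) / fs
    return pf.SpeechToken(amp * np.sin(2 * np.pi * freq * t), fs, **kw)


def make_noise(seed, duration=0.25, amp=0.1, fs=FS, **kw):
    x = np.random.default_rng(seed).standard_normal(int(duration * fs))
    return pf.SpeechToken(amp * x / np.max(np.abs(x)), fs, **kw)


@pytest.fixture
def tone_token():
    return make_tone


@pytest.fixture
def noise_token():
    return make_noise


def _extract_features(tokens):
    """CSIFs + OSPP FeatureMatrix pair for a token list."""
    P = np.array([pf.csifs_feature(t).p for t in tokens])
    D = np.array([pf.ospp_feature(t).DF for t in tokens])
    labels = np.array([t.label for t in tokens])
    cons = np.array([t.consonant for t in tokens])
    fm_c = pf.FeatureMatrix(P, labels, cons,
                            [f"p_{i + 1}" for i in range(P.shape[1])])
    fm_o = pf.FeatureMatrix(D, labels, cons,
                            [f"df_{i + 1}" for i in range(D.shape[1])])
    return fm_c, fm_o


def make_preset_tokens(n_per_class=50, seed=7):
    """Jittered tokens from the two class presets, consonants cycled."""
    rng = np.random.default_rng(seed)
    tokens = []
    for preset in (pf.class_preset("PF"), pf.class_preset("NS")):
        for i in range(n_per_class):
            p = pf.perturb(preset.params, rng)
            from dataclasses import replace
            p = replace(p, seed=int(rng.integers(2**31)))
            tokens.append(pf.synth_token(
                p, consonant=pf.CONSONANTS[i % 6], label=preset.name,
                source_id=f"{preset.name}_{i}"))
    return tokens


@pytest.fixture(scope="session")
def preset_features():
    """(csifs, ospp, combined) FeatureMatrix triple, 50 tokens per class."""
    fm_c, fm_o = _extract_features(make_preset_tokens(50, seed=7))
    return fm_c, fm_o, pf.FeatureMatrix.combine(fm_c, fm_o)
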