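# pharfric

Acoustic analysis toolkit for screening pharyngeal-fricative misarticulation
in pre-segmented initial consonants (`/c/ /ch/ /q/ /s/ /sh/ /x/`). It
implements two per-frame features plus a bagged decision-tree detector:

- **CSIFs** — the token's magnitude spectrum is split at an adaptively
  detected cut-off into a high-energy region (HER) and low-energy region
  (LER); the time-domain band signals (order-10 zero-phase Butterworth
  low/high-pass) are cut into 10 non-overlapping frames and the Pearson
  correlation of each frame pair is the feature vector. The cut-off comes
  from a "matching filter": 1024-point magnitude spectrum → 689/344 Hz
  Hamming-windowed segmentation → per-segment variance envelope → tail
  regression slopes → significance-gated back-to-front boundary scan.
- **OSPP** — each of 10 frames is mapped to a 43-band one-third-octave
  spectrum (top-anchored at fs/2 = 22 050 Hz) in dB; the excess of the most
  prominent spectral line over an ordinary-least-squares baseline across
  band indices is the feature. Gain and spectral tilt are absorbed by the
  baseline.
- **Detector** — 30 bootstrap-aggregated decision trees with majority
  voting (ties resolve to "no disorder"), evaluated by 10× repeated
  stratified 10-fold cross-validation with accuracy / sensitivity /
  specificity / AUC overall and per consonant, plus Welch-test feature
  significance reports.

Clinical recordings of this kind are not redistributable, so the package
ships a `synthetic` module generating two-class filtered-noise tokens with
controllable band placement, in/out-of-band contrast, band-edge coupling
(the CSIFs driver) and resonance prominence (the OSPP driver). All tests
and examples run on synthetic data only.

## CLI

```sh
pharfric simulate --n 50 --out data/ --seed 7        # WAVs + manifest.csv
pharfric extract  --manifest data/manifest.csv --features csifs,ospp --out feats.csv
pharfric evaluate --features feats.csv --set both --k 10 --repeats 10 \
                  --trees 30 --seed 7 --report report.json
pharfric train    --features feats.csv --set both --out model.bin
pharfric detect   --model model.bin --wav data/PF_c_0000.wav
```

The feature CSV has one row per token
(`source_id,consonant,label,p_1..p_10,df_1..df_10`); the report JSON holds
overall and per-consonant metrics as mean ± SD over CV repeats. Pipeline
defaults can be overridden with a YAML file passed via
`pharfric extract --config` (see `pharfric.config.PharfricConfig`).

## Layout

| module | contents |
|---|---|
| `pharfric.audio_io` | `SpeechToken`, WAV read/write, manifests, framing |
| `pharfric.spectral` | magnitude spectrum, variance envelope, tail slopes |
| `pharfric.bandsplit` | cut-off detection, Butterworth split, DSCS translation |
| `pharfric.csifs` | per-frame band correlation feature |
| `pharfric.ospp` | one-third-octave prominent-peak feature |
| `pharfric.detector` | bagging, repeated CV, significance reports |
| `pharfric.synthetic` | two-class token generator and presets |
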