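# tmsclean

Simulation benchmark for TMS–EEG muscle-artifact rejection. The package
generates a synthetic ground-truth evoked-potential dataset, superposes
parametrically controlled scalp-muscle artifacts on it, cleans the corrupted
data with two methods — signal-space projection with source-informed
reconstruction (SSP–SIR) and FastICA single-component subtraction — and
quantifies how well each method recovers the ground truth across a grid of
artifact topographies and inter-trial variabilities. It also provides the
artifact-characterization operators used on measured-like data (SVD artifact
extraction, inter-trial coherence, minimum-norm montage extrapolation,
pulse-interval handling, signal-space angle distributions).

## Layout

| module | contents |
|---|---|
| `tmsclean.headmodel` | three-layer concentric-sphere forward model, idealized 10–20 montages, lead fields, artifact dipoles |
| `tmsclean.ground_truth` | calibrated synthetic clean epoched datasets (60 ch × 1000 samples × 173 trials at 5 kHz by default) |
| `tmsclean.artifact_sim` | Daubechies-4 wavelet artifact time courses, conductivity-contrast topographies, amplitude scaling, superposition |
| `tmsclean.ssp_sir` | high-pass artifact basis, projector, source-informed reconstruction, windowed application with median blending |
| `tmsclean.ica_clean` | symmetric tanh FastICA on concatenated trials, component selection and subtraction |
| `tmsclean.evaluate` | trial-wise relative error, the 11 × 11 Monte-Carlo condition grid, balanced two-way ANOVA with η² |
| `tmsclean.characterize` | SVD extraction, Morlet ITC, MNE extrapolation, pulse-interval zeroing/interpolation, angle distributions |
| `tmsclean.pipeline` | HDF5 + JSON-sidecar container I/O, study orchestration, CLI |

## CLI

```bash
tmsclean print-config
tmsclean simulate ground-truth --seed 1 --out gt.h5
tmsclean simulate artifact --alpha 0 --contrast 0.005 --amplitude-uv 250 --seed 1 --out art.h5
tmsclean corrupt --truth gt.h5 --artifact art.h5 --out corrupted.h5
tmsclean clean ssp-sir --in corrupted.h5 --out cleaned.h5
tmsclean clean ica --in corrupted.h5 --known-topo topo.csv --out cleaned.h5
tmsclean evaluate --cleaned cleaned.h5 --truth gt.h5
tmsclean grid run --amplitude-uv 250 --reps 2 --trials 24 --fs 1000 --seed 0 --out results/
tmsclean grid anova results/
tmsclean characterize --in corrupted.h5 --out profile.json
tmsclean reproduce --reps 2 --trials 24 --fs 1000 --out results/
```

`reproduce` runs the full desk-scale study (ground truth → condition grid →
two-way ANOVA → markdown report with the per-condition error matrices and
η² table).

## Notes

- Epoched data live in a channels × samples × trials array (μV) with a ms
  time axis; files are HDF5 with a JSON sidecar (`*.h5.json`).
- All randomness flows from explicit seeds; grid cells derive per-cell
  streams from the master seed, so any cell can be recomputed in isolation.
- The artifact topographies come from a head model with jittered electrode
  positions, distinct from the model used inside SSP–SIR, so the
  reconstruction never sees the exact forward model that generated the
  artifacts.
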