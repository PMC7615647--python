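# kymotrace

Quantification suite for single-molecule confocal kymograph experiments on
stretched DNA tethers: sub-pixel particle tracking, MSD/diffusion analysis,
binding/nucleation kinetics, photobleaching step counting, and extensible
worm-like-chain (eWLC) force-extension analysis — together with a synthetic
data generator so every stage is verifiable by parameter recovery against
known ground truth.

## Modules

| module | what it does |
| --- | --- |
| `kymotrace.io` | domain types (`Kymograph`, `Trajectory`, `ForceExtensionCurve`, `RunConfig`) and bit-exact TIFF/CSV/JSON readers & writers |
| `kymotrace.synth` | simulators: diffusing/static/directed emitters, kymograph rendering (Gaussian PSF + Poisson noise), eWLC curves with planted rips, exponential dwells, bleaching staircases, Poisson nucleation |
| `kymotrace.tracking` | bead-margin cropping, per-line 1D Gaussian localization on a moving-window average, greedy nearest-neighbour linking, Savitzky-Golay smoothing |
| `kymotrace.diffusion` | time-averaged MSD, windowed linear/power-law fits (D, b, alpha), motion classification, ensemble summaries, condition regressions |
| `kymotrace.kinetics` | event detection, two-channel arrival-order classes, dwell-time exponential fits, nucleation rates, binding frequencies, positional profiles with junction statistics, obstacle-collision outcomes |
| `kymotrace.photobleach` | change-point step counting (exact DP segmentation, noise-aware merging, unit-height quantization) and oligomer distributions |
| `kymotrace.mechanics` | eWLC evaluation & fitting, rip detection on the implied contour length, contour-length-to-bp conversion, gapped-tether classification |
| `kymotrace.genome` | Cas9 D10A nick-site arithmetic on a reference genome (ships the 48,502-bp lambda phage sequence) |
| `kymotrace.cli` | `kymotrace` command with `simulate`, `track`, `msd`, `events`, `dwell`, `nucleation`, `profile`, `steps`, `fec`, `run` subcommands |

## CLI quick start

```bash
# render a synthetic kymograph + ground truth from a JSON scenario
kymotrace simulate --scenario scenario.json --seed 7 --out out/

# track particles and fit per-trajectory diffusion coefficients
kymotrace track --in out/kymo.tif --channel eGFP --out out/tracks.csv
kymotrace msd --tracks out/tracks.csv --window 0.25 2.0 --convention paper \
    --out out/fits.csv

# detect rips in a force-extension curve
kymotrace fec --in curve.csv --out rips.csv

# full pipeline with a reproducibility manifest
kymotrace run --config config.json --scenario scenario.json --out out/
```

`config.json` is a `RunConfig` snapshot (see `kymotrace.io.RunConfig` for all
fields and defaults; an explicit `seed` is required for `run`).

Two slope conventions are supported when converting an MSD slope to a
diffusion coefficient: `paper` (D = slope, matching the published
"MSD = D t + b" fit) and `physical` (D = slope/2, the 1D Einstein relation).
Every output records which convention was used.

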