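# transloquant

Quantification machinery for fluorescent **lipid-biosensor translocation**
experiments: when a biosensor (for example a phosphatidic-acid binding
domain fused to a fluorescent protein) moves from the cytosol to a
membrane, the readout is a per-cell **membrane/cytosol intensity ratio**
over time. This package implements the full analysis chain for such
experiments — and the in-vitro liposome-binding arm that usually
accompanies them — as a tested, reusable library with a CLI.

It is aimed at cell biologists and image analysts who quantify confocal or
TIRF time-lapses of organelle-targeted biosensors and want a scriptable,
reproducible version of the usual FIJI-macro workflow.

## What it computes

**Organelle masking (wavelet product).** The marker channel is blurred
with a Gaussian ladder at 1x..Nx the Airy radius
(0.61 λ / NA, in pixels), adjacent scales are subtracted into band-pass
("wavelet") planes, the planes are multiplied pixel-wise, thresholded at
0.5 SD, and dilated 1–2 px. Structures present at *every* chosen scale
survive; per-organelle defaults use ladders 1–4x (plasma membrane,
mitochondria, Golgi), 1–2x (ER), and 1–3x (endosomes).

**Localization ratio.** Per frame and cell,

    ratio = (mean I_sensor inside mask ∩ cell − bg) / (mean I_sensor in cytosol ROI − bg)

with the background `bg` measured in a background ROI per frame. For TIRF
time-lapses the readout is instead F_t/F_pre: the background-subtracted
cell-footprint mean normalized to its pre-stimulation average, with the
footprint derived from a minimum-intensity projection.

**Response statistics.** Per cell: baseline-subtracted area under the
post-stimulation curve (AUC, ratio·min, signed) and the change in ratio at
a fixed time after stimulation. Aggregation follows the superplot
convention: replicate means are the units of inference; the grand mean is
the unweighted mean of replicate means and the SEM is taken across
replicates.

**Binding assays.** Percent bound from supernatant/pellet gel bands,
P/(P+S)·100; the one-site specific binding model with background,

    Y = BG + (Bmax − BG) · X / (Kd + X)

fitted with BG fixed to min(Y) and Bmax ≤ 100 (asymptotic 95% CIs, R²,
df); flotation-assay fractions with the ×6 middle-lane dilution
correction; and CD molar ellipticity, m° × 10⁶ / (pathlength(mm) ×
concentration(µM) × n peptide bonds).

**Synthetic scenes.** Because every stage needs ground truth to be
testable, `transloquant.synthetic` generates two-channel microscopy
time-lapses (organelle structure + translocating sensor, Gaussian PSF,
Poisson + read noise) with known masks, cytosol regions and true ratio
traces, plus TIRF footprint movies and binding tables drawn from the
one-site model.

## Worked example

Simulate a single-cell plasma-membrane scene (12 frames, 30 s interval,
stimulation after frame 3, bound fraction rising 0.1 → 0.4), then run the
full mask→ratio→summary pipeline:

```sh
transloquant simulate --out demo --seed 3 --n-frames 12 --stim-frame 3 --f-max 0.4
transloquant ratio demo/stack.tif --rois demo/rois --out demo_out
```

`demo_out/timeseries.csv` starts:

```
cell_id  replicate_id  time_s    value          kind
      1             1       0 1.316366 pm_cyto_ratio
      1             1      30 1.321937 pm_cyto_ratio
      1             1      60 1.319170 pm_cyto_ratio
      1             1      90 1.326366 pm_cyto_ratio
      1             1     120 1.943917 pm_cyto_ratio
      1             1     150 2.434420 pm_cyto_ratio
```

The ratio sits at ~1.32 during the four baseline frames (the sensor is
slightly membrane-enriched at rest) and climbs after the stimulation at
t = 90 s. `demo_out/summary.csv` condenses the trace per cell:

```
cell_id,replicate_id,auc,baseline,delta_30s
1,1,5.85750507,1.31915768,0.624758841
```

i.e. an AUC of 5.86 ratio·min above baseline and a ratio increase of 0.62
thirty seconds after stimulation. A binding-fit example:

```sh
transloquant binding fit binding.csv --out fit.json
```

on noise-free data generated from BG = 9.504, Bmax = 95, Kd = 422 µM
returns `"kd": 422.0, "r_squared": 1.0, "df": 3`.

## Layout

- `transloquant.masking` — Airy-scaled Gaussian ladder, wavelet product, per-organelle profiles
- `transloquant.quant` — ROIs, localization ratios, TIRF normalization, AUC/Δratio, superplot aggregation
- `transloquant.synthetic` — scene/footprint/binding-table generators with ground truth
- `transloquant.binding` — percent bound, one-site fit, flotation, CD conversion
- `transloquant.io`, `transloquant.cli` — TIFF/YAML/CSV round-trips and the `transloquant` command
- `docs/methods.md` — models, conventions, parameter choices and limitations
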