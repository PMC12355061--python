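# platelab

Quantitative analysis of spatially confined platelets: time-lapse
spreading morphometry on micropatterned fibrinogen lines, scanning ion
conductance microscopy (SICM) topography and elastic-modulus mapping
from I-z approach curves, per-platelet morpho-mechanical statistics, and
nonparametric group comparisons — all driven by a synthetic-data
generator with known ground truth.

## Who this is for

Labs that confine platelets (or other small adherent cells) on
microcontact-printed protein lines and follow them with phase-contrast
time-lapse imaging and/or pressure-assisted SICM. The package provides
the complete measurement chain downstream of segmentation and
acquisition, plus a forward simulator that makes every step of that
chain testable against ground truth.

## What it computes

**Spreading morphometry** (from binary mask sequences, 15-s frames):

- Equivalent-ellipse shape: each mask is reduced to the moment ellipse
  rescaled to the mask's exact pixel area; reported as area *A*, major
  and minor axis, orientation θ ∈ (−90°, 90°], aspect ratio.
- Nearest-neighbour tracking; a platelet is *spreading* iff its area at
  least doubles; the onset *t₀* is the 25 %-above-initial crossing.
- Spreading time: with first/last-frame areas as 0/100 %, the interval
  between the 25 % and 75 % crossings (linear interpolation).
- Early growth rates: OLS slopes of the axis lengths over the first
  5 min after onset; alignment angle vs the pattern direction;
  platelet–fibrinogen overlap.

**SICM processing** (from per-pixel I-z curves, 98 % trigger, 10 kPa):

- Topography as the z-position of the trigger crossing; iterative plane
  leveling; segmentation by the >50 nm height criterion.
- Deformation distance dz = z(99 %) − z(98 %) per pixel; apparent
  modulus `E_app = c_d·P·r_i·C_geom / (dz − dz_rigid)`; bottom-effect
  correction `E_corr = E_app·φ(h)` with `φ(h) = h/(h+h_c)`.
- Per-platelet records: median corrected modulus, 99th-percentile
  height, volume (mean height × area), height skewness.

**Statistics**: Dunn's rank test for nonparametric multiple comparisons
(midrank tie correction, Holm adjustment), Rayleigh's test for circular
uniformity (axial angles are doubled), and box summaries with inner
fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR.

The forward simulator uses a hyperbolic current law
`I/I_sat = g/(g+λ_c)` with pressure-induced indentation
`w(g) = w_max·λ_P/(λ_P+g)`, `w_max = c_d·P·r_i/E_eff`, and thickness
factor `E_eff = E/φ(h)`; see `docs/methods.md` for the model, all
constants, and the analysis design choices.

## Worked example

```python
import dataclasses
from platelab.pipeline import RunConfig, run_spreading_pipeline
from platelab.synthgen import spreading_defaults

cfg = RunConfig(seed=7)
cfg.spreading = {c: dataclasses.replace(spreading_defaults(c), n=10)
                 for c in ("confined", "control")}
out = run_spreading_pipeline(cfg)
table = out["table"]
print(table[table.is_spreading].groupby("condition")[
    ["spreading_time_min", "final_aspect_ratio", "final_area_um2", "overlap"]
].median().round(2))
print(out["stats"]["dunn"]["spreading_time_min"].round(4).to_string(index=False))
```

prints

```
           spreading_time_min  final_aspect_ratio  final_area_um2  overlap
condition
confined                15.50                2.23           27.92     0.99
control                  8.75                1.07           28.67     0.73

  group1  group2      z  p_raw  p_adj
confined control 3.7796 0.0002 0.0002
```

Reading this: confined platelets on 4-µm lines reach the same final area
as controls (~28 µm²) but are elongated (aspect ratio 2.2 vs 1.1), lie
almost entirely on the fibrinogen lines (overlap 0.99 vs the 0.73 a
randomly placed control shows on a striped field), and spread more
slowly (median 25–75 % spreading time 15.5 vs 8.7 min; Dunn z = 3.78,
p < 0.001 at n = 10 + 10). The same entry point with `mode="analyze"`
consumes mask-sequence TIFFs from disk instead of simulating.

A command-line interface wraps the pipelines:

```
platelab simulate --seed 1 --out fixtures/        # write TIFF/HDF5 fixtures
platelab analyze  --input-dir fixtures/ --out res/
platelab run-all  --config run.yaml --seed 7 --out res/
platelab stats    --input values.csv --test dunn --adjust holm
```

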