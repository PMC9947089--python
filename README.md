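# thermodose

MR-thermometry thermal-dose analysis for intracavitary laser heating
experiments — in particular, assessing how much kidney tissue is pushed past
the thermal-damage threshold during Ho:YAG laser lithotripsy.

Pulsed holmium lasers used to fragment urinary stones deposit most of their
energy in the irrigation fluid surrounding the stone. At low irrigation
rates, in small renal calyces, or at high power, that heat accumulates and
can thermally injure the renal parenchyma. Dynamic MR imaging can watch this
happen: the water proton resonance frequency shifts with temperature, so a
gradient-echo phase time series is a quantitative, spatially resolved
thermometer. `thermodose` turns such a series into damage-area estimates,
for MR physicists and urology researchers running (or simulating) heating
experiments.

## What it computes

**Temperature maps (PRF method).** For each pixel, the phase change from a
pre-heating baseline is converted to a temperature change

```
ΔT = Δφ / (2π · γ · B0 · α · 10⁻⁶ · TE)
```

with γ = 42.577 MHz/T, α ≈ −0.01 ppm/°C the PRF coefficient, B0 the field
strength and TE the echo time. Phase differences are computed as complex
ratios (no wrap seams) and unwrapped temporally frame to frame.

**Pixel exclusion and smoothing.** Pixels whose signal magnitude S falls
below 3.7 · S_air (S_air = mean magnitude in an air region) are discarded as
phase noise; a manually drawn kidney ROI restricts the analysis; a
mask-aware 3 × 3 averaging filter suppresses residual noise.

**Thermal dose (CEM43).** Each temperature history is converted to
cumulative equivalent minutes at 43 °C,

```
CEM43 = Σ Δt · R^(43 − T),   R = 0.5 for T ≥ 43 °C, 0.25 below
```

(no accrual below 39 °C). The primary readout is the **critical area**: the
summed area of pixels whose CEM43 exceeds 120 min, the damage threshold for
most tissues including renal parenchyma, plus the hottest pixel and its
temperature curve.

**Synthetic experiments.** Because the chain needs input data to be tested,
the package includes a 2-D finite-difference heating simulator (pulsed
Gaussian source plus well-mixed cavity heating, irrigation-rate-dependent
Newtonian cooling, thermal diffusion into tissue, no perfusion — an ex vivo
kidney) and an MR encoder that converts simulated temperature fields into
noisy magnitude/phase series with a realistic acquisition geometry
(235 × 259 mm² FOV, 174 × 192 matrix ⇒ 1.82 mm²/pixel, 620 ms per frame,
TE 15 ms at 1.5 T). Calyx-like (~0.95 cm³) and pelvis-like (~8.86 cm³)
scene presets mirror the two fiber sites of a typical experiment.

## Worked example

```python
from thermodose import (
    ExperimentConfig, LaserProtocol, SimulationSource,
    run_experiment, scene_preset,
)

protocol = LaserProtocol(power_watts=30.0, t_on_s=10.0, t_off_s=5.0,
                         n_applications=3)
scene = scene_preset("calyx", power_watts=30.0, irrigation_ml_per_min=10.0,
                     grid_shape=(64, 64))
config = ExperimentConfig(
    run_id="calyx-30W-10ml",
    source=SimulationSource(protocol=protocol, scene=scene, seed=1234,
                            fiber_site="calyx"),
)
res = run_experiment(config).result
print(f"critical area (CEM43 > 120 min): {res.area_mm2:.1f} mm^2 "
      f"({res.n_pixels} pixels)")
print(f"hottest pixel: {res.hottest_pixel}, "
      f"max temperature rise {res.max_delta_t_C:.1f} degC")
```

prints

```
critical area (CEM43 > 120 min): 198.6 mm^2 (109 pixels)
hottest pixel: (32, 32), max temperature rise 49.5 degC
```

Three 10-s applications of 30 W with 5-s pauses at only 10 ml/min irrigation
drive ~199 mm² of the calyx scene past the 120-min damage threshold, with a
peak temperature rise of ~50 °C at the fiber tip. Raising irrigation to
100 ml/min in the same scene yields 0 mm². The same `run_experiment` entry
point accepts `DicomSource(directory=...)` with user-supplied air/kidney
ROIs to analyze measured magnitude/phase DICOM series.

A command-line interface wraps the same machinery:

```
thermodose simulate --power 30 --t-on 10 --t-off 5 --irrigation 10 \
    --duration 80 --seed 1 --out series_dir
thermodose analyze --dicom-dir series_dir --air-roi air.json \
    --kidney-roi kidney.json --out results
thermodose sweep --config sweep.yaml --out sweep_results
```

`sweep` runs the full factorial grid (powers × pulse protocols × irrigation
rates × fiber sites × replicates) and writes a long-format CSV plus a
mean ± SD pivot table of critical areas.

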