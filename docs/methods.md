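# Methods

## Temperature reconstruction

The proton resonance frequency (PRF) of tissue water shifts approximately
linearly with temperature, α ≈ −0.01 ppm/°C. In a gradient-echo acquisition
this appears as a phase shift Δφ = 2π·γ·B0·α·10⁻⁶·ΔT·TE per pixel, which
`thermometry.reconstruct_delta_t` inverts. Design choices:

- **Baseline**: the circular mean (mean unit phasor) of the first
  `baseline_frame_count` phase frames (default 5, i.e. ~3 s of pre-laser
  frames at 620 ms/frame). Averaging several baseline frames reduces the
  phase-noise floor of every subsequent difference map by ~√n; the circular
  mean is insensitive to the ±π seam.
- **Complex-difference phase**: per-frame differences are computed as
  `angle(exp(iφ_t)·conj(z_baseline))` rather than by subtracting stored
  phase maps, which is identical modulo 2π but has no wrap seam.
- **Temporal unwrapping only**: frame-to-frame increments are wrapped into
  (−π, π] and cumulatively summed. At TE = 15 ms and 1.5 T one phase cycle
  corresponds to ~104 °C, and per-frame temperature steps in these
  experiments are a few °C, far inside the unwrapping capture range. No
  spatial (2-D) unwrapping is performed.
- **No B0-drift correction**: scanner drift over the ~1–2 min of a heating
  run is small against the tens of °C of signal here; a reference-ROI
  drift correction is left as future work.

The PRF coefficient and baseline policy are configurable; the defaults are
the literature-standard values.

## Pixel exclusion and smoothing

Low-SNR pixels produce phase noise that converts into spurious temperature
excursions and hence spurious dose. Two rules are applied, both evaluated
once per experiment (a static mask keeps the dose integral over a fixed
pixel set):

1. **Magnitude threshold**: a pixel is kept iff its mean baseline magnitude
   is ≥ 3.7 × the mean magnitude of an air region (strictly-below pixels
   are removed). The factor 3.7 is configurable.
2. **Kidney ROI**: a polygon (rasterized by the pixel-centre even-odd rule)
   or boolean raster restricts analysis to parenchyma and collecting
   system. Coordinates are 0-based (row, col) with pixel (i, j) centred at
   (i, j).

Smoothing is a mask-aware 3 × 3 box filter on the temperature maps: each
kept pixel becomes the mean of the *kept* pixels in its neighbourhood,
truncated at image borders. Renormalizing instead of zero-padding avoids
biasing rim temperatures toward zero — the rim is exactly where the
area-threshold decision is made. Whether smoothing runs before or after
dose accumulation is switchable (`smooth_enabled`); the default order is
mask → ROI → smooth → dose.

## Thermal dose and critical area

CEM43 converts a temperature history into the equivalent exposure time at
43 °C: each frame contributes Δt·R^(43−T) minutes with R = 0.5 at or above
the 43 °C breakpoint and R = 0.25 between a 39 °C floor and the breakpoint;
below the floor nothing accrues. All four constants (breakpoint, two R
values, floor) are explicit `DoseParams` fields with these conventional
defaults. Frame Δt is the acquisition interval TA (0.62 s by default), the
real elapsed time per image. Absolute temperature is the configured
baseline (37 °C bath temperature by default) plus the reconstructed ΔT.

The critical area sums pixels whose dose **strictly exceeds** 120 min
(the damage threshold for most tissues, including renal parenchyma) times
the per-pixel area (FOV/matrix per axis; 1.82 mm² for the default
geometry). The hottest pixel is the kept pixel with the largest ΔT over
time, ties broken in row-major order; its full temperature curve is
reported.

## Heating simulator

A 2-D single-slice explicit finite-difference model:

    dT/dt = D ∇²T + s(r)·[laser on] − k_irr·I·(T − T_irr)  (cavity pixels)
                                    − k_tissue·(T − T_base) (elsewhere)

- **Geometry**: a disk-shaped fluid cavity (calyx ~0.95 cm³ or pelvis
  ~8.86 cm³, converted to a disk of equivalent cross-section at 4 mm slice
  thickness) with a parenchymal rim, embedded in bath background. The
  fiber tip sits at the cavity centre.
- **Source**: an isotropic Gaussian hotspot at the tip (σ = 2.5 mm,
  amplitude 0.1 K/s per W) plus a uniform well-mixed term over the cavity,
  η·P/(ρc·V) with η = 0.2 and ρc = 4.18 J/(cm³·K). Ho:YAG radiation is
  absorbed within millimetres in water and convectively redistributed, so
  the cavity fluid behaves partly as a stirred compartment; the 1/V
  scaling is what makes the small calyx markedly more hazardous than the
  large pelvis at equal power, as observed experimentally. The two gains
  were calibrated once against the stated design point (30 W at 10 ml/min
  must exceed 43 °C in the cavity within 10 s) under the constraint of
  sub-boiling peaks, and then frozen.
- **Cooling**: Newtonian sinks. Cavity pixels relax at rate k_irr·I
  (k_irr = 0.004 s⁻¹ per ml/min — time constant 25 s at 10 ml/min, 2.5 s
  at 100 ml/min); all other pixels couple to the bath at 0.01 s⁻¹. The
  linear-in-flow Newtonian form is the minimal model that is monotone in
  irrigation rate.
- **Irrigant temperature**: by default the cavity sink relaxes toward the
  *baseline* temperature, i.e. irrigation removes excess heat relative to
  the pre-laser equilibrated state. This makes the sourceless system an
  exact equilibrium (a zero-power run stays identically at baseline, and
  reconstructed ΔT is pure noise), which is what the pre-run rinse
  establishes physically and what the baseline-referenced thermometry
  measures. A colder irrigant (e.g. 22.1 °C tap water) can be set
  explicitly via `irrigant_temp_C`, at the cost of a drifting baseline.
- **Diffusion**: D = 0.14 mm²/s (water/soft tissue) with a 5-point stencil
  and zero-flux boundaries. The explicit scheme requires
  dt ≤ min(pixel)²/(4D) ≈ 3.3 s at the 1.35 mm default pixel; the default
  dt = 0.1 s is well inside it and resolves the cooling rates. Violations
  raise a configuration error naming the admissible maximum.
- **No perfusion, no advection, no 3-D transport, no boiling physics.**

Frames are sampled at exact multiples of the MR frame interval (620 ms)
with a shortened final integration step before each sample, so the
simulation is deterministic and timestamp-exact.

## MR encoding

Simulated temperatures are encoded into complex images: magnitude is a
constant tissue/fluid level (default 100) inside the object and a
near-zero level (default 1) in a border of configurable width — the "air"
region that gives every synthetic frame a well-defined S_air for the noise
mask. The phase advances from a fixed smooth baseline map by the PRF shift
of the temperature change relative to the first frame. Complex Gaussian
noise (default SD 2 per channel, i.e. SNR 50 in the object, phase noise
~0.02 rad ≈ 0.33 °C per frame before smoothing) is drawn from a single
`numpy` generator seeded per call; output is bit-reproducible per seed.

What the generator does *not* emulate: motion and flow artifacts (the
air-suction disturbances that force real runs to be discarded appear only
as a QC-exclusion flag), EPI distortion and k-space effects, B0 drift,
coil shading, and fat signal. Passing tests therefore demonstrate the
correctness of the processing chain and the qualitative physics of the
heating trends, not the artifact robustness needed on measured data.

## Pipeline and sweeps

`run_experiment` executes reconstruct → noise mask → kidney ROI → smooth →
CEM43 → critical area from either a simulation spec or a DICOM directory,
and writes the dose map (float TIFF), a summary CSV row (fixed column
order) and a JSON provenance record (full configuration, seed, software
version, input SHA-256). Runs flagged `qc_excluded` are skipped with a
logged reason. `run_sweep` iterates a factorial grid with per-cell seeds
derived deterministically from the base seed (CRC32 of the cell key), so
partial reruns are stable; per-cell failures are recorded per row and the
sweep continues. Summaries report mean ± SD per cell only — with three to
eight replicates, inferential statistics would be overreach.

Synthetic experiments default to simulation grids of 64 × 64 pixels at the
acquisition pixel size and ~80 s of simulated time (three pulse cycles
plus a 30 s cool-down tail), sizes at which a full preset sweep completes
in seconds while leaving the heated region far from the grid boundary.

## Known limitations

- The heating model is 2-D and unperfused; absolute areas depend on the
  calibration constants and should be read as order-of-magnitude analogues
  of measured values, while *orderings* across irrigation, power, pause
  structure and cavity size are robust model predictions.
- Temporal unwrapping fails if a pixel heats by more than ~52 °C between
  consecutive frames; at 620 ms frames this margin is comfortable.
- The DICOM reader expects paired magnitude/phase series with standard
  rescale tags and per-frame timing (TriggerTime, with InstanceNumber
  fallback); vendor-specific phase conventions may need the PRF
  coefficient's sign flipped.
- One experimentally reported inversion — a *larger* damage area for the
  longer pause in one small-cavity series — is not reproduced by this
  cooling model, which always predicts that longer pauses shed more heat;
  the simulator deliberately follows the physics rather than that single
  observation.
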