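"""Synthetic pulsed-laser heating and MR phase encoding.

A 2-D single-slice forward model of intracavitary laser heating with
irrigation cooling, plus the complex MR signal model that turns a
temperature history into a dynamic magnitude/phase series.  The heat model
is an explicit finite-difference diffusion equation with Newtonian sink
terms:

    dT/dt = D lap(T) + s(r) [laser on]
            - k_irr * I * (T - T_irrigant)     on cavity (fluid) pixels
            - k_tissue * (T - T_baseline)      elsewhere

where s(r) is an isotropic Gaussian heating rate centred at the fiber tip
plus a uniform well-mixed term over the cavity fluid (Ho:YAG energy is
absorbed within millimetres in water and convectively redistributed, so
the per-volume heating rate of the cavity fluid scales inversely with
cavity volume — the mechanism by which small calyces are more hazardous
than the large renal pelvis).  I is the irrigation rate (ml/min); the sink
terms model irrigation flushing and coupling of the ex vivo organ to the
surrounding bath.  There is no blood perfusion term: the model emulates an
ex vivo kidney.

The MR encoder maps absolute temperature into gradient-echo phase via the
PRF shift, assigns a tissue/fluid signal level inside the object and a
near-zero level in a border "air" region, and adds complex Gaussian noise
from a single seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .acquisition import (
    DEFAULT_PRF_COEFF_PPM_PER_C,
    AcquisitionParams,
)
from .errors import ConfigurationError, DataError, UsageError
from .thermometry import DynamicSeries, prf_rad_per_C, wrap_phase

#: Peak Gaussian heating rate per watt of mean laser power (K/s per W),
#: for the local hotspot at the fiber tip.  Calibrated once so that the
#: 30 W / 10 ml/min cavity presets drive peak cavity temperatures past
#: 43 degC within 10 s of laser-on while staying below boiling.
SOURCE_GAIN_K_PER_S_PER_W = 0.1

#: Fraction of the optical power that ends up uniformly heating the cavity
#: fluid (convective mixing of the strongly absorbed Ho:YAG energy).  The
#: resulting well-mixed heating rate is eta * P / (rho_c * V_cavity) with
#: rho_c the volumetric heat capacity of water, so small cavities heat
#: faster than large ones at equal power.
MIXING_EFFICIENCY = 0.2

#: Volumetric heat capacity of water, J / (cm^3 K).
WATER_RHO_C_J_PER_CM3_K = 4.18

#: Thermal diffusivity of water/soft tissue, mm^2/s.
DEFAULT_DIFFUSIVITY_MM2_PER_S = 0.14

#: Newtonian irrigation cooling rate per unit flow, (1/s) per (ml/min).
DEFAULT_COOLING_COEFF_PER_ML = 0.004

#: Coupling of non-cavity pixels to the bath/baseline temperature, 1/s.
DEFAULT_TISSUE_COUPLING_PER_S = 0.01

#: Irrigation-rate presets (ml/min) used in the replication sweeps.
IRRIGATION_PRESETS_ML_MIN = (10, 30, 50, 70, 100)


@dataclass(frozen=True)
class LaserProtocol:
    """A pulsed laser application protocol.

    The laser runs for ``t_on_s`` (the application time t_L), pauses for
    ``t_off_s`` (the intermittent delay t_D) and repeats ``n_applications``
    times.  ``power_watts`` is the mean optical power; the heating source
    amplitude in the scene scales linearly with it.
    """

    power_watts: float
    t_on_s: float
    t_off_s: float
    n_applications: int = 3

    def __post_init__(self) -> None:
        if self.power_watts < 0:
            raise ConfigurationError("power_watts must be >= 0")
        if self.t_on_s <= 0:
            raise ConfigurationError("t_on_s must be > 0")
        if self.t_off_s < 0:
            raise ConfigurationError("t_off_s must be >= 0")
        if self.n_applications < 1:
            raise ConfigurationError("n_applications must be >= 1")

    @property
    def total_time_s(self) -> float:
        """Time from first laser-on to end of the last pause."""
        return self.n_applications * (self.t_on_s + self.t_off_s)

    def is_on(self, t_since_start_s: float) -> bool:
        """Whether the laser is firing at a time measured from first on."""
        if t_since_start_s < 0:
            return False
        cycle = self.t_on_s + self.t_off_s
        k = int(np.floor(t_since_start_s / cycle))
        if k >= self.n_applications:
            return False
        return (t_since_start_s - k * cycle) < self.t_on_s


@dataclass
class ThermalSceneConfig:
    """Geometry and physics of the heated scene.

    The grid covers the kidney slice: a fluid-filled cavity (calyx or
    pelvis), the surrounding parenchyma, and background bath.  The laser
    fiber tip sits inside the cavity.
    """

    grid_shape: tuple[int, int]
    pixel_mm: tuple[float, float]
    cavity_mask: np.ndarray
    tissue_mask: np.ndarray
    source_position: tuple[int, int]
    source_amplitude_K_per_s: float
    mixed_amplitude_K_per_s: float = 0.0
    source_sigma_mm: float = 2.5
    diffusivity_mm2_per_s: float = DEFAULT_DIFFUSIVITY_MM2_PER_S
    irrigation_ml_per_min: float = 10.0
    cooling_coeff_per_ml: float = DEFAULT_COOLING_COEFF_PER_ML
    tissue_coupling_per_s: float = DEFAULT_TISSUE_COUPLING_PER_S
    baseline_temp_C: float = 37.0
    irrigant_temp_C: float | None = None
    sim_dt_s: float = 0.1

    def __post_init__(self) -> None:
        self.cavity_mask = np.asarray(self.cavity_mask, dtype=bool)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.cavity_mask.shape != tuple(self.grid_shape):
            raise ConfigurationError("cavity_mask shape must equal grid_shape")
        if self.tissue_mask.shape != tuple(self.grid_shape):
            raise ConfigurationError("tissue_mask shape must equal grid_shape")
        if np.any(self.cavity_mask & self.tissue_mask):
            raise ConfigurationError("cavity_mask and tissue_mask must be disjoint")
        r, c = self.source_position
        if not (0 <= r < self.grid_shape[0] and 0 <= c < self.grid_shape[1]):
            raise ConfigurationError("source_position outside the grid")
        if not self.cavity_mask[r, c]:
            raise ConfigurationError("source_position must lie inside cavity_mask")
        if self.irrigation_ml_per_min < 0:
            raise ConfigurationError("irrigation_ml_per_min must be >= 0")
        max_dt = self.max_stable_dt_s()
        if self.sim_dt_s > max_dt:
            raise ConfigurationError(
                f"sim_dt_s={self.sim_dt_s} violates the explicit-scheme "
                f"stability bound; maximum admissible sim_dt_s is {max_dt:.6g} s"
            )

    def max_stable_dt_s(self) -> float:
        """Stability bound min(pixel)^2 / (4 D) of the explicit scheme."""
        if self.diffusivity_mm2_per_s <= 0:
            return np.inf
        return min(self.pixel_mm) ** 2 / (4.0 * self.diffusivity_mm2_per_s)

    @property
    def effective_irrigant_temp_C(self) -> float:
        """Temperature toward which irrigation pulls cavity pixels.

        Defaults to the baseline temperature, i.e. irrigation removes excess
        heat relative to the pre-laser equilibrated state (the rinse before
        each run homogenises the cavity).  Set ``irrigant_temp_C`` explicitly
        to model a colder irrigant; note the sourceless system is then no
        longer at rest at baseline.
        """
        if self.irrigant_temp_C is None:
            return self.baseline_temp_C
        return self.irrigant_temp_C


@dataclass
class GroundTruthSeries:
    """Absolute-temperature rasters sampled at the MR frame interval."""

    frames: np.ndarray
    times_s: np.ndarray
    laser_on: np.ndarray
    baseline_temp_C: float = 37.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.laser_on = np.asarray(self.laser_on, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def delta_t(self) -> np.ndarray:
        """Temperature change of every frame relative to the first frame."""
        return self.frames - self.frames[0]


def _laplacian(t: np.ndarray, dr_mm: float, dc_mm: float) -> np.ndarray:
    # 5-point stencil with zero-flux (replicated-edge) boundaries.
    p = np.pad(t, 1, mode="edge")
    return (p[:-2, 1:-1] - 2.0 * t + p[2:, 1:-1]) / dr_mm**2 + (
        p[1:-1, :-2] - 2.0 * t + p[1:-1, 2:]
    ) / dc_mm**2


def gaussian_source(scene: ThermalSceneConfig) -> np.ndarray:
    """Isotropic Gaussian heating-rate field (K/s) at full laser power."""
    rr, cc = np.meshgrid(
        np.arange(scene.grid_shape[0], dtype=float) * scene.pixel_mm[0],
        np.arange(scene.grid_shape[1], dtype=float) * scene.pixel_mm[1],
        indexing="ij",
    )
    r0 = scene.source_position[0] * scene.pixel_mm[0]
    c0 = scene.source_position[1] * scene.pixel_mm[1]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    return scene.source_amplitude_K_per_s * np.exp(
        -d2 / (2.0 * scene.source_sigma_mm**2)
    )


def simulate_temperature(
    protocol: LaserProtocol,
    scene: ThermalSceneConfig,
    duration_s: float,
    frame_interval_s: float = 0.62,
    start_delay_s: float = 3.1,
) -> GroundTruthSeries:
    """Integrate the heat model and sample frames at the MR frame interval.

    The laser fires according to ``protocol`` starting at ``start_delay_s``
    (the leading frames are the thermometry baseline).  Integration is
    explicit Euler at ``scene.sim_dt_s`` with a shortened final step before
    each frame time, so frame timestamps are exact multiples of
    ``frame_interval_s``.  Deterministic: no randomness is involved.

    Returns
    -------
    GroundTruthSeries
        Absolute temperature (degC) per frame, frame times, and a per-frame
        laser-on flag.
    """
    if duration_s < protocol.total_time_s:
        raise UsageError(
            "duration_s must cover the protocol's total on+off time "
            f"({protocol.total_time_s} s)"
        )
    dr, dc = scene.pixel_mm
    diff = scene.diffusivity_mm2_per_s
    cavity = scene.cavity_mask
    source = gaussian_source(scene) + np.where(
        cavity, scene.mixed_amplitude_K_per_s, 0.0
    )
    k_irr = scene.cooling_coeff_per_ml * scene.irrigation_ml_per_min
    k_tis = scene.tissue_coupling_per_s
    t_irr = scene.effective_irrigant_temp_C
    base = scene.baseline_temp_C

    n_frames = int(np.floor(duration_s / frame_interval_s)) + 1
    frame_times = np.arange(n_frames) * frame_interval_s
    frames = np.empty((n_frames, *scene.grid_shape), dtype=float)
    laser_on = np.zeros(n_frames, dtype=bool)

    temp = np.full(scene.grid_shape, base, dtype=float)
    t_now = 0.0
    frames[0] = temp
    laser_on[0] = protocol.power_watts > 0 and protocol.is_on(t_now - start_delay_s)
    for k in range(1, n_frames):
        target = frame_times[k]
        while t_now < target - 1e-12:
            dt = min(scene.sim_dt_s, target - t_now)
            on = protocol.is_on(t_now - start_delay_s)
            rate = diff * _laplacian(temp, dr, dc)
            if on:
                rate = rate + source
            cool = np.where(cavity, k_irr * (temp - t_irr), k_tis * (temp - base))
            temp = temp + dt * (rate - cool)
            t_now += dt
        frames[k] = temp
        laser_on[k] = protocol.power_watts > 0 and protocol.is_on(
            target - start_delay_s
        )
    return GroundTruthSeries(
        frames=frames,
        times_s=frame_times,
        laser_on=laser_on,
        baseline_temp_C=base,
    )


def _resample_stack(frames: np.ndarray, matrix: tuple[int, int]) -> np.ndarray:
    if frames.shape[1:] == tuple(matrix):
        return frames
    zr = matrix[0] / frames.shape[1]
    zc = matrix[1] / frames.shape[2]
    return np.stack(
        [ndimage.zoom(f, (zr, zc), order=1, grid_mode=True, mode="nearest")
         for f in frames]
    )


def encode_mr_series(
    truth: GroundTruthSeries,
    acq: AcquisitionParams,
    prf_coeff_ppm_per_C: float = DEFAULT_PRF_COEFF_PPM_PER_C,
    noise_sd: float = 2.0,
    air_margin_px: int = 6,
    seed: int = 0,
    signal_level: float = 100.0,
    air_level: float = 1.0,
) -> DynamicSeries:
    """Encode a temperature history into a noisy dynamic MR series.

    Each pixel's phase advances from a fixed smooth baseline phase map by
    the PRF shift of its temperature change relative to the first frame.
    Magnitude is ``signal_level`` inside the object and ``air_level`` in a
    border of width ``air_margin_px`` (the "air outside the water bath"),
    so noise-masking rules have a well-defined air reference on every
    synthetic frame.  Complex Gaussian noise of standard deviation
    ``noise_sd`` per channel is drawn from a single generator seeded with
    ``seed``; output is bit-for-bit reproducible for a fixed seed.
    """
    if noise_sd < 0:
        raise UsageError("noise_sd must be >= 0")
    if not np.all(np.isfinite(truth.frames)):
        raise DataError("ground-truth temperatures contain non-finite values")

    frames = _resample_stack(truth.frames, acq.matrix)
    delta_t = frames - frames[0]
    scale = prf_rad_per_C(acq, prf_coeff_ppm_per_C)

    rows, cols = acq.matrix
    rr = np.arange(rows)[:, None] / max(rows - 1, 1)
    cc = np.arange(cols)[None, :] / max(cols - 1, 1)
    baseline_phase = 0.4 * np.pi * rr - 0.2 * np.pi * cc  # smooth, wrap-free

    object_mask = np.zeros((rows, cols), dtype=bool)
    m = air_margin_px
    if m > 0:
        object_mask[m:-m, m:-m] = True
    else:
        object_mask[:] = True
    magnitude = np.where(object_mask, signal_level, air_level)

    rng = np.random.default_rng(seed)
    n = truth.n_frames
    mag_out = np.empty((n, rows, cols))
    phs_out = np.empty((n, rows, cols))
    for k in range(n):
        z = magnitude * np.exp(1j * (baseline_phase + scale * delta_t[k]))
        if noise_sd > 0:
            z = z + rng.normal(0.0, noise_sd, z.shape) + 1j * rng.normal(
                0.0, noise_sd, z.shape
            )
        mag_out[k] = np.abs(z)
        phs = np.angle(z)
        phs_out[k] = np.where(phs >= np.pi, phs - 2 * np.pi, phs)

    first_on = np.flatnonzero(truth.laser_on)
    baseline_count = int(first_on[0]) if first_on.size else max(1, n // 4)
    baseline_count = max(1, min(baseline_count, n - 1))
    return DynamicSeries(
        magnitude_frames=mag_out,
        phase_frames=phs_out,
        times_s=truth.times_s.copy(),
        acq=acq,
        baseline_frame_count=baseline_count,
    )


# ---------------------------------------------------------------------------
# Scene presets: calyx-like (small cavity) and pelvis-like (large cavity)
# ---------------------------------------------------------------------------

#: Cavity volume analogues (cm^3) for the two fiber sites; converted to a
#: disk of equivalent cross-section at the slice thickness.
SITE_VOLUMES_CM3 = {"calyx": 0.95, "pelvis": 8.86}


def scene_preset(
    site: str,
    power_watts: float,
    irrigation_ml_per_min: float,
    grid_shape: tuple[int, int] = (64, 64),
    pixel_mm: tuple[float, float] | None = None,
    slice_mm: float = 4.0,
    tissue_rim_mm: float = 8.0,
    baseline_temp_C: float = 37.0,
) -> ThermalSceneConfig:
    """Build a kidney-cavity scene for a fiber site preset.

    ``site`` is ``"calyx"`` (small, ~0.95 cm^3) or ``"pelvis"`` (large,
    ~8.86 cm^3).  The cavity is a centred disk whose area equals the site
    volume divided by the slice thickness; parenchyma is a rim of
    ``tissue_rim_mm`` around it (clipped to the grid).  The fiber tip sits
    at the cavity centre; its local hotspot amplitude is
    ``SOURCE_GAIN_K_PER_S_PER_W * power_watts`` and the well-mixed cavity
    heating rate is ``MIXING_EFFICIENCY * power / (rho_c * V_cavity)``, so
    the small calyx heats much faster than the large pelvis.
    """
    if site not in SITE_VOLUMES_CM3:
        raise ConfigurationError(f"unknown fiber site {site!r}")
    if pixel_mm is None:
        acq = AcquisitionParams()
        pixel_mm = acq.pixel_mm
    area_mm2 = SITE_VOLUMES_CM3[site] * 1000.0 / slice_mm
    radius_mm = float(np.sqrt(area_mm2 / np.pi))

    rr, cc = np.meshgrid(
        np.arange(grid_shape[0], dtype=float) * pixel_mm[0],
        np.arange(grid_shape[1], dtype=float) * pixel_mm[1],
        indexing="ij",
    )
    centre = ((grid_shape[0] // 2) * pixel_mm[0], (grid_shape[1] // 2) * pixel_mm[1])
    dist = np.sqrt((rr - centre[0]) ** 2 + (cc - centre[1]) ** 2)
    cavity = dist <= radius_mm
    tissue = (dist > radius_mm) & (dist <= radius_mm + tissue_rim_mm)

    return ThermalSceneConfig(
        grid_shape=tuple(grid_shape),
        pixel_mm=tuple(pixel_mm),
        cavity_mask=cavity,
        tissue_mask=tissue,
        source_position=(grid_shape[0] // 2, grid_shape[1] // 2),
        source_amplitude_K_per_s=SOURCE_GAIN_K_PER_S_PER_W * power_watts,
        mixed_amplitude_K_per_s=(
            MIXING_EFFICIENCY
            * power_watts
            / (WATER_RHO_C_J_PER_CM3_K * SITE_VOLUMES_CM3[site])
        ),
        irrigation_ml_per_min=irrigation_ml_per_min,
        baseline_temp_C=baseline_temp_C,
    )


def acquisition_for_scene(
    scene: ThermalSceneConfig, base: AcquisitionParams | None = None
) -> AcquisitionParams:
    """Acquisition parameters whose matrix matches the scene grid.

    Keeps the timing and field parameters of ``base`` (default: the standard
    kidney protocol) but sets matrix = grid and FOV = grid * pixel size, so
    encoded series need no resampling and the per-pixel area is preserved.
    """
    if base is None:
        base = AcquisitionParams()
    fov = (
        scene.grid_shape[0] * scene.pixel_mm[0],
        scene.grid_shape[1] * scene.pixel_mm[1],
    )
    return replace(base, matrix=tuple(scene.grid_shape), fov_mm=fov)
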