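"""Proton-resonance-frequency (PRF) temperature reconstruction.

The water proton resonance frequency shifts by roughly -0.01 ppm per degC of
heating, so in a gradient-echo image the phase of each pixel moves by

    dphi = 2 pi * gamma * B0 * alpha * 1e-6 * dT * TE        [rad]

with gamma the proton gyromagnetic ratio (Hz/T), B0 the field strength (T),
alpha the PRF coefficient (ppm/degC) and TE the echo time (s).  Inverting
this per pixel and per frame against a pre-heating baseline phase yields
temperature-difference maps.  Phase is only known modulo 2 pi, so the
frame-to-frame phase increments are unwrapped temporally before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import (
    DEFAULT_PRF_COEFF_PPM_PER_C,
    GYROMAGNETIC_RATIO_HZ_PER_T,
    AcquisitionParams,
)
from .errors import ConfigurationError, UsageError

TWO_PI = 2.0 * np.pi


@dataclass
class DynamicSeries:
    """A time-ordered magnitude + phase MR image series.

    Attributes
    ----------
    magnitude_frames : ndarray, shape (n_frames, rows, cols)
        Non-negative signal magnitude per frame (arbitrary units).
    phase_frames : ndarray, shape (n_frames, rows, cols)
        Phase per frame in radians, within [-pi, pi).
    times_s : ndarray, shape (n_frames,)
        Frame timestamps in seconds, strictly increasing.
    acq : AcquisitionParams
        Acquisition metadata for the series.
    baseline_frame_count : int
        Number of leading frames acquired before any heating; these define
        the phase baseline.
    """

    magnitude_frames: np.ndarray
    phase_frames: np.ndarray
    times_s: np.ndarray
    acq: AcquisitionParams
    baseline_frame_count: int = 5

    def __post_init__(self) -> None:
        self.magnitude_frames = np.asarray(self.magnitude_frames, dtype=float)
        self.phase_frames = np.asarray(self.phase_frames, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.magnitude_frames.shape != self.phase_frames.shape:
            raise UsageError("magnitude and phase stacks must share one shape")
        if self.magnitude_frames.ndim != 3:
            raise UsageError("frame stacks must be 3-D (frames, rows, cols)")
        if len(self.times_s) != self.n_frames:
            raise UsageError("times_s length must equal the frame count")
        if self.baseline_frame_count < 1:
            raise UsageError("baseline_frame_count must be >= 1")
        if self.n_frames < self.baseline_frame_count + 1:
            raise UsageError(
                "series needs at least baseline_frame_count + 1 frames"
            )

    @property
    def n_frames(self) -> int:
        return self.magnitude_frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.magnitude_frames.shape[1:]


@dataclass
class TemperatureSeries:
    """Per-frame temperature-difference maps relative to the baseline state.

    ``delta_t_frames[k]`` is the pixelwise temperature change (degC) of frame
    k from the pre-heating baseline; ``baseline_temp_C`` is the absolute
    temperature of that baseline state so that absolute temperature is
    ``baseline_temp_C + delta_t_frames``.
    """

    delta_t_frames: np.ndarray
    times_s: np.ndarray
    baseline_temp_C: float = 37.0

    def __post_init__(self) -> None:
        self.delta_t_frames = np.asarray(self.delta_t_frames, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.delta_t_frames.ndim != 3:
            raise UsageError("delta_t_frames must be 3-D (frames, rows, cols)")
        if len(self.times_s) != self.delta_t_frames.shape[0]:
            raise UsageError("times_s length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return self.delta_t_frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.delta_t_frames.shape[1:]

    def frame_interval_s(self) -> float:
        """Median frame spacing in seconds."""
        if self.n_frames < 2:
            raise UsageError("need at least two frames for a frame interval")
        return float(np.median(np.diff(self.times_s)))


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Map phase values into the half-open interval (-pi, pi]."""
    w = np.mod(phi, TWO_PI)
    return np.where(w > np.pi, w - TWO_PI, w)


def unwrap_temporal(phase_stack: np.ndarray) -> np.ndarray:
    """Temporally unwrap a stack of phase rasters.

    Frame-to-frame increments are wrapped into (-pi, pi] and cumulatively
    summed per pixel; the first frame is returned unchanged.  This assumes
    the true per-frame phase step never exceeds pi in magnitude, which holds
    whenever heating between consecutive dynamics stays below ~50 degC at
    the default acquisition settings.
    """
    phase_stack = np.asarray(phase_stack, dtype=float)
    if phase_stack.shape[0] < 2:
        raise UsageError("temporal unwrapping needs at least 2 frames")
    steps = wrap_phase(np.diff(phase_stack, axis=0))
    out = np.empty_like(phase_stack)
    out[0] = phase_stack[0]
    np.cumsum(steps, axis=0, out=out[1:])
    out[1:] += phase_stack[0]
    return out


def prf_rad_per_C(acq: AcquisitionParams, prf_coeff_ppm_per_C: float) -> float:
    """Phase shift per degC of heating (rad/degC) for an acquisition."""
    if acq.te_s <= 0 or acq.b0_tesla <= 0:
        raise ConfigurationError("TE and B0 must be positive for PRF inversion")
    if prf_coeff_ppm_per_C == 0:
        raise ConfigurationError("PRF coefficient must be non-zero")
    return (
        TWO_PI
        * GYROMAGNETIC_RATIO_HZ_PER_T
        * acq.b0_tesla
        * prf_coeff_ppm_per_C
        * 1e-6
        * acq.te_s
    )


def reconstruct_delta_t(
    series: DynamicSeries,
    prf_coeff_ppm_per_C: float = DEFAULT_PRF_COEFF_PPM_PER_C,
    baseline_temp_C: float = 37.0,
) -> TemperatureSeries:
    """Reconstruct temperature-difference maps from a dynamic series.

    The phase baseline is the circular mean of the first
    ``series.baseline_frame_count`` phase frames.  Each frame's phase
    difference from that baseline is formed as the angle of the complex
    ratio (which is free of wrap seams at +/-pi), temporally unwrapped, and
    divided by the PRF phase sensitivity.  With the conventional negative
    PRF coefficient, heating produces positive temperature change.

    Parameters
    ----------
    series : DynamicSeries
        Input magnitude/phase series.
    prf_coeff_ppm_per_C : float
        PRF temperature coefficient in ppm/degC (default -0.01).
    baseline_temp_C : float
        Absolute temperature of the baseline state (degC), carried through
        so dose integration can form absolute temperatures.
    """
    scale = prf_rad_per_C(series.acq, prf_coeff_ppm_per_C)
    n_base = series.baseline_frame_count
    # Circular mean of the baseline phase frames: mean unit phasor.
    baseline_phasor = np.exp(1j * series.phase_frames[:n_base]).mean(axis=0)
    dphi = np.angle(np.exp(1j * series.phase_frames) * np.conj(baseline_phasor))
    dphi = unwrap_temporal(dphi)
    delta_t = dphi / scale
    return TemperatureSeries(
        delta_t_frames=delta_t,
        times_s=series.times_s.copy(),
        baseline_temp_C=baseline_temp_C,
    )
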