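"""CEM43 thermal dose accumulation and critical-area quantification.

The cumulative equivalent minutes at 43 degC (CEM43) metric converts an
arbitrary temperature history T(t) into the exposure time at 43 degC that
would produce equivalent thermal damage:

    CEM43 = sum_frames  dt_min * R ** (43 - T)

with R = 0.5 for T >= 43 degC and R = 0.25 below the breakpoint; no dose is
accrued below a 39 degC floor.  Tissue with CEM43 above ~120 min is
considered thermally damaged for most tissues including renal parenchyma;
the area of pixels exceeding that threshold is the primary readout of a
heating experiment, together with the hottest pixel's temperature curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams
from .errors import ConfigurationError, DataError
from .preprocess import PixelMask
from .thermometry import TemperatureSeries


@dataclass(frozen=True)
class DoseParams:
    """Constants of the CEM43 dose model and the damage threshold."""

    t_break_C: float = 43.0
    r_above: float = 0.5
    r_below: float = 0.25
    t_floor_C: float = 39.0
    threshold_min: float = 120.0

    def __post_init__(self) -> None:
        if not (0 < self.r_above < 1) or not (0 < self.r_below < 1):
            raise ConfigurationError("R values must lie in (0, 1)")
        if self.t_floor_C > self.t_break_C:
            raise ConfigurationError("t_floor_C must not exceed t_break_C")
        if self.threshold_min <= 0:
            raise ConfigurationError("threshold_min must be > 0")


@dataclass
class DoseMap:
    """Per-pixel cumulative equivalent minutes at 43 degC."""

    cem43_min: np.ndarray
    pixel_area_mm2: float

    def __post_init__(self) -> None:
        self.cem43_min = np.asarray(self.cem43_min, dtype=float)


@dataclass
class CriticalAreaResult:
    """Area above the critical dose threshold and the hottest pixel."""

    area_mm2: float
    n_pixels: int
    hottest_pixel: tuple[int, int] | None
    hottest_curve: np.ndarray | None
    max_delta_t_C: float
    qc_flag: str = ""


def pixel_area(acq: AcquisitionParams) -> float:
    """In-plane area per pixel in mm^2: (FOV_r/N_r) * (FOV_c/N_c)."""
    if any(m <= 0 for m in acq.matrix):
        raise ConfigurationError("matrix dimensions must be positive")
    return (acq.fov_mm[0] / acq.matrix[0]) * (acq.fov_mm[1] / acq.matrix[1])


def cem43(
    temps: TemperatureSeries,
    mask: PixelMask,
    params: DoseParams = DoseParams(),
    pixel_area_mm2: float = 1.0,
) -> DoseMap:
    """Accumulate the CEM43 dose map over all frames of a series.

    Absolute temperature per frame is ``temps.baseline_temp_C +
    delta_t_frames``.  Each frame contributes ``dt_min * R**(t_break - T)``
    per kept pixel, where dt_min is the frame interval in minutes, R is
    ``r_above`` at or above the breakpoint and ``r_below`` between the
    floor and the breakpoint; temperatures below ``t_floor_C`` contribute
    nothing.  Excluded pixels carry dose 0.
    """
    keep = mask.keep
    dt_min = temps.frame_interval_s() / 60.0
    t_abs = temps.baseline_temp_C + temps.delta_t_frames

    bad = ~np.isfinite(t_abs) & keep[None, :, :]
    if bad.any():
        f, r, c = np.argwhere(bad)[0]
        raise DataError(
            f"non-finite temperature at kept pixel ({r}, {c}) in frame {f}"
        )

    t_abs = np.where(np.isfinite(t_abs), t_abs, -np.inf)
    above = t_abs >= params.t_break_C
    warm = (t_abs >= params.t_floor_C) & ~above
    contrib = np.zeros_like(t_abs)
    contrib[above] = params.r_above ** (params.t_break_C - t_abs[above])
    contrib[warm] = params.r_below ** (params.t_break_C - t_abs[warm])
    dose = dt_min * contrib.sum(axis=0)
    dose[~keep] = 0.0
    return DoseMap(cem43_min=dose, pixel_area_mm2=pixel_area_mm2)


def critical_area(
    dose: DoseMap,
    temps: TemperatureSeries,
    mask: PixelMask,
    params: DoseParams = DoseParams(),
) -> CriticalAreaResult:
    """Sum the area of kept pixels whose dose strictly exceeds the threshold.

    Also locates the hottest kept pixel — the argmax over kept pixels of the
    maximum temperature difference over time, ties broken in row-major
    order — and extracts its temperature curve.
    """
    keep = mask.keep
    hot = keep & (dose.cem43_min > params.threshold_min)
    n_pix = int(hot.sum())
    area = n_pix * dose.pixel_area_mm2

    if not keep.any():
        return CriticalAreaResult(
            area_mm2=0.0,
            n_pixels=0,
            hottest_pixel=None,
            hottest_curve=None,
            max_delta_t_C=float("nan"),
            qc_flag="empty-mask",
        )
    finite = np.where(
        np.isfinite(temps.delta_t_frames), temps.delta_t_frames, -np.inf
    )
    peak = np.where(keep, finite.max(axis=0), -np.inf)
    idx = np.unravel_index(int(np.argmax(peak)), peak.shape)
    curve = temps.delta_t_frames[:, idx[0], idx[1]].copy()
    return CriticalAreaResult(
        area_mm2=float(area),
        n_pixels=n_pix,
        hottest_pixel=(int(idx[0]), int(idx[1])),
        hottest_curve=curve,
        max_delta_t_C=float(peak[idx]),
    )
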