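"""MR acquisition geometry and timing.

The dynamic thermometry scan is a single-slice gradient-echo (segmented EPI)
series; the parameters here are everything the temperature reconstruction and
the dose integration need to know about it: echo time (phase sensitivity),
field strength, field-of-view and matrix (pixel area) and the time per
dynamic frame (dose integration step).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

#: Gyromagnetic ratio of the proton, Hz/T.
GYROMAGNETIC_RATIO_HZ_PER_T = 42.577e6

#: Temperature coefficient of the water proton resonance frequency, ppm/degC.
#: Literature-standard value; heating lowers the resonance frequency.
DEFAULT_PRF_COEFF_PPM_PER_C = -0.01


@dataclass(frozen=True)
class AcquisitionParams:
    """Geometry and timing of a dynamic gradient-echo thermometry series.

    Parameters
    ----------
    te_s : float
        Echo time TE in seconds. The PRF phase shift is proportional to TE.
    tr_s : float
        Repetition time TR in seconds (informational; dose uses the frame
        interval, not TR).
    flip_deg : float
        Excitation flip angle in degrees.
    slice_mm : float
        Slice thickness in mm.
    fov_mm : tuple
        In-plane field-of-view (row extent, column extent) in mm.
    matrix : tuple
        Acquisition matrix (rows, columns).
    frame_interval_s : float
        Acquisition time per dynamic image (TA) in seconds; the temporal
        sampling step of the temperature series.
    b0_tesla : float
        Static field strength in tesla.
    """

    te_s: float = 0.015
    tr_s: float = 0.031
    flip_deg: float = 13.0
    slice_mm: float = 4.0
    fov_mm: tuple[float, float] = (235.0, 259.0)
    matrix: tuple[int, int] = (174, 192)
    frame_interval_s: float = 0.62
    b0_tesla: float = 1.5

    def __post_init__(self) -> None:
        if self.te_s <= 0:
            raise ConfigurationError("te_s must be positive")
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be positive")
        if any(m < 8 for m in self.matrix):
            raise ConfigurationError("matrix dimensions must be >= 8")
        if any(f <= 0 for f in self.fov_mm):
            raise ConfigurationError("fov_mm must be positive")
        if self.b0_tesla <= 0:
            raise ConfigurationError("b0_tesla must be positive")

    @property
    def pixel_mm(self) -> tuple[float, float]:
        """In-plane pixel edge lengths (row, column) in mm."""
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])


def default_acquisition() -> AcquisitionParams:
    """The 1.5 T single-slice protocol used for kidney thermometry.

    TR = 31 ms, TE = 15 ms, flip 13 deg, slice 4 mm, FOV 235 x 259 mm^2,
    matrix 174 x 192 (1.82 mm^2 per pixel), 620 ms per dynamic frame.
    """
    return AcquisitionParams()
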