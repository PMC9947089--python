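"""Pixel exclusion and spatial smoothing of temperature maps.

Two exclusion rules are applied before dose accumulation, mirroring common
practice in interventional MR thermometry of low-SNR, flow-contaminated
scenes: (1) a magnitude noise threshold — pixels whose mean baseline signal
S falls below ``factor * S_air`` (default factor 3.7, with S_air the mean
signal in an air region outside the bath) are phase noise and are removed;
(2) a manually drawn kidney region of interest restricts the analysis to
parenchyma and collecting system.  A mask-aware 3x3 averaging filter then
reduces residual phase noise on the temperature maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import UsageError
from .thermometry import TemperatureSeries

DEFAULT_NOISE_FACTOR = 3.7


@dataclass
class PixelMask:
    """Boolean keep-raster with a record of which rules removed how much."""

    keep: np.ndarray
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


@dataclass
class RoiSpec:
    """A region of interest: a polygon (pixel coordinates) or a raster.

    Polygon vertices are ordered (row, col) pairs in the image frame, where
    pixel (i, j) has its centre at coordinates (i, j).  A raster ROI is a
    boolean array of the frame shape.
    """

    vertices: np.ndarray | None = None
    raster: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.vertices is None) == (self.raster is None):
            raise UsageError("RoiSpec needs exactly one of vertices or raster")
        if self.vertices is not None:
            self.vertices = np.asarray(self.vertices, dtype=float)
            if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
                raise UsageError("polygon vertices must be an (n, 2) array")
            if len(self.vertices) < 3:
                raise UsageError("polygon ROI needs at least 3 vertices")
        if self.raster is not None:
            self.raster = np.asarray(self.raster, dtype=bool)

    @classmethod
    def from_polygon(cls, vertices) -> "RoiSpec":
        return cls(vertices=np.asarray(vertices, dtype=float))

    @classmethod
    def from_raster(cls, raster) -> "RoiSpec":
        return cls(raster=np.asarray(raster, dtype=bool))

    def polygon_area(self) -> float:
        """Shoelace area of a polygon ROI (0 for raster ROIs)."""
        if self.vertices is None:
            return float(self.raster.sum())
        r = self.vertices[:, 0]
        c = self.vertices[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize: pixels whose centres lie inside (even-odd rule)."""
        if self.raster is not None:
            if self.raster.shape != tuple(shape):
                raise UsageError("raster ROI shape must match the frame shape")
            return self.raster.copy()
        if self.polygon_area() == 0:
            raise UsageError("degenerate polygon ROI (zero area)")
        return _polygon_to_mask(self.vertices, shape)


def _polygon_to_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization at pixel centres (vectorized ray casting)."""
    rows, cols = shape
    pr = np.arange(rows, dtype=float)[:, None]  # centre row coords
    pc = np.arange(cols, dtype=float)[None, :]
    inside = np.zeros(shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        if r1 == r2:
            continue  # horizontal edge never crosses the horizontal ray
        crosses = (r1 > pr) != (r2 > pr)
        c_at = c1 + (pr - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (pc < c_at)
    return inside


def noise_mask(
    magnitude_frames: np.ndarray,
    air_roi: RoiSpec,
    factor: float = DEFAULT_NOISE_FACTOR,
) -> PixelMask:
    """Remove low-SNR pixels by the magnitude threshold S < factor * S_air.

    ``magnitude_frames`` are the baseline magnitude frames (a 2-D image or a
    stack, averaged over frames); ``S_air`` is the mean magnitude over the
    air ROI.  Pixels strictly below ``factor * S_air`` are removed; pixels
    at or above it are kept.
    """
    if factor <= 0:
        raise UsageError("noise factor must be > 0")
    mag = np.asarray(magnitude_frames, dtype=float)
    if mag.ndim == 3:
        mag = mag.mean(axis=0)
    air = air_roi.to_mask(mag.shape)
    if not air.any():
        raise UsageError("air ROI is empty")
    s_air = float(mag[air].mean())
    keep = mag >= factor * s_air
    return PixelMask(
        keep=keep, provenance={"noise": int(keep.size - keep.sum())}
    )


def apply_roi(mask: PixelMask, roi: RoiSpec) -> PixelMask:
    """Restrict a mask to a region of interest (logical AND)."""
    roi_mask = roi.to_mask(mask.keep.shape)
    keep = mask.keep & roi_mask
    provenance = dict(mask.provenance)
    provenance["roi"] = provenance.get("roi", 0) + int(mask.keep.sum() - keep.sum())
    return PixelMask(keep=keep, provenance=provenance)


def smooth(
    delta_t: TemperatureSeries, mask: PixelMask, width: int = 3
) -> TemperatureSeries:
    """Mask-aware box filter on each temperature frame.

    Each kept pixel becomes the mean of the kept pixels in its
    ``width x width`` neighbourhood; excluded pixels contribute nothing and
    stay excluded (NaN in the output).  At the image border the
    neighbourhood is truncated to in-frame pixels, so no zero-padding bias
    is introduced at the lesion rim.
    """
    if width % 2 == 0 or width < 1:
        raise UsageError("smoothing width must be odd and >= 1")
    keep = mask.keep
    if keep.shape != delta_t.frame_shape:
        raise UsageError("mask shape must match the frame shape")
    kernel = np.ones((width, width))
    counts = ndimage.correlate(keep.astype(float), kernel, mode="constant", cval=0.0)
    out = np.full_like(delta_t.delta_t_frames, np.nan)
    for k in range(delta_t.n_frames):
        vals = np.where(keep, delta_t.delta_t_frames[k], 0.0)
        sums = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frame = sums / counts
        out[k] = np.where(keep, frame, np.nan)
    return TemperatureSeries(
        delta_t_frames=out,
        times_s=delta_t.times_s.copy(),
        baseline_temp_C=delta_t.baseline_temp_C,
    )
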