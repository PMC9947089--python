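import numpy as np
import pytest

from thermodose import AcquisitionParams, ThermalSceneConfig


@pytest.fixture
def small_acq() -> AcquisitionParams:
    """16x16 acquisition with the standard timing/field parameters."""
    return AcquisitionParams(matrix=(16, 16), fov_mm=(21.6, 21.6))


@pytest.fixture
def tiny_scene_factory():
    """Factory for a 16x16 disk-cavity scene (fast to simulate)."""

    def make(
        grid: int = 16,
        amplitude: float = 3.0,
        mixed: float = 1.0,
        irrigation: float = 10.0,
        **kwargs,
    ) -> ThermalSceneConfig:
        rr, cc = np.indices((grid, grid))
        dist = np.hypot(rr - grid // 2, cc - grid // 2)
        cavity = dist <= grid / 5
        tissue = (dist > grid / 5) & (dist <= 2 * grid / 5)
        params = dict(
            grid_shape=(grid, grid),
            pixel_mm=(1.35, 1.35),
            cavity_mask=cavity,
            tissue_mask=tissue,
            source_position=(grid // 2, grid // 2),
            source_amplitude_K_per_s=amplitude,
            mixed_amplitude_K_per_s=mixed,
            irrigation_ml_per_min=irrigation,
        )
        params.update(kwargs)
        return ThermalSceneConfig(**params)

    return make
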