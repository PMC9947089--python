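"""End-to-end experiment orchestration and parameter sweeps.

An experiment runs the full chain

    (simulate + encode | read DICOM) -> reconstruct -> noise mask -> kidney
    ROI -> smooth -> CEM43 -> critical area

under a single configuration object, writes the dose map, a summary CSV row
and a JSON provenance record, and is bit-reproducible for a fixed
configuration.  Sweeps iterate the chain over a grid of laser powers, pulse
protocols, irrigation rates and fiber-site presets with deterministic
per-cell seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acquisition import DEFAULT_PRF_COEFF_PPM_PER_C, AcquisitionParams
from .dose import CriticalAreaResult, DoseMap, DoseParams, cem43, critical_area, pixel_area
from .errors import ConfigurationError, DataError
from .io import read_dicom_series, write_map_tiff
from .preprocess import (
    DEFAULT_NOISE_FACTOR,
    PixelMask,
    RoiSpec,
    apply_roi,
    noise_mask,
    smooth,
)
from .synthetic import (
    LaserProtocol,
    ThermalSceneConfig,
    acquisition_for_scene,
    encode_mr_series,
    scene_preset,
    simulate_temperature,
)
from .thermometry import DynamicSeries, TemperatureSeries, reconstruct_delta_t

logger = logging.getLogger("thermodose")

SUMMARY_COLUMNS = [
    "run_id",
    "power_W",
    "t_on_s",
    "t_off_s",
    "irrigation_ml_min",
    "fiber_site",
    "area_mm2",
    "n_pixels",
    "max_delta_t_C",
    "hottest_row",
    "hottest_col",
    "qc_flag",
]


@dataclass
class SimulationSource:
    """Generate the input series by forward simulation + MR encoding."""

    protocol: LaserProtocol
    scene: ThermalSceneConfig
    acq: AcquisitionParams | None = None
    seed: int = 0
    noise_sd: float = 2.0
    duration_s: float | None = None
    start_delay_s: float = 3.1
    air_margin_px: int = 6
    fiber_site: str = ""

    def resolved_acq(self) -> AcquisitionParams:
        return self.acq if self.acq is not None else acquisition_for_scene(self.scene)

    def resolved_duration(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        return self.start_delay_s + self.protocol.total_time_s + 30.0


@dataclass
class DicomSource:
    """Load the input series from a directory of magnitude/phase DICOMs."""

    directory: str | Path
    baseline_frame_count: int | None = None


@dataclass
class ExperimentConfig:
    """Everything needed to run (and re-run) one experiment."""

    run_id: str
    source: SimulationSource | DicomSource
    air_roi: RoiSpec | None = None
    kidney_roi: RoiSpec | None = None
    dose_params: DoseParams = field(default_factory=DoseParams)
    prf_coeff_ppm_per_C: float = DEFAULT_PRF_COEFF_PPM_PER_C
    baseline_temp_C: float = 37.0
    noise_factor: float = DEFAULT_NOISE_FACTOR
    smooth_enabled: bool = True
    smooth_width: int = 3
    output_dir: str | Path | None = None
    qc_excluded: bool = False
    qc_reason: str = ""


@dataclass
class ExperimentResult:
    """Artifacts of one pipeline run."""

    result: CriticalAreaResult
    dose_map: DoseMap
    mask: PixelMask
    temps: TemperatureSeries
    summary_row: dict


@dataclass
class SweepSpec:
    """A factorial grid of heating experiments."""

    powers_W: list[float]
    protocols: list[LaserProtocol]
    irrigation_rates_ml_min: list[float]
    fiber_sites: list[str] = field(default_factory=lambda: ["calyx"])
    replicates: int = 3
    base_seed: int = 0
    grid_shape: tuple[int, int] = (64, 64)
    noise_sd: float = 2.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        for name in ("powers_W", "protocols", "irrigation_rates_ml_min", "fiber_sites"):
            if not getattr(self, name):
                raise ConfigurationError(f"{name} must be non-empty")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")


def _border_roi(shape: tuple[int, int], margin: int) -> RoiSpec:
    raster = np.ones(shape, dtype=bool)
    if margin > 0:
        raster[margin:-margin, margin:-margin] = False
    return RoiSpec.from_raster(raster)


def _default_kidney_roi(source: SimulationSource, shape: tuple[int, int]) -> RoiSpec:
    scene = source.scene
    raster = scene.cavity_mask | scene.tissue_mask
    if raster.shape != tuple(shape):
        from scipy import ndimage

        zr = shape[0] / raster.shape[0]
        zc = shape[1] / raster.shape[1]
        raster = ndimage.zoom(raster.astype(float), (zr, zc), order=0) > 0.5
    # stay clear of the synthetic air border
    m = source.air_margin_px
    if m > 0:
        raster = raster.copy()
        raster[:m, :] = raster[-m:, :] = False
        raster[:, :m] = raster[:, -m:] = False
    return RoiSpec.from_raster(raster)


def _load_series(config: ExperimentConfig) -> DynamicSeries:
    src = config.source
    if isinstance(src, DicomSource):
        return read_dicom_series(src.directory, src.baseline_frame_count)
    truth = simulate_temperature(
        src.protocol,
        src.scene,
        src.resolved_duration(),
        frame_interval_s=src.resolved_acq().frame_interval_s,
        start_delay_s=src.start_delay_s,
    )
    return encode_mr_series(
        truth,
        src.resolved_acq(),
        prf_coeff_ppm_per_C=config.prf_coeff_ppm_per_C,
        noise_sd=src.noise_sd,
        air_margin_px=src.air_margin_px,
        seed=src.seed,
    )


def _provenance(config: ExperimentConfig, series: DynamicSeries) -> dict:
    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(series.magnitude_frames).tobytes())
    digest.update(np.ascontiguousarray(series.phase_frames).tobytes())

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return {"shape": list(obj.shape), "dtype": str(obj.dtype)}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return {
        "software": {"name": "thermodose", "version": __version__},
        "config": _clean(asdict(config)),
        "input_sha256": digest.hexdigest(),
    }


def run_experiment(config: ExperimentConfig) -> ExperimentResult | None:
    """Run the full analysis chain for one experiment.

    Returns ``None`` for configurations flagged ``qc_excluded`` (the run is
    skipped with a logged reason, mirroring runs lost to imaging
    artifacts).  Otherwise returns the critical-area result plus all
    intermediate artifacts, writing the dose map (float TIFF), a summary
    CSV row and a JSON provenance record when ``output_dir`` is set.
    """
    if config.qc_excluded:
        logger.warning("run %s skipped (QC): %s", config.run_id, config.qc_reason)
        if config.output_dir is not None:
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / f"{config.run_id}_skipped.json").write_text(
                json.dumps({"run_id": config.run_id, "qc_reason": config.qc_reason})
            )
        return None

    series = _load_series(config)
    shape = series.frame_shape
    temps = reconstruct_delta_t(
        series,
        prf_coeff_ppm_per_C=config.prf_coeff_ppm_per_C,
        baseline_temp_C=config.baseline_temp_C,
    )

    air_roi = config.air_roi
    kidney_roi = config.kidney_roi
    if isinstance(config.source, SimulationSource):
        if air_roi is None:
            air_roi = _border_roi(shape, max(1, config.source.air_margin_px - 1))
        if kidney_roi is None:
            kidney_roi = _default_kidney_roi(config.source, shape)
    if air_roi is None or kidney_roi is None:
        raise ConfigurationError("DICOM sources require explicit air and kidney ROIs")

    baseline_mag = series.magnitude_frames[: series.baseline_frame_count]
    mask = noise_mask(baseline_mag, air_roi, factor=config.noise_factor)
    mask = apply_roi(mask, kidney_roi)
    if config.smooth_enabled:
        temps = smooth(temps, mask, width=config.smooth_width)

    params = config.dose_params
    area_mm2 = pixel_area(series.acq)
    dose_map = cem43(temps, mask, params, pixel_area_mm2=area_mm2)
    result = critical_area(dose_map, temps, mask, params)

    row = {
        "run_id": config.run_id,
        "power_W": np.nan,
        "t_on_s": np.nan,
        "t_off_s": np.nan,
        "irrigation_ml_min": np.nan,
        "fiber_site": "",
        "area_mm2": result.area_mm2,
        "n_pixels": result.n_pixels,
        "max_delta_t_C": result.max_delta_t_C,
        "hottest_row": result.hottest_pixel[0] if result.hottest_pixel else -1,
        "hottest_col": result.hottest_pixel[1] if result.hottest_pixel else -1,
        "qc_flag": result.qc_flag,
    }
    if isinstance(config.source, SimulationSource):
        src = config.source
        row.update(
            power_W=src.protocol.power_watts,
            t_on_s=src.protocol.t_on_s,
            t_off_s=src.protocol.t_off_s,
            irrigation_ml_min=src.scene.irrigation_ml_per_min,
            fiber_site=src.fiber_site,
        )

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_map_tiff(dose_map.cem43_min, out / f"{config.run_id}_cem43.tif")
        summary_path = out / "summary.csv"
        df = pd.DataFrame([row], columns=SUMMARY_COLUMNS)
        df.to_csv(
            summary_path,
            mode="a",
            header=not summary_path.exists(),
            index=False,
        )
        (out / f"{config.run_id}_provenance.json").write_text(
            json.dumps(_provenance(config, series), indent=2)
        )
    return ExperimentResult(
        result=result, dose_map=dose_map, mask=mask, temps=temps, summary_row=row
    )


def cell_seed(base_seed: int, power: float, protocol: LaserProtocol,
              irrigation: float, site: str, replicate: int) -> int:
    """Deterministic per-cell seed: stable across partial reruns."""
    key = (
        f"{power}|{protocol.t_on_s}|{protocol.t_off_s}|"
        f"{protocol.n_applications}|{irrigation}|{site}|{replicate}"
    )
    return (base_seed + zlib.crc32(key.encode())) % (2**31 - 1)


def run_sweep(
    spec: SweepSpec, output_dir: str | Path | None = None
) -> pd.DataFrame:
    """Run the full factorial grid and return the long-format result table.

    One row per (power, protocol, irrigation, site, replicate).  Cell
    failures are recorded in the row's ``qc_flag`` and the sweep continues.
    When ``output_dir`` is given, writes ``sweep_long.csv`` and a pivoted
    mean +/- SD table ``sweep_summary.csv``.
    """
    rows = []
    for site in spec.fiber_sites:
        for power in spec.powers_W:
            for protocol in spec.protocols:
                protocol = replace(protocol, power_watts=power)
                for irr in spec.irrigation_rates_ml_min:
                    for rep in range(spec.replicates):
                        seed = cell_seed(spec.base_seed, power, protocol, irr,
                                         site, rep)
                        scene = scene_preset(site, power, irr,
                                             grid_shape=spec.grid_shape)
                        run_id = (
                            f"{site}_{power:g}W_{protocol.t_on_s:g}-"
                            f"{protocol.t_off_s:g}s_{irr:g}ml_r{rep}"
                        )
                        config = ExperimentConfig(
                            run_id=run_id,
                            source=SimulationSource(
                                protocol=protocol,
                                scene=scene,
                                seed=seed,
                                noise_sd=spec.noise_sd,
                                duration_s=spec.duration_s,
                                fiber_site=site,
                            ),
                            output_dir=output_dir,
                        )
                        try:
                            res = run_experiment(config)
                        except (ConfigurationError, DataError) as exc:
                            logger.error("cell %s failed: %s", run_id, exc)
                            rows.append(
                                {
                                    "run_id": run_id,
                                    "power_W": power,
                                    "t_on_s": protocol.t_on_s,
                                    "t_off_s": protocol.t_off_s,
                                    "irrigation_ml_min": irr,
                                    "fiber_site": site,
                                    "area_mm2": np.nan,
                                    "n_pixels": -1,
                                    "max_delta_t_C": np.nan,
                                    "hottest_row": -1,
                                    "hottest_col": -1,
                                    "qc_flag": f"error: {exc}",
                                    "replicate": rep,
                                    "seed": seed,
                                }
                            )
                            continue
                        row = dict(res.summary_row)
                        row["replicate"] = rep
                        row["seed"] = seed
                        rows.append(row)
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS + ["replicate", "seed"])
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sweep_long.csv", index=False)
        summarize_sweep(df).to_csv(out / "sweep_summary.csv")
    return df


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a sweep table to mean +/- SD of the critical area per cell.

    Rows: (site, power, protocol); columns: irrigation rate — the layout of
    a critical-area summary table.
    """
    g = df.groupby(["fiber_site", "power_W", "t_on_s", "t_off_s",
                    "irrigation_ml_min"])["area_mm2"]
    stats = g.agg(["mean", "std"]).reset_index()
    pivot = stats.pivot_table(
        index=["fiber_site", "power_W", "t_on_s", "t_off_s"],
        columns="irrigation_ml_min",
        values=["mean", "std"],
    )
    return pivot
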