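"""End-to-end orchestration: simulate -> mask -> classify -> unmix ->
aggregate -> trend/heatwave statistics.

All randomness flows from ``PipelineConfig.seed`` through
``numpy.random.SeedSequence``; identical configurations produce
byte-identical CSV outputs.  Each stage logs the counts the filtering rules
act on (pixels masked, kelp pixels, cells excluded, missing years) so a run
is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import classify as cls_mod
from . import masking, trends, unmix
from .io import PipelineConfig, write_cells
from .scene import OLI, SEAWATER, TM_ETM, Scene, SceneTruth
from .simulate import (
    DynamicsConfig,
    SimulatedAcquisition,
    SimulatedDomain,
    generate_scene,
    generate_scene_series,
    generate_spectral_library,
    make_domain,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "dynamics_from_config"]


@dataclass
class PipelineResult:
    """In-memory products of a full run (CSV files mirror the frames)."""

    config: PipelineConfig
    domain: SimulatedDomain
    trajectory: pd.DataFrame
    habitat: np.ndarray
    quarterly: pd.DataFrame
    annual: pd.DataFrame
    regional: pd.DataFrame
    cell_stats: pd.DataFrame
    regional_stats: pd.DataFrame
    tidal_flags: pd.DataFrame
    log_counts: dict = field(default_factory=dict)
    fraction_rasters: list = field(default_factory=list)
    class_rasters: list = field(default_factory=list)
    acquisitions: list = field(default_factory=list)


def dynamics_from_config(config: PipelineConfig) -> DynamicsConfig:
    return DynamicsConfig(
        n_years=config.n_years,
        start_year=config.start_year,
        trend=config.trend,
        ar_order=len(config.ar_coefficients),
        ar_coefficients=config.ar_coefficients,
        noise_sd=config.noise_sd,
        oscillation_period=config.oscillation_period,
        oscillation_amplitude=config.oscillation_amplitude,
        heatwave_years=config.event_years,
        heatwave_depth=config.heatwave_depth,
        recovery_years=config.recovery_years,
        recovery_level=config.recovery_level,
        acquisitions_per_quarter=config.acquisitions_per_quarter,
        cloud_coverage=config.cloud_coverage,
        scene_noise_sd=config.scene_noise_sd,
        peak_kelp_fraction=config.peak_kelp_fraction,
        seed=config.seed,
    )


def _reference_scene(domain: SimulatedDomain, library, seed: int) -> Scene:
    """Cloud-free negative-low-tide scene used to derive the intertidal mask."""
    truth = SceneTruth(
        kelp_fraction=np.zeros(domain.shape),
        class_map=np.where(
            domain.land, 3, np.where(domain.intertidal, 4, SEAWATER)
        ).astype(np.uint8),
        tide_height=-0.5,
        water_region=domain.water_region,
    )
    return generate_scene(truth, library, noise_sd=0.0, seed=seed, geometry=domain.geometry)


def _train_classifiers(acqs: list[SimulatedAcquisition], config: PipelineConfig):
    """One decision tree per sensor generation from truth-labelled samples."""
    out = {}
    for gen in (TM_ETM, OLI):
        subset = [a for a in acqs if a.scene.sensor_generation == gen]
        if not subset:
            continue
        # spread training scenes across the generation's time span; enough
        # scenes to sample the per-scene seawater variability
        n_train = min(12, len(subset))
        picks = [subset[i] for i in np.linspace(0, len(subset) - 1, n_train).astype(int)]
        X, y = cls_mod.build_training_set(
            [a.scene for a in picks],
            [a.truth for a in picks],
            n_samples=8000,
            k=config.kmeans_k,
            seed=config.seed,
        )
        out[gen] = cls_mod.train_decision_tree(
            X, y, gen, max_depth=config.tree_max_depth, seed=config.seed
        )
        logger.info(
            "classifier %s: training accuracy %.4f", gen, out[gen].training_accuracy
        )
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full chain on a synthetic archive defined by ``config``."""
    counts: dict = {}
    domain = make_domain(
        n_cells_x=config.n_cells_x,
        n_cells_y=config.n_cells_y,
        cell_px=config.cell_px,
        seed=config.seed,
    )
    library = generate_spectral_library(config.seed)
    dynamics = dynamics_from_config(config)
    acqs, traj = generate_scene_series(dynamics, domain, library)
    counts["n_acquisitions"] = len(acqs)

    land = masking.land_mask_from_dem(domain.dem)
    ref = _reference_scene(domain, library, seed=config.seed + 1)
    intertidal = masking.intertidal_mask(ref, land_mask=land, threshold=config.mndwi_threshold)
    counts["n_land_pixels"] = int(land.sum())
    counts["n_intertidal_pixels"] = int(intertidal.sum())

    classifiers = _train_classifiers(acqs, config)

    ss = np.random.SeedSequence([config.seed, 77])
    em_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(acqs))]
    kelp_em = library.kelp_endmember[: unmix.N_UNMIX]

    fraction_rasters: list[np.ndarray] = []
    area_rasters: list[np.ndarray] = []
    class_rasters: list[np.ndarray] = []
    n_kelp_px = 0
    for i, acq in enumerate(acqs):
        cloud = masking.cloud_mask_from_qa(acq.scene.qa)
        class_raster = cls_mod.classify_scene(
            acq.scene, classifiers[acq.scene.sensor_generation],
            cloud_mask=cloud, land_mask=land, intertidal=intertidal,
        )
        masked = cloud | land | intertidal
        water_ems = unmix.select_seawater_endmembers(
            acq.scene, class_raster, n=config.n_seawater_endmembers, seed=em_seeds[i]
        )
        fraction = unmix.unmix_scene(acq.scene, class_raster, kelp_em, water_ems, masked=masked)
        area = unmix.fraction_to_area(fraction, config.pixel_area)
        n_kelp_px += int(np.nansum(fraction > 0))
        fraction_rasters.append(fraction)
        area_rasters.append(area)
        class_rasters.append(class_raster)
    counts["n_kelp_pixel_detections"] = n_kelp_px

    # seasonal per-pixel statistics
    stats_list = []
    key_order = []
    by_quarter: dict[tuple[int, int], list[np.ndarray]] = {}
    for acq, area in zip(acqs, area_rasters):
        key = (acq.year, acq.quarter)
        if key not in by_quarter:
            by_quarter[key] = []
            key_order.append(key)
        by_quarter[key].append(area)
    for year, quarter in key_order:
        stats_list.append(
            agg.seasonal_pixel_stats(by_quarter[(year, quarter)], year=year, quarter=quarter)
        )

    habitat = agg.derive_habitat_mask(fraction_rasters)
    counts["n_habitat_pixels"] = int(habitat.sum())
    retained, hab_counts = agg.filter_cells_by_habitat(
        domain.cells, habitat, domain.geometry, config.habitat_threshold
    )
    counts["n_cells_retained"] = len(retained)
    counts["n_cells_excluded"] = len(domain.cells) - len(retained)

    quarterly = agg.aggregate_cells(
        stats_list, retained, domain.geometry, habitat,
        max_unobserved_fraction=config.max_unobserved_fraction,
    )
    annual = agg.annual_max_table(quarterly)
    regions = {"all": [c.id for c in retained]}
    regional = agg.regional_annual(annual, regions, strict_missing=config.strict_regional_missing)
    counts["n_region_years_missing"] = int(regional["missing"].sum())

    # tide-sensitivity flags on land-adjacent pixels
    adjacency = masking.land_adjacency(land)
    area_stack = np.stack(area_rasters)
    tides = np.array([a.truth.tide_height for a in acqs])
    tidal_flags = masking.flag_tidal_pixels(area_stack, tides, adjacency)
    counts["n_tidal_flagged"] = int(tidal_flags["flagged"].sum()) if len(tidal_flags) else 0

    # per-cell statistics
    cell_rows = []
    for cell in retained:
        series = (
            annual[annual["cell_id"] == cell.id]
            .set_index("year")["area_m2"]
            .sort_index()
        )
        row = {"cell_id": cell.id, "latitude": cell.latitude,
               "habitat_pixels": hab_counts[cell.id]}
        try:
            fit = trends.fit_gls_ar(
                trends.normalize_by_max(series), orders=config.ar_orders
            )
            row.update(
                slope_pct_yr=fit.slope_pct_yr, stderr_pct_yr=fit.stderr_pct_yr,
                p_value=fit.p_value, ar_order=fit.ar_order,
            )
        except ValueError as exc:
            logger.warning("cell %s trend fit failed: %s", cell.id, exc)
            row.update(slope_pct_yr=np.nan, stderr_pct_yr=np.nan,
                       p_value=np.nan, ar_order=-1)
        for name, fn in (
            ("response_pct", trends.heatwave_response),
            ("recovery_pct", trends.heatwave_recovery),
            ("recent_pct", trends.recent_state),
        ):
            try:
                row[name] = fn(series, baseline_years=config.baseline_years)
            except ValueError:
                row[name] = np.nan
        cell_rows.append(row)
    cell_stats = pd.DataFrame(cell_rows)

    # regional statistics
    reg_rows = []
    for region in regions:
        series = (
            regional[regional["region"] == region]
            .set_index("year")["area_m2"]
            .sort_index()
        )
        row = {"region": region}
        try:
            fit = trends.fit_gls_ar(
                trends.normalize_by_max(series), orders=config.ar_orders
            )
            row.update(
                slope_pct_yr=fit.slope_pct_yr, stderr_pct_yr=fit.stderr_pct_yr,
                p_value=fit.p_value, ar_order=fit.ar_order, n_years=fit.n_years,
            )
        except ValueError as exc:
            logger.warning("region %s trend fit failed: %s", region, exc)
            row.update(slope_pct_yr=np.nan, stderr_pct_yr=np.nan,
                       p_value=np.nan, ar_order=-1, n_years=len(series))
        for name, fn in (
            ("response_pct", trends.heatwave_response),
            ("recovery_pct", trends.heatwave_recovery),
            ("recent_pct", trends.recent_state),
        ):
            try:
                row[name] = fn(series, baseline_years=config.baseline_years)
            except ValueError:
                row[name] = np.nan
        resp = cell_stats["response_pct"].to_numpy()
        if np.isfinite(resp).sum() >= 3:
            corr = trends.latitude_correlation(resp, cell_stats["latitude"].to_numpy())
            row["latitude_r"] = corr.r
            row["latitude_p"] = corr.p_value
        reg_rows.append(row)
    regional_stats = pd.DataFrame(reg_rows)

    result = PipelineResult(
        config=config,
        domain=domain,
        trajectory=traj,
        habitat=habitat,
        quarterly=quarterly,
        annual=annual,
        regional=regional,
        cell_stats=cell_stats,
        regional_stats=regional_stats,
        tidal_flags=tidal_flags,
        log_counts=counts,
        fraction_rasters=fraction_rasters,
        class_rasters=class_rasters,
        acquisitions=acqs,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": result.config.hash(),
        "seed": result.config.seed,
        "counts": result.log_counts,
    }
    for name in ("quarterly", "annual", "regional", "cell_stats",
                 "regional_stats", "tidal_flags", "trajectory"):
        frame: pd.DataFrame = getattr(result, name)
        frame.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.6f")
    write_cells(result.domain.cells, out_dir / "cells.geojson", result.domain.geometry)
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
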