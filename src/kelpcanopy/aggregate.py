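"""Seasonal statistics and zonal aggregation of canopy area.

The processing chain is: per-quarter per-pixel statistics over all
acquisitions (mean, standard error, overpass count), a habitat mask (pixels
where canopy was ever detected), summation into grid-cell polygons with a
cloud-cover missing-data rule, annual maxima per cell, and regional sums.

Missing-data rules (all strict inequalities):

* a cell-quarter is missing when **more than** 25% of the cell's habitat
  pixels had no cloud-free acquisition that quarter;
* a cell-year is missing when **two or more** of its quarters are missing;
* a region-year is missing when **more than half** of the region's cells
  were missing more than one quarter that year;
* cells with **fewer than** the habitat-pixel threshold (500 at the 10 km
  scale, 25 at the 1 km scale) are excluded outright.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CellPolygon",
    "SeasonalPixelStats",
    "seasonal_pixel_stats",
    "derive_habitat_mask",
    "cell_pixel_mask",
    "aggregate_cell_quarter",
    "aggregate_cells",
    "filter_cells_by_habitat",
    "annual_max",
    "annual_max_table",
    "regional_annual",
]


@dataclass
class CellPolygon:
    """Axis-aligned grid cell in projected metres (x0 < x1, y0 < y1)."""

    id: str
    x0: float
    y0: float
    x1: float
    y1: float
    nominal_size_m: float = 10_000.0
    latitude: float = 0.0

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"cell {self.id!r} is degenerate")


@dataclass
class SeasonalPixelStats:
    """Per-pixel quarterly canopy-area statistics."""

    year: int
    quarter: int
    mean_area: np.ndarray  # m^2; NaN where no cloud-free acquisition
    stderr: np.ndarray  # m^2; sample sd / sqrt(n); 0 when n == 1
    n_overpasses: np.ndarray  # int count of cloud-free acquisitions


def seasonal_pixel_stats(
    area_rasters: Sequence[np.ndarray], year: int = 0, quarter: int = 1
) -> SeasonalPixelStats:
    """Mean/SE/count per pixel over one quarter's acquisitions.

    ``area_rasters`` holds one canopy-area raster (m^2) per acquisition with
    NaN at pixels masked (cloud/land) in that acquisition.  A pixel with no
    cloud-free acquisition is missing (NaN mean, n = 0).
    """
    if len(area_rasters) == 0:
        raise ValueError("at least the raster shape is needed; got no rasters")
    stack = np.stack([np.asarray(a, dtype=float) for a in area_rasters])
    valid = ~np.isnan(stack)
    n = valid.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    mean = np.where(n >= 1, mean, np.nan)
    stderr = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    stderr = np.where(n >= 1, stderr, np.nan)
    return SeasonalPixelStats(
        year=year, quarter=quarter, mean_area=mean, stderr=stderr, n_overpasses=n
    )


def derive_habitat_mask(fraction_rasters: Iterable[np.ndarray]) -> np.ndarray:
    """Pixels where kelp fractional cover was ever positive in the series."""
    habitat: np.ndarray | None = None
    for f in fraction_rasters:
        f = np.asarray(f, dtype=float)
        seen = np.nan_to_num(f, nan=0.0) > 0
        habitat = seen if habitat is None else (habitat | seen)
    if habitat is None:
        raise ValueError("no rasters supplied")
    return habitat


def cell_pixel_mask(cell: CellPolygon, geometry, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centre falls in the half-open rectangle [x0,x1) x [y0,y1)."""
    x, y = geometry.pixel_centers(shape)
    return (x >= cell.x0) & (x < cell.x1) & (y >= cell.y0) & (y < cell.y1)


def aggregate_cell_quarter(
    stats: SeasonalPixelStats,
    cell_mask: np.ndarray,
    habitat: np.ndarray,
    max_unobserved_fraction: float = 0.25,
    denominator_mask: np.ndarray | None = None,
) -> dict:
    """Sum a cell's canopy area for one quarter, applying the cloud rule.

    The denominator of the unobserved fraction defaults to the cell's habitat
    pixels; pass ``denominator_mask`` (e.g. all water pixels) to change it.
    The cell is missing iff that fraction **exceeds** ``max_unobserved_fraction``
    (strict: exactly 25% unobserved is kept).
    """
    if not cell_mask.any():
        raise ValueError("cell does not overlap the raster")
    denom = cell_mask & (habitat if denominator_mask is None else denominator_mask)
    n_denom = int(denom.sum())
    unobserved = denom & (stats.n_overpasses == 0)
    cloud_fraction = float(unobserved.sum()) / n_denom if n_denom else 0.0
    missing = cloud_fraction > max_unobserved_fraction
    cell_hab = cell_mask & habitat
    if missing or not cell_hab.any():
        area = np.nan if missing else 0.0
        stderr = np.nan if missing else 0.0
    else:
        area = float(np.nansum(stats.mean_area[cell_hab]))
        stderr = float(np.sqrt(np.nansum(stats.stderr[cell_hab] ** 2)))
    n_mean = float(stats.n_overpasses[cell_hab].mean()) if cell_hab.any() else 0.0
    return {
        "year": stats.year,
        "quarter": stats.quarter,
        "area_m2": area,
        "stderr_m2": stderr,
        "n_overpasses": n_mean,
        "cloud_fraction": cloud_fraction,
        "missing": bool(missing),
    }


def aggregate_cells(
    stats_list: Sequence[SeasonalPixelStats],
    cells: Sequence[CellPolygon],
    geometry,
    habitat: np.ndarray,
    max_unobserved_fraction: float = 0.25,
    denominator_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Quarterly cell table over all quarters and cells (the interchange CSV)."""
    shape = habitat.shape
    masks = {c.id: cell_pixel_mask(c, geometry, shape) for c in cells}
    rows = []
    for stats in stats_list:
        for cell in cells:
            rec = aggregate_cell_quarter(
                stats,
                masks[cell.id],
                habitat,
                max_unobserved_fraction=max_unobserved_fraction,
                denominator_mask=denominator_mask,
            )
            rows.append({"cell_id": cell.id, **rec})
    return pd.DataFrame(rows)


def filter_cells_by_habitat(
    cells: Sequence[CellPolygon],
    habitat: np.ndarray,
    geometry,
    threshold: int,
) -> tuple[list[CellPolygon], dict[str, int]]:
    """Keep cells with at least ``threshold`` habitat pixels.

    Returns the retained cells and the habitat-pixel count per cell (all
    cells, including excluded ones, for audit logging).
    """
    counts: dict[str, int] = {}
    retained = []
    for cell in cells:
        mask = cell_pixel_mask(cell, geometry, habitat.shape)
        counts[cell.id] = int((mask & habitat).sum())
        if counts[cell.id] >= threshold:
            retained.append(cell)
        else:
            logger.info(
                "cell %s excluded: %d habitat pixels < %d",
                cell.id, counts[cell.id], threshold,
            )
    return retained, counts


def annual_max(quarter_values: Sequence[float], missing_quarter_limit: int = 2) -> float:
    """Annual maximum over quarters; NaN when >= ``missing_quarter_limit`` miss."""
    v = np.asarray(quarter_values, dtype=float)
    n_missing = int(np.isnan(v).sum())
    if n_missing >= missing_quarter_limit or len(v) == 0:
        return float("nan")
    return float(np.nanmax(v))


def annual_max_table(
    quarterly: pd.DataFrame, missing_quarter_limit: int = 2
) -> pd.DataFrame:
    """Per-cell annual maxima from the quarterly table.

    Output columns: cell_id, year, area_m2 (NaN when the year is missing),
    n_missing_quarters.
    """
    rows = []
    for (cell_id, year), grp in quarterly.groupby(["cell_id", "year"]):
        vals = grp["area_m2"].to_numpy(dtype=float)
        n_missing = int(np.isnan(vals).sum())
        rows.append(
            {
                "cell_id": cell_id,
                "year": int(year),
                "area_m2": annual_max(vals, missing_quarter_limit),
                "n_missing_quarters": n_missing,
            }
        )
    return pd.DataFrame(rows).sort_values(["cell_id", "year"], ignore_index=True)


def regional_annual(
    annual: pd.DataFrame,
    regions: Mapping[str, Sequence[str]],
    strict_missing: bool = False,
) -> pd.DataFrame:
    """Sum cell annual maxima into regions with the majority-missing rule.

    A region-year is missing when more than half of the region's cells were
    missing more than one quarter (i.e. are themselves missing under the
    two-quarter rule).  In non-missing years, a sporadically missing cell
    contributes 0 with a warning by default; with ``strict_missing`` the
    region-year becomes missing instead.
    """
    rows = []
    for region, cell_ids in regions.items():
        cell_ids = list(cell_ids)
        if not cell_ids:
            raise ValueError(f"region {region!r} has no cells")
        sub = annual[annual["cell_id"].isin(cell_ids)]
        for year, grp in sub.groupby("year"):
            n_cells = len(cell_ids)
            n_bad = int((grp["n_missing_quarters"] >= 2).sum())
            missing = n_bad > n_cells / 2.0
            vals = grp["area_m2"].to_numpy(dtype=float)
            if missing:
                total = np.nan
            elif np.isnan(vals).any() and strict_missing:
                total = np.nan
                missing = True
            else:
                if np.isnan(vals).any():
                    logger.warning(
                        "region %s year %s: %d missing cells contribute 0",
                        region, year, int(np.isnan(vals).sum()),
                    )
                total = float(np.nansum(vals))
            rows.append(
                {
                    "region": region,
                    "year": int(year),
                    "area_m2": total,
                    "n_cells": n_cells,
                    "n_cells_missing": n_bad,
                    "missing": bool(missing),
                }
            )
    return pd.DataFrame(rows).sort_values(["region", "year"], ignore_index=True)
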