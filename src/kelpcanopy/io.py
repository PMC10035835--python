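"""Readers and writers for the interchange formats, plus run configuration.

Rasters travel as plain TIFF (via :mod:`tifffile`) with a JSON sidecar
carrying the grid geometry and acquisition metadata; grid cells as GeoJSON
(polygon features in lon/lat with the projected rectangle in the feature
properties); tabular outputs as CSV; and per-pixel seasonal layers
optionally as netCDF (classic format through the scipy engine).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml
from shapely.geometry import box
from shapely.strtree import STRtree

from .aggregate import CellPolygon, SeasonalPixelStats
from .scene import BANDS, GridGeometry, Scene

__all__ = [
    "write_scene",
    "read_scene",
    "write_raster",
    "read_raster",
    "write_cells",
    "read_cells",
    "write_seasonal_netcdf",
    "PipelineConfig",
]


def _geometry_dict(g: GridGeometry) -> dict:
    return {"x0": g.x0, "y0": g.y0, "pixel_size": g.pixel_size, "lat0": g.lat0}


def write_scene(scene: Scene, path: str | Path) -> Path:
    """Write a scene as ``<path>.tif`` (6 band planes + QA plane) with a
    ``<path>.json`` metadata sidecar.  Returns the TIFF path."""
    path = Path(path)
    tif = path.with_suffix(".tif")
    stack = np.concatenate(
        [scene.bands.transpose(2, 0, 1).astype(np.float32),
         scene.qa[None].astype(np.float32)]
    )
    tifffile.imwrite(tif, stack, photometric="minisblack")
    meta = {
        "bands": list(BANDS),
        "acquired": scene.acquired.isoformat(),
        "sensor_generation": scene.sensor_generation,
        "tide_height": scene.tide_height,
        "geometry": _geometry_dict(scene.geometry),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return tif


def read_scene(path: str | Path) -> Scene:
    """Read a scene written by :func:`write_scene` (lossless round trip)."""
    path = Path(path)
    tif, sidecar = path.with_suffix(".tif"), path.with_suffix(".json")
    if not tif.exists():
        raise FileNotFoundError(f"scene raster {tif} not found")
    if not sidecar.exists():
        raise FileNotFoundError(f"scene metadata sidecar {sidecar} not found")
    try:
        stack = tifffile.imread(tif)
    except Exception as exc:  # truncated/corrupt file
        raise ValueError(f"could not read scene raster {tif}: {exc}") from exc
    meta = json.loads(sidecar.read_text())
    if meta.get("bands") != list(BANDS):
        raise ValueError(
            f"band mismatch in {sidecar}: expected {list(BANDS)}, got {meta.get('bands')}"
        )
    if stack.ndim != 3 or stack.shape[0] != len(BANDS) + 1:
        raise ValueError(
            f"{tif}: expected {len(BANDS) + 1} planes (bands + QA), got shape {stack.shape}"
        )
    g = meta["geometry"]
    return Scene(
        bands=stack[: len(BANDS)].transpose(1, 2, 0).astype(float),
        qa=stack[len(BANDS)].astype(np.int64),
        acquired=date.fromisoformat(meta["acquired"]),
        sensor_generation=meta["sensor_generation"],
        tide_height=float(meta["tide_height"]),
        geometry=GridGeometry(**g),
    )


def write_raster(array: np.ndarray, path: str | Path) -> Path:
    """Single-band TIFF; boolean masks are stored as 0/1 uint8."""
    path = Path(path).with_suffix(".tif")
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    return path


def read_raster(path: str | Path, as_bool: bool = False) -> np.ndarray:
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"could not read raster {path}: {exc}") from exc
    return arr.astype(bool) if as_bool else arr


_M_PER_DEG = 111_320.0


def _xy_to_lonlat(x: float, y: float, g: GridGeometry) -> tuple[float, float]:
    lat = g.latitude_of_y(y)
    lon = x / (_M_PER_DEG * np.cos(np.radians(g.lat0)))
    return float(lon), float(lat)


def write_cells(
    cells: Sequence[CellPolygon], path: str | Path, geometry: GridGeometry | None = None
) -> Path:
    """Cells as a GeoJSON FeatureCollection.

    Polygon rings are corner coordinates in lon/lat (degrees); the projected
    rectangle is kept in the properties so the reader does not depend on the
    inverse projection.
    """
    g = geometry or GridGeometry()
    features = []
    for cell in cells:
        corners_xy = [
            (cell.x0, cell.y0), (cell.x1, cell.y0),
            (cell.x1, cell.y1), (cell.x0, cell.y1), (cell.x0, cell.y0),
        ]
        ring = [list(_xy_to_lonlat(x, y, g)) for x, y in corners_xy]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "id": cell.id,
                    "nominal_size_m": cell.nominal_size_m,
                    "x0": cell.x0, "y0": cell.y0, "x1": cell.x1, "y1": cell.y1,
                },
            }
        )
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=2))
    return path


def read_cells(path: str | Path) -> list[CellPolygon]:
    """Read and validate a cell grid from GeoJSON.

    Features must carry an ``id`` and the projected rectangle; rectangles
    must be non-degenerate and pairwise disjoint (overlaps are rejected with
    both ids named).  The centroid latitude is the mean of the corner
    latitudes of the polygon ring.
    """
    data = json.loads(Path(path).read_text())
    cells: list[CellPolygon] = []
    for feat in data.get("features", []):
        props = feat.get("properties", {})
        if "id" not in props:
            raise ValueError("cell feature without an 'id' property")
        ring = feat["geometry"]["coordinates"][0]
        corner_lats = [pt[1] for pt in ring[:-1]]  # drop closing vertex
        lat = float(np.mean(corner_lats))
        try:
            cells.append(
                CellPolygon(
                    id=str(props["id"]),
                    x0=float(props["x0"]), y0=float(props["y0"]),
                    x1=float(props["x1"]), y1=float(props["y1"]),
                    nominal_size_m=float(props.get("nominal_size_m", 10_000.0)),
                    latitude=lat,
                )
            )
        except ValueError as exc:
            raise ValueError(f"degenerate cell {props['id']!r}: {exc}") from exc
    boxes = [box(c.x0, c.y0, c.x1, c.y1) for c in cells]
    tree = STRtree(boxes)
    for i, b in enumerate(boxes):
        for j in tree.query(b):
            j = int(j)
            if j > i and boxes[j].intersection(b).area > 0:
                raise ValueError(
                    f"cells {cells[i].id!r} and {cells[j].id!r} overlap"
                )
    return cells


def write_seasonal_netcdf(
    stats_list: Sequence[SeasonalPixelStats], path: str | Path
) -> Path:
    """Per-pixel seasonal mean/stderr/overpass-count layers as netCDF.

    Classic netCDF3 via the scipy engine; layout mirrors the quarterly
    per-pixel structure of the canopy dataset (time = year + quarter).
    """
    import xarray as xr

    time = [s.year + (s.quarter - 1) / 4.0 for s in stats_list]
    ds = xr.Dataset(
        {
            "mean_area": (("time", "y", "x"), np.stack([s.mean_area for s in stats_list])),
            "stderr": (("time", "y", "x"), np.stack([s.stderr for s in stats_list])),
            "n_overpasses": (
                ("time", "y", "x"),
                np.stack([s.n_overpasses for s in stats_list]).astype(np.int32),
            ),
        },
        coords={"time": time},
        attrs={"mean_area_units": "m^2"},
    )
    path = Path(path)
    ds.to_netcdf(path, engine="scipy")
    return path


@dataclass
class PipelineConfig:
    """Everything a full synthetic-archive run needs, seeds included.

    Thresholds default to the published processing rules (water-index cutoff
    0.1, 25% cloud rule, 900 m^2 pixels, 30 seawater endmembers, heatwave
    windows 1984-2013 / 2014-2016 / 2017-2021); the habitat-pixel threshold
    defaults to the local-scale 25 because the simulated cells are
    desk-scale, not 10 km.
    """

    seed: int = 1
    # domain
    n_cells_x: int = 2
    n_cells_y: int = 2
    cell_px: int = 24
    # dynamics
    n_years: int = 38
    start_year: int = 1984
    trend: float = -0.008
    ar_coefficients: tuple[float, ...] = (0.3,)
    noise_sd: float = 0.05
    oscillation_period: float = 10.0
    oscillation_amplitude: float = 0.1
    heatwave_depth: float = 0.2
    recovery_level: float = 0.8
    acquisitions_per_quarter: int = 3
    cloud_coverage: float = 0.15
    scene_noise_sd: float = 0.005
    peak_kelp_fraction: float = 0.6
    # processing thresholds
    mndwi_threshold: float = 0.1
    max_unobserved_fraction: float = 0.25
    habitat_threshold: int = 25
    pixel_area: float = 900.0
    n_seawater_endmembers: int = 30
    ar_orders: tuple[int, ...] = (0, 1, 2)
    baseline_years: tuple[int, int] = (1984, 2013)
    event_years: tuple[int, int] = (2014, 2016)
    recovery_years: tuple[int, int] = (2017, 2021)
    kmeans_k: int = 15
    tree_max_depth: int = 8
    remove_tidal_flags: bool = False
    strict_regional_missing: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.max_unobserved_fraction <= 1:
            raise ValueError("max_unobserved_fraction must be in [0, 1]")
        if not -1 <= self.mndwi_threshold <= 1:
            raise ValueError("mndwi_threshold must be in [-1, 1]")
        if self.pixel_area <= 0 or self.habitat_threshold < 0:
            raise ValueError("invalid pixel_area or habitat_threshold")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("ar_coefficients", "ar_orders", "baseline_years",
                    "event_years", "recovery_years"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
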