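"""Core raster domain types shared across the pipeline.

A :class:`Scene` is a single multispectral acquisition: six surface-reflectance
bands on one grid, a per-pixel quality-assurance (QA) code raster, and the
acquisition metadata the downstream stages need (date, sensor generation,
tide height at overpass).  Grids are north-up, projected metres, pixel-centre
georeferenced; the affine transform is ``(x0, y0, pixel_size)`` with
``x = x0 + pixel_size * (col + 0.5)`` and ``y = y0 - pixel_size * (row + 0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np

#: Band order used everywhere in the package.
BANDS: tuple[str, ...] = ("blue", "green", "red", "nir", "swir1", "swir2")

#: The four bands used by spectral unmixing (classification uses all six).
UNMIX_BANDS: tuple[str, ...] = BANDS[:4]

N_BANDS = len(BANDS)

# Class codes for truth maps and classified rasters.
SEAWATER, KELP, CLOUD, LAND, INTERTIDAL = 0, 1, 2, 3, 4
CLASS_NAMES = {
    SEAWATER: "seawater",
    KELP: "kelp",
    CLOUD: "cloud",
    LAND: "land",
    INTERTIDAL: "intertidal",
}

#: Default QA code dialect: 0 = clear, 1 = cloud.  Configurable because QA
#: bit conventions differ across product collections.
QA_CLEAR = 0
QA_CLOUD = 1
DEFAULT_CLOUD_CODES = frozenset({QA_CLOUD})

# Sensor generations: one classifier per generation because band response
# functions differ between the TM/ETM+ and OLI instrument families.
TM_ETM = "TM/ETM+"
OLI = "OLI"
SENSOR_GENERATIONS = (TM_ETM, OLI)


@dataclass
class GridGeometry:
    """North-up projected grid: origin of the top-left pixel corner and size."""

    x0: float = 0.0
    y0: float = 0.0
    pixel_size: float = 30.0  # metres
    #: Latitude (degrees) of the grid origin; used to assign cell latitudes.
    lat0: float = 36.0

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.indices(shape)
        x = self.x0 + self.pixel_size * (cols + 0.5)
        y = self.y0 - self.pixel_size * (rows + 0.5)
        return x, y

    def latitude_of_y(self, y: float) -> float:
        # ~111.32 km per degree of latitude
        return self.lat0 + y / 111_320.0

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2


@dataclass
class Scene:
    """One multiband acquisition with QA codes and metadata."""

    bands: np.ndarray  # (H, W, 6) float reflectance
    qa: np.ndarray  # (H, W) integer QA codes
    acquired: _date
    sensor_generation: str = TM_ETM
    tide_height: float = 0.0  # metres relative to MLLW-like datum
    geometry: GridGeometry = field(default_factory=GridGeometry)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        self.qa = np.asarray(self.qa)
        if self.bands.ndim != 3 or self.bands.shape[-1] != N_BANDS:
            raise ValueError(
                f"bands must be (H, W, {N_BANDS}); got {self.bands.shape}"
            )
        if self.qa.shape != self.bands.shape[:2]:
            raise ValueError("qa grid does not match band grid")
        if self.sensor_generation not in SENSOR_GENERATIONS:
            raise ValueError(f"unknown sensor generation {self.sensor_generation!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[:2]

    def band(self, name: str) -> np.ndarray:
        return self.bands[..., BANDS.index(name)]


@dataclass
class SceneTruth:
    """Ground truth for a simulated scene.

    ``kelp_fraction`` is the true per-pixel fractional canopy cover in [0, 1];
    it is positive only where ``class_map`` equals :data:`KELP`.
    """

    kelp_fraction: np.ndarray  # (H, W) in [0, 1]
    class_map: np.ndarray  # (H, W) int class codes
    tide_height: float = 0.0
    #: Per-pixel index of the seawater water-mass each pixel mixes with.
    water_region: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.kelp_fraction = np.asarray(self.kelp_fraction, dtype=float)
        self.class_map = np.asarray(self.class_map)
        if self.kelp_fraction.shape != self.class_map.shape:
            raise ValueError("kelp_fraction and class_map shapes differ")
        if np.any((self.kelp_fraction < 0) | (self.kelp_fraction > 1)):
            raise ValueError("kelp_fraction outside [0, 1]")
        if np.any((self.kelp_fraction > 0) & (self.class_map != KELP)):
            raise ValueError("positive kelp fraction on a non-kelp pixel")
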