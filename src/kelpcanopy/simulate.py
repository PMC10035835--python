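"""Synthetic Landsat-like scenes and multi-decade canopy dynamics.

Everything downstream of this module (masking, classification, unmixing,
aggregation, trend statistics) is exercised on scenes produced here, for
which the ground truth — per-pixel fractional canopy cover, class map, and
the generating annual trajectory — is known exactly.

The simulator emulates the structure of coastal surface-reflectance tiles:

* kelp pixels are linear two-endmember mixtures ``f * E_kelp + (1-f) * E_water``
  with kelp bright in the near infrared and seawater near zero there;
* seawater conditions vary across the scene as a small number of discrete
  water masses (sun-glint / turbidity analogues), each with its own spectrum
  redrawn per acquisition;
* a land strip, an intertidal fringe that is exposed (land-like) only at
  negative tide, and random cloud blobs recorded in the QA band;
* a quarterly acquisition cadence over ~38 years whose true annual canopy
  follows trend + decadal oscillation + autoregressive noise, with a
  marine-heatwave dip and partial recovery superimposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import ndimage

from .aggregate import CellPolygon
from .scene import (
    BANDS,
    CLOUD,
    INTERTIDAL,
    KELP,
    LAND,
    N_BANDS,
    OLI,
    QA_CLEAR,
    QA_CLOUD,
    SEAWATER,
    TM_ETM,
    GridGeometry,
    Scene,
    SceneTruth,
)

__all__ = [
    "SpectralLibrary",
    "DynamicsConfig",
    "SimulatedDomain",
    "SimulatedAcquisition",
    "generate_spectral_library",
    "generate_scene",
    "generate_tide_series",
    "make_domain",
    "canopy_trajectory",
    "generate_scene_series",
]


@dataclass
class SpectralLibrary:
    """Endmember spectra (6 bands each, unitless reflectance in [0, 1])."""

    kelp_endmember: np.ndarray
    seawater_base: np.ndarray
    seawater_variability: np.ndarray  # per-band spread of water-mass spectra
    land_spectrum: np.ndarray
    cloud_spectrum: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "kelp_endmember",
            "seawater_base",
            "seawater_variability",
            "land_spectrum",
            "cloud_spectrum",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_BANDS,):
                raise ValueError(f"{name} must have {N_BANDS} bands")
            setattr(self, name, arr)
        nir = BANDS.index("nir")
        if not self.kelp_endmember[nir] > self.seawater_base[nir]:
            raise ValueError("kelp NIR reflectance must exceed seawater NIR")

    def water_mass_spectra(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` water-mass spectra around the seawater base."""
        z = rng.normal(size=(n, N_BANDS))
        return np.clip(self.seawater_base + z * self.seawater_variability, 0.0, 1.0)


def generate_spectral_library(seed: int) -> SpectralLibrary:
    """Deterministic synthetic endmember library.

    The spectra are stand-ins with the qualitative structure that drives the
    method (kelp bright in the NIR, seawater dark there, land with high SWIR
    so its water index is negative, bright flat cloud); no claim of
    radiometric realism is made.
    """
    rng = np.random.default_rng(seed)
    # bands:            blue   green  red    nir    swir1  swir2
    kelp = np.array([0.020, 0.045, 0.030, 0.350, 0.060, 0.030])
    water = np.array([0.060, 0.050, 0.030, 0.012, 0.004, 0.003])
    land = np.array([0.080, 0.110, 0.140, 0.250, 0.300, 0.240])
    cloud = np.array([0.650, 0.660, 0.670, 0.680, 0.600, 0.550])
    # seed-specific perturbation of the water base (regional conditions)
    water = np.clip(water + rng.normal(scale=0.004, size=N_BANDS), 0.001, 1.0)
    water[BANDS.index("nir")] = min(water[BANDS.index("nir")], 0.02)
    variability = np.array([0.015, 0.015, 0.010, 0.003, 0.002, 0.002])
    kelp = kelp + rng.normal(scale=0.002, size=N_BANDS)
    return SpectralLibrary(
        kelp_endmember=np.clip(kelp, 0.0, 1.0),
        seawater_base=water,
        seawater_variability=variability,
        land_spectrum=land,
        cloud_spectrum=cloud,
    )


def generate_scene(
    truth: SceneTruth,
    library: SpectralLibrary,
    noise_sd: float,
    seed: int,
    acquired: date = date(2000, 7, 1),
    sensor_generation: str = TM_ETM,
    geometry: GridGeometry | None = None,
) -> Scene:
    """Render a :class:`Scene` from ground truth and an endmember library.

    Kelp pixels get ``f * E_kelp + (1-f) * E_water`` with the water-mass
    spectrum of their region; cloud pixels get the cloud spectrum and a
    cloud QA code; land (and exposed intertidal, tide < 0) pixels get the
    land spectrum.  Independent Gaussian noise per band, truncated to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    cls = truth.class_map
    shape = cls.shape

    region = (
        truth.water_region
        if truth.water_region is not None
        else np.zeros(shape, dtype=int)
    )
    n_regions = int(region.max()) + 1
    water_spectra = library.water_mass_spectra(n_regions, rng)
    per_pixel_water = water_spectra[region]  # (H, W, 6)

    bands = per_pixel_water.copy()
    f = truth.kelp_fraction[..., None]
    kelp_px = cls == KELP
    bands[kelp_px] = (
        f[kelp_px] * library.kelp_endmember
        + (1.0 - f[kelp_px]) * per_pixel_water[kelp_px]
    )
    bands[cls == LAND] = library.land_spectrum
    exposed = (cls == INTERTIDAL) & (truth.tide_height < 0)
    bands[exposed] = library.land_spectrum
    bands[cls == CLOUD] = library.cloud_spectrum

    if noise_sd > 0:
        bands = bands + rng.normal(scale=noise_sd, size=bands.shape)
    bands = np.clip(bands, 0.0, 1.0)

    qa = np.full(shape, QA_CLEAR, dtype=np.uint8)
    qa[cls == CLOUD] = QA_CLOUD
    return Scene(
        bands=bands,
        qa=qa,
        acquired=acquired,
        sensor_generation=sensor_generation,
        tide_height=truth.tide_height,
        geometry=geometry or GridGeometry(),
    )


def generate_tide_series(
    seed: int, n: int, amplitude: float = 1.0, mean_level: float = 0.0
) -> np.ndarray:
    """Bounded oscillatory tide heights (m) at acquisition times.

    Two incommensurate sinusoids with seeded random phases approximate the
    mixed semidiurnal/spring-neap beat sampled at overpass times; amplitude 0
    degenerates to a constant series.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    t = np.arange(n, dtype=float)
    series = 0.7 * np.sin(2 * np.pi * t / 3.7 + phases[0]) + 0.3 * np.sin(
        2 * np.pi * t / 13.1 + phases[1]
    )
    return mean_level + amplitude * series


@dataclass
class DynamicsConfig:
    """Multi-decade canopy dynamics: the study conditions for the simulator.

    The true annual canopy level (fraction of its maximum) is
    ``1 + trend * (year - start) + oscillation + AR-noise`` with heatwave
    years forced to ``heatwave_depth`` of the pre-event baseline mean and the
    recovery window to ``recovery_level`` of it.  Noise is multiplicative
    (variability scales with abundance; canopy cannot be negative).
    """

    n_years: int = 38
    start_year: int = 1984
    quarters_per_year: int = 4
    acquisitions_per_quarter: int = 3
    trend: float = 0.0  # fraction of max per year
    ar_order: int = 1
    ar_coefficients: tuple[float, ...] = (0.3,)
    noise_sd: float = 0.05  # innovation sd, fraction of baseline level
    oscillation_period: float = 10.0  # years
    oscillation_amplitude: float = 0.1  # fraction of max
    heatwave_years: tuple[int, int] | None = (2014, 2016)
    heatwave_depth: float = 0.2  # fraction of baseline retained
    recovery_years: tuple[int, int] = (2017, 2021)
    recovery_level: float = 0.8  # fraction of baseline
    seasonal_profile: tuple[float, ...] = (0.7, 0.85, 1.0, 0.8)
    cloud_coverage: float = 0.15  # expected cloud fraction per acquisition
    fully_clouded_quarters: tuple[tuple[int, int], ...] = ()
    scene_noise_sd: float = 0.0  # reflectance noise per band
    tide_amplitude: float = 1.0
    peak_kelp_fraction: float = 0.6  # canopy density at the patch core
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.heatwave_depth < 0 or self.recovery_level < 0:
            raise ValueError("heatwave_depth and recovery_level must be >= 0")
        if len(self.ar_coefficients) != self.ar_order:
            raise ValueError("ar_coefficients length must equal ar_order")
        if self.ar_order and not _ar_is_stationary(self.ar_coefficients):
            raise ValueError("ar_coefficients do not define a stationary process")
        if len(self.seasonal_profile) != self.quarters_per_year:
            raise ValueError("seasonal_profile length must match quarters_per_year")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


def _ar_is_stationary(coeffs: tuple[float, ...]) -> bool:
    poly = np.r_[1.0, -np.asarray(coeffs, dtype=float)]
    roots = np.roots(poly[::-1])
    return bool(np.all(np.abs(roots) > 1.0 + 1e-9)) if len(roots) else True


def _ar_noise(
    rng: np.random.Generator, n: int, coeffs: tuple[float, ...], sd: float
) -> np.ndarray:
    p = len(coeffs)
    if sd == 0:
        return np.zeros(n)
    burn = 100
    e = rng.normal(scale=sd, size=n + burn)
    if p == 0:
        return e[burn:]
    x = np.zeros(n + burn)
    a = np.asarray(coeffs)
    for t in range(n + burn):
        hist = sum(a[i] * x[t - 1 - i] for i in range(min(p, t)))
        x[t] = hist + e[t]
    return x[burn:]


def canopy_trajectory(config: DynamicsConfig) -> pd.DataFrame:
    """True annual canopy level per year (fraction of maximum).

    Returns a frame with columns ``year``, ``deterministic`` (trend +
    oscillation + heatwave overrides) and ``level`` (with multiplicative
    AR noise applied, clipped at zero).
    """
    years = config.years
    t = years - config.start_year
    det = (
        1.0
        + config.trend * t
        + config.oscillation_amplitude
        * np.sin(2 * np.pi * t / config.oscillation_period)
    )
    if config.heatwave_years is not None:
        hw0, hw1 = config.heatwave_years
        baseline = years < hw0
        if not baseline.any():
            raise ValueError("heatwave window leaves no baseline years")
        base_mean = det[baseline].mean()
        det = det.copy()
        det[(years >= hw0) & (years <= hw1)] = config.heatwave_depth * base_mean
        r0, r1 = config.recovery_years
        det[(years >= r0) & (years <= r1)] = config.recovery_level * base_mean
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    noise = _ar_noise(rng, len(years), config.ar_coefficients, config.noise_sd)
    level = np.clip(det * (1.0 + noise), 0.0, None)
    return pd.DataFrame({"year": years, "deterministic": det, "level": level})


@dataclass
class SimulatedDomain:
    """Fixed geography for a simulated archive.

    A coastal strip of land (with an intertidal fringe at elevation exactly
    zero), open water partitioned into discrete water masses, one kelp patch
    per grid cell, and the cell polygons themselves.
    """

    shape: tuple[int, int]
    geometry: GridGeometry
    land: np.ndarray  # bool
    intertidal: np.ndarray  # bool
    water_region: np.ndarray  # int, water-mass id per pixel
    dem: np.ndarray  # float metres
    cells: list[CellPolygon] = field(default_factory=list)
    patch_masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_habitat_pixels(self) -> dict[str, int]:
        return {cid: int(m.sum()) for cid, m in self.patch_masks.items()}


def _smooth_field(shape, rng, sigma: float = 4.0) -> np.ndarray:
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma)


def make_domain(
    n_cells_x: int = 2,
    n_cells_y: int = 2,
    cell_px: int = 24,
    land_cols: int = 3,
    intertidal_cols: int = 1,
    n_water_regions: int = 4,
    patch_radius_px: float = 7.0,
    seed: int = 0,
    geometry: GridGeometry | None = None,
) -> SimulatedDomain:
    """Build the fixed geography: cells, land strip, patches, water masses."""
    if n_cells_x < 1 or n_cells_y < 1:
        raise ValueError("domain must contain at least one cell")
    H, W = n_cells_y * cell_px, n_cells_x * cell_px
    geom = geometry or GridGeometry(y0=H * 30.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))

    land = np.zeros((H, W), dtype=bool)
    land[:, :land_cols] = True
    intertidal = np.zeros((H, W), dtype=bool)
    intertidal[:, land_cols : land_cols + intertidal_cols] = True

    field_ = _smooth_field((H, W), rng, sigma=max(4.0, cell_px / 4))
    edges = np.quantile(field_, np.linspace(0, 1, n_water_regions + 1)[1:-1])
    water_region = np.digitize(field_, edges)

    dem = np.where(land, 5.0, -10.0)
    dem[intertidal] = 0.0  # exactly sea level: below the strict > 0 land rule

    px = geom.pixel_size
    cells: list[CellPolygon] = []
    patch_masks: dict[str, np.ndarray] = {}
    rows, cols = np.indices((H, W))
    for cy in range(n_cells_y):
        for cx in range(n_cells_x):
            cid = f"cell_{cy}_{cx}"
            x0, x1 = cx * cell_px * px, (cx + 1) * cell_px * px
            # y decreases with row; cell y-extent from bottom to top edge
            y_top = geom.y0 - cy * cell_px * px
            y_bot = geom.y0 - (cy + 1) * cell_px * px
            lat = geom.latitude_of_y((y_top + y_bot) / 2.0)
            cells.append(
                CellPolygon(
                    id=cid, x0=x0, y0=y_bot, x1=x1, y1=y_top,
                    nominal_size_m=cell_px * px, latitude=lat,
                )
            )
            # offshore patch: centred in the water part of the cell
            cx_px = cx * cell_px + (cell_px + land_cols + intertidal_cols) / 2.0
            cy_px = cy * cell_px + cell_px / 2.0
            jitter = rng.uniform(-cell_px / 8, cell_px / 8, size=2)
            dist = np.hypot(rows - (cy_px + jitter[0]), cols - (cx_px + jitter[1]))
            mask = (dist <= patch_radius_px) & ~land & ~intertidal
            in_cell = (
                (rows // cell_px == cy) & (cols // cell_px == cx)
            )
            patch_masks[cid] = mask & in_cell
    return SimulatedDomain(
        shape=(H, W),
        geometry=geom,
        land=land,
        intertidal=intertidal,
        water_region=water_region,
        dem=dem,
        cells=cells,
        patch_masks=patch_masks,
    )


def _cloud_blobs(shape, coverage: float, rng: np.random.Generator) -> np.ndarray:
    if coverage <= 0:
        return np.zeros(shape, dtype=bool)
    if coverage >= 1:
        return np.ones(shape, dtype=bool)
    f = _smooth_field(shape, rng, sigma=3.0)
    return f > np.quantile(f, 1.0 - coverage)


@dataclass
class SimulatedAcquisition:
    """One simulated overpass with its ground truth and calendar position."""

    scene: Scene
    truth: SceneTruth
    year: int
    quarter: int  # 1..4


_QUARTER_MONTHS = {1: 2, 2: 5, 3: 8, 4: 11}


def generate_scene_series(
    dynamics: DynamicsConfig,
    domain: SimulatedDomain,
    library: SpectralLibrary | None = None,
) -> tuple[list[SimulatedAcquisition], pd.DataFrame]:
    """Simulate the full archive.

    Returns the list of acquisitions (scene + truth, ordered by time) and the
    true annual trajectory frame from :func:`canopy_trajectory` augmented with
    the true summed canopy area (m^2) per year at the seasonal peak.
    """
    if not domain.cells:
        raise ValueError("domain has no cells")
    library = library or generate_spectral_library(dynamics.seed)
    traj = canopy_trajectory(dynamics)
    ss = np.random.SeedSequence([dynamics.seed, 23])
    n_total = (
        dynamics.n_years
        * dynamics.quarters_per_year
        * dynamics.acquisitions_per_quarter
    )
    tide_seed = int(ss.generate_state(1)[0] % (2**31))
    tides = generate_tide_series(tide_seed, n_total, amplitude=dynamics.tide_amplitude)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_total)]

    pixel_area = domain.geometry.pixel_area
    # Canopy dynamics act mainly on patch extent: pixels are occupied from the
    # patch core outward, with a fixed density taper (dense core, sparser
    # edge).  The cumulative-density inversion makes the true summed canopy
    # area exactly proportional to the trajectory level until the patch
    # saturates.
    profiles = {}
    for cid, patch in domain.patch_masks.items():
        rr, cc = np.nonzero(patch)
        r0, c0 = rr.mean(), cc.mean()
        dist = np.hypot(rr - r0, cc - c0)
        rmax = max(dist.max(), 1.0)
        w = dynamics.peak_kelp_fraction * (1.0 - 0.6 * (dist / rmax) ** 2)
        order = np.lexsort((cc, rr, dist))  # deterministic tie-break
        profiles[cid] = (rr[order], cc[order], w[order], np.cumsum(w[order]))
    acquisitions: list[SimulatedAcquisition] = []
    fully_clouded = set(dynamics.fully_clouded_quarters)
    idx = 0
    for yi, year in enumerate(traj["year"].to_numpy()):
        level = traj["level"].to_numpy()[yi]
        for q in range(1, dynamics.quarters_per_year + 1):
            s_q = dynamics.seasonal_profile[q - 1]
            occupancy = max(level * s_q, 0.0)
            base_fraction = np.zeros(domain.shape)
            base_class = np.full(domain.shape, SEAWATER, dtype=np.uint8)
            for cid, (rr, cc, w, cum) in profiles.items():
                target = min(occupancy, 1.0) * cum[-1]
                if target <= 0:
                    continue
                n_full = int(np.searchsorted(cum, target, side="right"))
                base_fraction[rr[:n_full], cc[:n_full]] = w[:n_full]
                if n_full < len(w):
                    residual = target - (cum[n_full - 1] if n_full else 0.0)
                    if residual > 1e-12:
                        base_fraction[rr[n_full], cc[n_full]] = residual
                occupied = base_fraction[rr, cc] > 0
                base_class[rr[occupied], cc[occupied]] = KELP
            base_class[domain.intertidal] = INTERTIDAL
            base_class[domain.land] = LAND
            for a in range(dynamics.acquisitions_per_quarter):
                seed_a = child_seeds[idx]
                rng_a = np.random.default_rng(seed_a)
                coverage = (
                    1.0
                    if (int(year), q) in fully_clouded
                    else dynamics.cloud_coverage * rng_a.uniform(0.0, 2.0)
                )
                clouds = _cloud_blobs(domain.shape, coverage, rng_a)
                cls = base_class.copy()
                cls[clouds] = CLOUD
                fraction = np.where(clouds, 0.0, base_fraction)
                truth = SceneTruth(
                    kelp_fraction=fraction,
                    class_map=cls,
                    tide_height=float(tides[idx]),
                    water_region=domain.water_region,
                )
                sensor = OLI if year >= 2013 else TM_ETM
                acq_date = date(
                    int(year), _QUARTER_MONTHS[q], min(1 + a * 10, 28)
                )
                scene = generate_scene(
                    truth,
                    library,
                    dynamics.scene_noise_sd,
                    seed=seed_a,
                    acquired=acq_date,
                    sensor_generation=sensor,
                    geometry=domain.geometry,
                )
                acquisitions.append(
                    SimulatedAcquisition(scene=scene, truth=truth, year=int(year), quarter=q)
                )
                idx += 1

    total_w = sum(cum[-1] for _, _, _, cum in profiles.values())
    traj = traj.assign(
        true_peak_area_m2=np.clip(
            traj["level"].to_numpy() * max(dynamics.seasonal_profile), 0.0, 1.0
        )
        * total_w
        * pixel_area
    )
    return acquisitions, traj
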