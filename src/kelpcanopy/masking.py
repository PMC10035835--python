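"""Cloud, land and intertidal masks, plus tide-sensitivity flagging.

Masks are boolean rasters on the scene grid with True = excluded.  The
chain mirrors the standard coastal preprocessing: clouds from the product
QA band, land from a digital elevation model (strictly positive elevation),
an intertidal fringe from the water index MNDWI of a reference scene
acquired at negative low tide, and an after-the-fact flag for pixels whose
apparent canopy area co-varies negatively with tide height (likely
intertidal rock/sand rather than kelp).
"""

from __future__ import annotations

import logging
from typing import Iterable, Set

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .scene import DEFAULT_CLOUD_CODES, Scene

logger = logging.getLogger(__name__)

__all__ = [
    "cloud_mask_from_qa",
    "land_mask_from_dem",
    "compute_mndwi",
    "intertidal_mask",
    "land_adjacency",
    "flag_tidal_pixels",
]

#: Pixels with MNDWI strictly below this value in the negative-tide
#: reference scene are treated as exposed intertidal.
MNDWI_INTERTIDAL_THRESHOLD = 0.1


def cloud_mask_from_qa(
    qa: np.ndarray, cloud_codes: Iterable[int] = DEFAULT_CLOUD_CODES
) -> np.ndarray:
    """True where the QA code is one of ``cloud_codes``.

    Codes not in the dialect pass through unmasked; unexpected nonzero codes
    are logged so a mismatched QA convention is noticeable.
    """
    qa = np.asarray(qa)
    codes: Set[int] = set(int(c) for c in cloud_codes)
    mask = np.isin(qa, list(codes))
    unknown = np.unique(qa[~mask])
    unknown = [int(u) for u in unknown if int(u) != 0 and int(u) not in codes]
    if unknown:
        logger.info("QA codes not in cloud dialect, left unmasked: %s", unknown)
    return mask


def land_mask_from_dem(dem: np.ndarray) -> np.ndarray:
    """True where elevation is strictly greater than zero metres.

    Missing elevations (NaN) are treated as land (masked) and logged: a
    coastal pixel with no elevation cannot be trusted to be water.
    """
    dem = np.asarray(dem, dtype=float)
    missing = np.isnan(dem)
    if missing.any():
        logger.info("%d pixels with missing elevation masked as land", missing.sum())
    return (dem > 0.0) | missing


def compute_mndwi(green: np.ndarray, swir: np.ndarray) -> np.ndarray:
    """Modified Normalized Difference Water Index, (green - swir)/(green + swir).

    Undefined (NaN) where the denominator is zero.  Bounded in [-1, 1] for
    non-negative inputs.
    """
    green = np.asarray(green, dtype=float)
    swir = np.asarray(swir, dtype=float)
    denom = green + swir
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = (green - swir) / denom
    return np.where(denom == 0.0, np.nan, idx)


def intertidal_mask(
    reference_scene: Scene,
    land_mask: np.ndarray | None = None,
    cloud_mask: np.ndarray | None = None,
    threshold: float = MNDWI_INTERTIDAL_THRESHOLD,
) -> np.ndarray:
    """Intertidal pixels from a cloud-free reference scene at negative low tide.

    A pixel is intertidal iff its MNDWI is strictly below ``threshold``
    (exactly 0.1 is *not* masked), evaluated on pixels that are neither land
    nor cloud.  Warns when the reference scene was not acquired at negative
    tide, since exposed intertidal is then not distinguishable from water.
    """
    if reference_scene.tide_height >= 0:
        logger.warning(
            "reference scene tide height %.2f m is not negative; "
            "intertidal pixels may be submerged and missed",
            reference_scene.tide_height,
        )
    idx = compute_mndwi(reference_scene.band("green"), reference_scene.band("swir1"))
    mask = idx < threshold  # strict; NaN compares False
    if land_mask is not None:
        mask &= ~land_mask
    if cloud_mask is not None:
        mask &= ~cloud_mask
    return mask


def land_adjacency(land: np.ndarray, radius_px: int = 1) -> np.ndarray:
    """Water pixels within ``radius_px`` (8-connectivity) of the land mask."""
    structure = np.ones((2 * radius_px + 1, 2 * radius_px + 1), dtype=bool)
    dilated = ndimage.binary_dilation(land, structure=structure)
    return dilated & ~np.asarray(land, dtype=bool)


def flag_tidal_pixels(
    area_series: np.ndarray,
    tide_heights: np.ndarray,
    adjacent_to_land: np.ndarray,
    alpha: float = 0.05,
    min_n: int = 8,
) -> pd.DataFrame:
    """Flag land-adjacent pixels whose area declines significantly with tide.

    ``area_series`` is (T, H, W) canopy area per acquisition with NaN where
    the pixel was masked; ``tide_heights`` is the matching (T,) vector.  A
    pixel is flagged iff it is adjacent to land, has at least ``min_n``
    paired observations, an ordinary least-squares slope of area against
    tide height that is negative, and a two-sided p-value below ``alpha``.

    Returns one row per land-adjacent pixel with enough data:
    (row, col, n, slope, p_value, flagged).  Pixels with constant area are
    reported unflagged (the regression is undefined) and logged.
    """
    area_series = np.asarray(area_series, dtype=float)
    tide_heights = np.asarray(tide_heights, dtype=float)
    if area_series.shape[0] != tide_heights.shape[0]:
        raise ValueError("area_series and tide_heights lengths differ")
    rows_out = []
    n_constant = 0
    for r, c in zip(*np.nonzero(adjacent_to_land)):
        y = area_series[:, r, c]
        ok = ~np.isnan(y)
        if ok.sum() < min_n:
            continue
        yv, tv = y[ok], tide_heights[ok]
        if np.ptp(yv) == 0 or np.ptp(tv) == 0:
            n_constant += 1
            rows_out.append(
                dict(row=int(r), col=int(c), n=int(ok.sum()),
                     slope=0.0, p_value=np.nan, flagged=False)
            )
            continue
        res = stats.linregress(tv, yv)
        flagged = (res.slope < 0) and (res.pvalue < alpha)
        rows_out.append(
            dict(row=int(r), col=int(c), n=int(ok.sum()),
                 slope=float(res.slope), p_value=float(res.pvalue),
                 flagged=bool(flagged))
        )
    if n_constant:
        logger.info("%d land-adjacent pixels with constant area not flagged", n_constant)
    return pd.DataFrame(
        rows_out, columns=["row", "col", "n", "slope", "p_value", "flagged"]
    )
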