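"""Multiple endmember spectral mixture analysis (MESMA) for kelp canopy.

Each kelp-class pixel spectrum ``x`` (blue, green, red, NIR) is modelled as
the two-endmember linear mixture

    x_b = f * K_b + (1 - f) * W_b + e_b

with the single static kelp endmember ``K`` and each candidate seawater
endmember ``W`` in turn.  For one candidate the least-squares fraction has
the closed form

    f* = sum_b (x_b - W_b)(K_b - W_b) / sum_b (K_b - W_b)^2

clamped to [0, 1] (so the reported model is a feasible proportion); the
candidate minimizing the root mean squared residual over the four bands
wins, ties broken by lowest candidate index.  Fractional cover converts to
canopy area by multiplying by the pixel area (900 m^2 for 30 m pixels).

The model deliberately has no shade endmember and sums to one; submerged
canopy is not corrected for (it is essentially invisible in the NIR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scene import KELP, UNMIX_BANDS, Scene

__all__ = [
    "EndmemberSet",
    "UnmixResult",
    "select_seawater_endmembers",
    "unmix_pixel",
    "unmix_scene",
    "fraction_to_area",
    "DEFAULT_PIXEL_AREA",
]

DEFAULT_PIXEL_AREA = 900.0  # m^2, a 30 m pixel
N_UNMIX = len(UNMIX_BANDS)
_DEGENERATE_TOL = 1e-12


@dataclass
class EndmemberSet:
    """Per-scene seawater endmembers (n, 4) for the unmixing bands."""

    spectra: np.ndarray
    source_pixels: np.ndarray | None = None  # (n, 2) row/col provenance

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if self.spectra.shape[1] != N_UNMIX:
            raise ValueError(f"endmembers must have {N_UNMIX} bands")

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class UnmixResult:
    fraction: float  # kelp fractional cover in [0, 1]
    rmse: float  # reflectance units, >= 0
    selected_endmember: int  # index of the winning seawater candidate


def select_seawater_endmembers(
    scene: Scene,
    class_raster: np.ndarray,
    n: int = 30,
    seed: int = 0,
    seawater_class: int = 0,
    n_strata: tuple[int, int] = (5, 6),
) -> EndmemberSet:
    """Spatially stratified sample of n seawater-class spectra from one scene.

    The scene is divided into a coarse grid of strata and samples are drawn
    round-robin across non-empty strata so that spectrally distinct water
    regions (glint, turbidity) are all represented.  Deterministic per seed.
    With fewer than ``n`` seawater pixels, all are used (with a warning via
    the returned set's size).
    """
    rows, cols = np.nonzero(np.asarray(class_raster) == seawater_class)
    if len(rows) == 0:
        raise ValueError("scene has no seawater-class pixels")
    H, W = scene.shape
    rng = np.random.default_rng(seed)
    if len(rows) <= n:
        order = np.argsort(rows * W + cols)  # deterministic
        sel = order
    else:
        sr, sc = n_strata
        stratum = (rows * sr // H) * sc + (cols * sc // W)
        # round-robin across shuffled members of each non-empty stratum
        picked: list[int] = []
        members = {}
        for s in np.unique(stratum):
            idx = np.nonzero(stratum == s)[0]
            members[s] = rng.permutation(idx)
        depth = 0
        while len(picked) < n:
            progressed = False
            for s in sorted(members):
                if depth < len(members[s]) and len(picked) < n:
                    picked.append(int(members[s][depth]))
                    progressed = True
            if not progressed:
                break
            depth += 1
        sel = np.asarray(picked[:n])
    spectra = scene.bands[rows[sel], cols[sel], :N_UNMIX]
    pix = np.stack([rows[sel], cols[sel]], axis=1)
    return EndmemberSet(spectra=spectra, source_pixels=pix)


def _closed_form_fractions(
    X: np.ndarray, kelp: np.ndarray, water: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-endmember fits for pixels X (m, 4) over candidates (n, 4).

    Returns (fractions (m, n), rmse (m, n), degenerate (n,) bool)."""
    d = kelp[None, :] - water  # (n, 4)
    denom = np.sum(d * d, axis=1)  # (n,)
    degenerate = denom < _DEGENERATE_TOL
    safe = np.where(degenerate, 1.0, denom)
    # f[m, n] = (x_m - w_n) . (k - w_n) / |k - w_n|^2
    num = np.einsum("mb,nb->mn", X, d) - np.sum(water * d, axis=1)[None, :]
    f = np.clip(num / safe[None, :], 0.0, 1.0)
    model = f[..., None] * kelp[None, None, :] + (1.0 - f[..., None]) * water[None, :, :]
    resid = X[:, None, :] - model
    rmse = np.sqrt(np.mean(resid**2, axis=2))
    return f, rmse, degenerate


def unmix_pixel(
    spectrum: np.ndarray, kelp_em: np.ndarray, water_ems: EndmemberSet
) -> UnmixResult:
    """Best two-endmember model for one pixel spectrum (4 bands).

    Degenerate candidates (seawater equal to the kelp endmember) are skipped;
    if every candidate is degenerate the pixel cannot be unmixed.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.shape != (N_UNMIX,) or not np.all(np.isfinite(x)):
        raise ValueError(f"spectrum must be {N_UNMIX} finite reflectances")
    kelp = np.asarray(kelp_em, dtype=float)[:N_UNMIX]
    f, rmse, degenerate = _closed_form_fractions(x[None, :], kelp, water_ems.spectra)
    if degenerate.all():
        raise ValueError("all seawater endmembers equal the kelp endmember")
    rmse = np.where(degenerate[None, :], np.inf, rmse)
    best = int(np.argmin(rmse[0]))  # argmin takes the lowest index on ties
    return UnmixResult(
        fraction=float(f[0, best]),
        rmse=float(rmse[0, best]),
        selected_endmember=best,
    )


def unmix_scene(
    scene: Scene,
    class_raster: np.ndarray,
    kelp_em: np.ndarray,
    water_ems: EndmemberSet,
    masked: np.ndarray | None = None,
) -> np.ndarray:
    """Kelp fraction raster: fitted for kelp-class pixels only.

    Non-kelp unmasked pixels get fraction 0; masked pixels get NaN.
    """
    kelp = np.asarray(kelp_em, dtype=float)[:N_UNMIX]
    out = np.zeros(scene.shape, dtype=float)
    if masked is not None:
        out[masked] = np.nan
    kelp_px = (np.asarray(class_raster) == KELP)
    if masked is not None:
        kelp_px &= ~masked
    if kelp_px.any():
        X = scene.bands[kelp_px][:, :N_UNMIX]
        f, rmse, degenerate = _closed_form_fractions(X, kelp, water_ems.spectra)
        if degenerate.all():
            raise ValueError("all seawater endmembers equal the kelp endmember")
        rmse = np.where(degenerate[None, :], np.inf, rmse)
        best = np.argmin(rmse, axis=1)
        out[kelp_px] = f[np.arange(len(X)), best]
    return out


def fraction_to_area(
    fraction: np.ndarray | float, pixel_area: float = DEFAULT_PIXEL_AREA
):
    """Canopy area = fractional cover x pixel area (m^2); NaN propagates."""
    if pixel_area < 0:
        raise ValueError("pixel_area must be non-negative")
    arr = np.asarray(fraction, dtype=float)
    if np.any(np.nan_to_num(arr, nan=0.5) < 0) or np.any(np.nan_to_num(arr, nan=0.5) > 1):
        raise ValueError("fractions must lie in [0, 1]")
    out = arr * pixel_area
    return float(out) if np.isscalar(fraction) else out
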