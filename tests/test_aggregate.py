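"""Seasonal statistics, habitat mask, cell aggregation and missing-data rules."""

import numpy as np
import pandas as pd
import pytest

from kelpcanopy.aggregate import (
    CellPolygon,
    aggregate_cell_quarter,
    aggregate_cells,
    annual_max,
    annual_max_table,
    cell_pixel_mask,
    derive_habitat_mask,
    filter_cells_by_habitat,
    regional_annual,
    seasonal_pixel_stats,
)
from kelpcanopy.scene import GridGeometry


class TestSeasonalPixelStats:
    def test_mean_and_count(self):
        rasters = [np.full((1, 1), v) for v in (300.0, 600.0, 900.0)]
        s = seasonal_pixel_stats(rasters)
        assert s.mean_area[0, 0] == 600.0 and s.n_overpasses[0, 0] == 3

    def test_always_cloudy_pixel_is_missing(self):
        rasters = [np.full((1, 2), np.nan), np.array([[np.nan, 5.0]])]
        s = seasonal_pixel_stats(rasters)
        assert np.isnan(s.mean_area[0, 0]) and s.n_overpasses[0, 0] == 0
        assert s.mean_area[0, 1] == 5.0 and s.stderr[0, 1] == 0.0  # n=1

    def test_stderr_matches_brute_force(self, rng):
        stack = rng.random((5, 6, 6)) * 100
        stack[rng.random((5, 6, 6)) < 0.3] = np.nan
        s = seasonal_pixel_stats(list(stack))
        for r in range(6):
            for c in range(6):
                vals = stack[:, r, c]
                vals = vals[~np.isnan(vals)]
                if len(vals) == 0:
                    assert np.isnan(s.mean_area[r, c])
                elif len(vals) == 1:
                    assert s.stderr[r, c] == 0.0
                else:
                    expected = np.std(vals, ddof=1) / np.sqrt(len(vals))
                    assert s.stderr[r, c] == pytest.approx(expected)


class TestHabitatMask:
    def test_never_kelp_empty(self):
        assert not derive_habitat_mask([np.zeros((3, 3))] * 4).any()

    def test_single_detection_is_habitat(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        b[1, 2] = 0.01
        hab = derive_habitat_mask([a, b])
        assert hab.sum() == 1 and hab[1, 2]

    def test_matches_set_union_oracle(self, rng):
        rasters = [np.where(rng.random((5, 5)) < 0.2, rng.random((5, 5)), 0.0)
                   for _ in range(6)]
        hab = derive_habitat_mask(rasters)
        oracle = set()
        for f in rasters:
            for r in range(5):
                for c in range(5):
                    if f[r, c] > 0:
                        oracle.add((r, c))
        assert hab.sum() == len(oracle)


def _one_cell_setup(n=4, observed_missing=0):
    """n x n cell, all pixels habitat; first `observed_missing` pixels n=0."""
    geom = GridGeometry(y0=n * 30.0)
    cell = CellPolygon(id="c", x0=0, y0=0, x1=n * 30.0, y1=n * 30.0)
    mean = np.full((n, n), 100.0)
    nobs = np.full((n, n), 3)
    flat = nobs.reshape(-1)
    flat[:observed_missing] = 0
    m = mean.reshape(-1)
    m[:observed_missing] = np.nan
    stats = seasonal_pixel_stats([mean])  # shape template; overwrite below
    stats.mean_area, stats.n_overpasses = mean, nobs
    stats.stderr = np.zeros((n, n))
    habitat = np.ones((n, n), dtype=bool)
    mask = cell_pixel_mask(cell, geom, (n, n))
    return stats, mask, habitat


class TestCellQuarterRule:
    def test_simple_sum(self):
        stats, mask, hab = _one_cell_setup()
        stats.mean_area[:] = 0.0
        stats.mean_area[0, 0] = 450.0
        stats.mean_area[0, 1] = 450.0
        rec = aggregate_cell_quarter(stats, mask, hab)
        assert rec["area_m2"] == 900.0 and not rec["missing"]

    def test_exactly_25_percent_unobserved_kept(self):
        stats, mask, hab = _one_cell_setup(n=4, observed_missing=4)  # 4/16 = 25%
        rec = aggregate_cell_quarter(stats, mask, hab)
        assert not rec["missing"]
        assert rec["cloud_fraction"] == pytest.approx(0.25)

    def test_more_than_25_percent_unobserved_missing(self):
        stats, mask, hab = _one_cell_setup(n=4, observed_missing=5)  # 31% > 25%
        rec = aggregate_cell_quarter(stats, mask, hab)
        assert rec["missing"] and np.isnan(rec["area_m2"])

    def test_cell_outside_raster_rejected(self):
        stats, _, hab = _one_cell_setup()
        geom = GridGeometry(y0=120.0)
        far = CellPolygon(id="far", x0=1e6, y0=1e6, x1=2e6, y1=2e6)
        with pytest.raises(ValueError, match="overlap"):
            aggregate_cell_quarter(
                stats, cell_pixel_mask(far, geom, (4, 4)), hab
            )

    def test_matches_naive_double_loop_on_random_cells(self, rng):
        geom = GridGeometry(y0=20 * 30.0)
        H = W = 20
        for trial in range(20):
            mean = rng.random((H, W)) * 100
            nobs = rng.integers(0, 3, size=(H, W))
            mean[nobs == 0] = np.nan
            stats = seasonal_pixel_stats([mean])
            stats.mean_area, stats.n_overpasses = mean, nobs
            stats.stderr = np.zeros((H, W))
            habitat = rng.random((H, W)) < 0.8
            r0, c0 = rng.integers(0, 10, 2)
            h, w = rng.integers(4, 10, 2)
            cell = CellPolygon(
                id=f"t{trial}", x0=c0 * 30.0, x1=(c0 + w) * 30.0,
                y0=(H - r0 - h) * 30.0, y1=(H - r0) * 30.0,
            )
            mask = cell_pixel_mask(cell, geom, (H, W))
            rec = aggregate_cell_quarter(stats, mask, habitat)
            # naive oracle
            in_cell = [
                (r, c)
                for r in range(H)
                for c in range(W)
                if c0 * 30 <= (c + 0.5) * 30 < (c0 + w) * 30
                and (H - r0 - h) * 30 <= geom.y0 - (r + 0.5) * 30 < (H - r0) * 30
            ]
            hab_px = [(r, c) for r, c in in_cell if habitat[r, c]]
            unobs = sum(1 for r, c in hab_px if nobs[r, c] == 0)
            miss = len(hab_px) > 0 and unobs / len(hab_px) > 0.25
            assert rec["missing"] == miss
            if not miss:
                total = sum(
                    mean[r, c] for r, c in hab_px if not np.isnan(mean[r, c])
                )
                assert rec["area_m2"] == pytest.approx(total)


class TestHabitatFilter:
    def _cells_with_counts(self, counts):
        geom = GridGeometry(y0=30.0 * 40)
        habitat = np.zeros((40, len(counts) * 30), dtype=bool)
        cells = []
        for i, n in enumerate(counts):
            cells.append(
                CellPolygon(id=f"c{i}", x0=i * 900.0, x1=(i + 1) * 900.0,
                            y0=0.0, y1=1200.0)
            )
            flat = np.zeros(40 * 30, dtype=bool)
            flat[:n] = True
            habitat[:, i * 30 : (i + 1) * 30] = flat.reshape(40, 30)
        return cells, habitat, geom

    def test_499_excluded_500_retained(self):
        cells, habitat, geom = self._cells_with_counts([499, 500])
        kept, counts = filter_cells_by_habitat(cells, habitat, geom, 500)
        assert [c.id for c in kept] == ["c1"]
        assert counts == {"c0": 499, "c1": 500}

    def test_matches_brute_force_filter(self, rng):
        counts = rng.integers(0, 60, size=50).tolist()
        cells, habitat, geom = self._cells_with_counts(counts)
        kept, _ = filter_cells_by_habitat(cells, habitat, geom, 25)
        expected = [f"c{i}" for i, n in enumerate(counts) if n >= 25]
        assert [c.id for c in kept] == expected


class TestAnnualMax:
    @pytest.mark.parametrize(
        "quarters, expected",
        [
            ((100, 400, 200, 150), 400.0),
            ((100, np.nan, np.nan, 150), np.nan),
            ((100, np.nan, 200, 150), 200.0),
        ],
    )
    def test_missing_quarter_rule(self, quarters, expected):
        out = annual_max(quarters)
        if np.isnan(expected):
            assert np.isnan(out)
        else:
            assert out == expected

    def test_annual_max_dominates_quarters(self, rng):
        rows = []
        for year in range(2000, 2010):
            for q in range(1, 5):
                v = rng.random() * 100 if rng.random() > 0.2 else np.nan
                rows.append(dict(cell_id="c", year=year, quarter=q, area_m2=v))
        quarterly = pd.DataFrame(rows)
        annual = annual_max_table(quarterly)
        for _, row in annual.iterrows():
            if not np.isnan(row.area_m2):
                q = quarterly[quarterly.year == row.year]["area_m2"]
                assert row.area_m2 >= np.nanmin(q) and row.area_m2 == np.nanmax(q)


class TestRegionalAnnual:
    def _annual(self, values, n_missing):
        return pd.DataFrame(
            [
                dict(cell_id=f"c{i}", year=2000, area_m2=v, n_missing_quarters=m)
                for i, (v, m) in enumerate(zip(values, n_missing))
            ]
        )

    def test_simple_sum(self):
        annual = self._annual([1e6, 2e6, 3e6, 4e6], [0, 0, 0, 0])
        out = regional_annual(annual, {"r": [f"c{i}" for i in range(4)]})
        assert out.iloc[0].area_m2 == 10e6 and not out.iloc[0].missing

    def test_three_of_four_cells_bad_year_missing(self):
        annual = self._annual([1, np.nan, np.nan, np.nan], [0, 2, 2, 3])
        out = regional_annual(annual, {"r": [f"c{i}" for i in range(4)]})
        assert out.iloc[0].missing and np.isnan(out.iloc[0].area_m2)

    def test_exactly_half_bad_not_missing(self):
        annual = self._annual([1.0, 2.0, np.nan, np.nan], [0, 0, 2, 2])
        out = regional_annual(annual, {"r": [f"c{i}" for i in range(4)]})
        assert not out.iloc[0].missing
        assert out.iloc[0].area_m2 == 3.0  # missing cells contribute 0

    def test_strict_missing_propagation(self):
        annual = self._annual([1.0, 2.0, np.nan, 4.0], [0, 0, 2, 0])
        out = regional_annual(
            annual, {"r": [f"c{i}" for i in range(4)]}, strict_missing=True
        )
        assert out.iloc[0].missing

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="no cells"):
            regional_annual(self._annual([1.0], [0]), {"r": []})


def test_conservation_against_scene_totals(pipeline_run):
    """Sum of retained-cell quarterly areas never exceeds the scene total."""
    res = pipeline_run
    pixel_area = res.config.pixel_area
    # per quarter: total estimated area over all pixels vs sum over cells
    for (year, quarter), grp in res.quarterly.groupby(["year", "quarter"]):
        cells_sum = grp["area_m2"].sum()  # NaN-missing cells excluded by sum
        if np.isnan(cells_sum):
            continue
        idx = [
            i for i, a in enumerate(res.acquisitions)
            if a.year == year and a.quarter == quarter
        ]
        stack = np.stack([res.fraction_rasters[i] for i in idx]) * pixel_area
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scene_total = np.nansum(np.nanmean(stack, axis=0))
        assert cells_sum <= scene_total + 1e-6
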