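"""Equal-area gridding, cell metrics, deviation score and LOESS profiles."""

import numpy as np
import pandas as pd
import pytest
from conftest import SEED
from hypothesis import given, settings, strategies as st

from latdiv.spatial import (
    EqualAreaGrid,
    cell_deviation,
    cell_metrics,
    grid_index,
    latitudinal_profile,
    loess,
)

GRID = EqualAreaGrid()


def _occ(rows, with_climate=True):
    cols = ["species", "lon", "lat"]
    if with_climate:
        cols += ["mat", "mtwm", "mtdq"]
    return pd.DataFrame(rows, columns=cols)


class TestGrid:
    def test_origin_cell(self):
        col, row = GRID.cell_of(0.0, 0.0)
        assert (col, row) == (0, 0)

    def test_projection_roundtrip(self):
        lon, lat = np.array([-120.0, 3.5, 77.0]), np.array([-60.0, 12.0, 48.0])
        x, y = GRID.project(lon, lat)
        lon2, lat2 = GRID.unproject(x, y)
        assert np.allclose(lon, lon2) and np.allclose(lat, lat2)

    def test_equatorial_points_150km_apart_differ(self):
        # 150 km east of a cell-aligned point must fall in the next cell
        x0 = 0.0
        lon0, lat0 = GRID.unproject(x0, 0.0)
        lon1, _ = GRID.unproject(x0 + 150_000.0, 0.0)
        c0 = GRID.cell_of(lon0, lat0)
        c1 = GRID.cell_of(lon1, lat0)
        assert c0 != c1

    def test_identical_point_identical_cell(self):
        assert GRID.cell_of(33.3, 44.4) == GRID.cell_of(33.3, 44.4)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            GRID.cell_of(np.nan, 10.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        lon=st.floats(-179.9, 179.9),
        lat=st.floats(-84.0, 84.0),
    )
    def test_cell_assignment_consistent_with_centroid(self, lon, lat):
        """A cell's centroid must map back into the same cell (the cell
        index <-> centroid mapping is a bijection on occupied cells)."""
        col, row = GRID.cell_of(lon, lat)
        clon, clat = GRID.cell_centroid(col, row)
        assert GRID.cell_of(float(clon), float(clat)) == (col, row)


class TestCellMetrics:
    def test_hand_aggregation(self):
        # three species co-occurring in one cell, far from a singleton cell
        rows = [
            ("s1", 10.0, 40.0, 5.0, 13.0, -5.0),
            ("s2", 10.1, 40.05, 5.0, 13.0, -5.0),
            ("s2", 10.1, 40.06, 7.0, 15.0, -3.0),
            ("s3", 10.05, 40.1, 6.0, 14.0, -4.0),
            ("lone", 100.0, -20.0, 20.0, 28.0, 10.0),
        ]
        ages = pd.Series({"s1": 10.0, "s2": 5.0, "s3": 1.0, "lone": 2.5})
        dr = pd.Series({"s1": 0.1, "s2": 0.2, "s3": 0.3, "lone": 0.4})
        cells = cell_metrics(_occ(rows), ages, dr, GRID)
        assert len(cells) == 2
        big = cells[cells["richness"] == 3].iloc[0]
        assert big["evo_time_ma"] == 10.0
        assert big["mean_dr"] == pytest.approx(0.2)
        assert big["present_mat"] == pytest.approx((5 + 5 + 7 + 6) / 4)
        lone = cells[cells["richness"] == 1].iloc[0]
        assert lone["evo_time_ma"] == 2.5 and lone["mean_dr"] == 0.4

    def test_species_missing_from_tree_counts_in_richness_only(self):
        rows = [("known", 10.0, 40.0, 5, 6, 4), ("alien", 10.0, 40.0, 5, 6, 4)]
        ages = pd.Series({"known": 3.0})
        dr = pd.Series({"known": 0.5})
        cells = cell_metrics(_occ(rows), ages, dr, GRID)
        assert cells["richness"].iloc[0] == 2
        assert cells["evo_time_ma"].iloc[0] == 3.0

    def test_evo_time_monotone_under_added_species(self):
        base = [("a", 10.0, 40.0, 5, 6, 4)]
        extra = base + [("b", 10.0, 40.0, 5, 6, 4)]
        ages = pd.Series({"a": 2.0, "b": 9.0})
        dr = pd.Series({"a": 0.5, "b": 0.1})
        t1 = cell_metrics(_occ(base), ages, dr, GRID)["evo_time_ma"].iloc[0]
        t2 = cell_metrics(_occ(extra), ages, dr, GRID)["evo_time_ma"].iloc[0]
        assert t2 >= t1

    def test_richness_matches_bruteforce_distinct_count(self):
        rng = np.random.default_rng(SEED)
        n = 1000
        occ = pd.DataFrame(
            {
                "species": rng.choice([f"sp{i}" for i in range(40)], size=n),
                "lon": rng.uniform(-170, 170, size=n),
                "lat": rng.uniform(-75, 75, size=n),
            }
        )
        ages = pd.Series(1.0, index=[f"sp{i}" for i in range(40)])
        dr = pd.Series(0.5, index=ages.index)
        cells = cell_metrics(occ, ages, dr, GRID)
        indexed = grid_index(occ, GRID)
        brute = (
            indexed.groupby(["cell_col", "cell_row"])["species"].nunique()
        )
        assert cells["richness"].sort_index().equals(brute.sort_index())
        assert cells["richness"].sum() >= occ["species"].nunique()


class TestCellDeviation:
    def _cells(self, mats):
        return pd.DataFrame(
            {
                "richness": 1,
                "present_mat": mats,
                "present_mtwm": [m + 8 for m in mats],
                "present_mtdq": [m - 10 for m in mats],
                "centroid_lat": np.linspace(10, 50, len(mats)),
            }
        )

    def test_zero_when_present_equals_ancestral(self):
        cells = self._cells([6.0, 6.0, 6.0])
        out = cell_deviation(cells, {"mat": 6.0, "mtwm": 14.0, "mtdq": -4.0})
        assert (out["deviation"] == 0.0).all()

    def test_minmax_normalization_values(self):
        cells = self._cells([8.0, 10.0, 12.0])  # raw deltas 2, 4, 6
        out = cell_deviation(cells, {"mat": 6.0, "mtwm": 14.0, "mtdq": -4.0})
        assert out["delta_mat_norm"].tolist() == pytest.approx([0.0, 0.5, 1.0])
        assert out["deviation"].tolist() == pytest.approx([0.0, 1.5, 3.0])

    def test_invariant_under_unit_rescaling(self):
        cells = self._cells([3.0, 9.0, 4.5, 7.2])
        roots = {"mat": 6.0, "mtwm": 14.0, "mtdq": -4.0}
        a = cell_deviation(cells, roots)
        scaled = cells.copy()
        for c in ("present_mat", "present_mtwm", "present_mtdq"):
            scaled[c] = scaled[c] * 10
        b = cell_deviation(scaled, {k: v * 10 for k, v in roots.items()})
        assert np.allclose(a["deviation"], b["deviation"])

    def test_missing_present_climate_gives_nan(self):
        cells = self._cells([8.0, 10.0, 12.0])
        cells.loc[1, "present_mat"] = np.nan
        out = cell_deviation(cells, {"mat": 6.0, "mtwm": 14.0, "mtdq": -4.0})
        assert np.isnan(out["deviation"].iloc[1])
        assert np.isfinite(out["deviation"].iloc[0])


class TestLatitudinalProfile:
    def test_loess_exact_on_constants(self):
        x = np.linspace(0, 60, 80)
        y = np.full_like(x, 3.3)
        out = loess(x, y, np.array([5.0, 30.0, 55.0]))
        assert np.allclose(out, 3.3, atol=1e-12)

    def test_gaussian_peak_recovered(self):
        rng = np.random.default_rng(SEED)
        lat = rng.uniform(10, 80, size=400)
        val = np.exp(-0.5 * ((lat - 45) / 5) ** 2) + rng.normal(0, 0.03, 400)
        cells = pd.DataFrame({"centroid_lat": lat, "richness": val})
        prof = latitudinal_profile(cells, "richness", span=0.3)
        assert abs(prof.peak_latitude - 45.0) <= 2.0

    def test_empty_band_is_nan_not_zero(self):
        lat = np.concatenate([np.linspace(10, 20, 30), np.linspace(40, 50, 30)])
        cells = pd.DataFrame({"centroid_lat": lat, "richness": 1.0})
        prof = latitudinal_profile(cells, "richness")
        gap = prof.band_means.query("30 < band_center_lat < 40")
        assert gap["mean"].isna().all() and (gap["n_cells"] == 0).all()

    def test_too_few_cells_rejected(self):
        cells = pd.DataFrame({"centroid_lat": [1.0, 2.0], "richness": [1, 2]})
        with pytest.raises(ValueError, match="few"):
            latitudinal_profile(cells, "richness")
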