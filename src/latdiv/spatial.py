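"""Equal-area grid macroecology: per-cell richness, evolutionary time,
mean DR, deviation-from-ancestral-niche score, and latitudinal profiles.

The grid lives in a cylindrical equal-area (Behrmann, standard parallel
30 deg) projection with 100 km x 100 km half-open cells anchored at the
projection origin. The deviation score per cell is the sum of the three
min-max-normalized absolute differences |present mean - ancestral root
state| for MAT, MTWM and MTDQ, so it ranges over [0, 3]. Latitudinal
trends are modeled with a hand-rolled LOESS (tricube weights, local
polynomials, default degree 2, span 0.75).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EqualAreaGrid",
    "grid_index",
    "cell_metrics",
    "cell_deviation",
    "latitudinal_profile",
    "loess",
    "LatProfile",
]

EARTH_RADIUS_M = 6_371_007.181  # authalic sphere radius


@dataclass(frozen=True)
class EqualAreaGrid:
    """Cylindrical equal-area grid with half-open square cells.

    x = R cos(phi_s) * lon_rad, y = R sin(lat) / cos(phi_s); with the
    default standard parallel phi_s = 30 deg this is the Behrmann
    projection. Cell (col, row) covers [col*s, (col+1)*s) x
    [row*s, (row+1)*s) in projected meters (s = ``cell_size_m``).
    """

    cell_size_m: float = 100_000.0
    standard_parallel_deg: float = 30.0
    radius_m: float = EARTH_RADIUS_M

    @property
    def _cos_sp(self) -> float:
        return float(np.cos(np.radians(self.standard_parallel_deg)))

    def project(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = self.radius_m * self._cos_sp * np.radians(lon)
        y = self.radius_m * np.sin(np.radians(lat)) / self._cos_sp
        return x, y

    def unproject(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = np.degrees(x / (self.radius_m * self._cos_sp))
        sin_lat = np.clip(y * self._cos_sp / self.radius_m, -1.0, 1.0)
        return lon, np.degrees(np.arcsin(sin_lat))

    def cell_of(self, lon, lat):
        """(col, row) integer indices; raises on non-finite coordinates."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
            raise ValueError("non-finite coordinate passed to the grid")
        x, y = self.project(lon, lat)
        col = np.floor(x / self.cell_size_m).astype(int)
        row = np.floor(y / self.cell_size_m).astype(int)
        return col, row

    def cell_centroid(self, col, row):
        """Centroid (lon, lat) of cells given by integer indices."""
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        x = (col + 0.5) * self.cell_size_m
        y = (row + 0.5) * self.cell_size_m
        return self.unproject(x, y)


def grid_index(table: pd.DataFrame, grid: EqualAreaGrid) -> pd.DataFrame:
    """Append integer cell indices (cell_col, cell_row) to a lon/lat table."""
    out = table.copy()
    col, row = grid.cell_of(out["lon"].to_numpy(), out["lat"].to_numpy())
    out["cell_col"] = col
    out["cell_row"] = row
    return out


def cell_metrics(
    occurrences: pd.DataFrame,
    ages: pd.Series,
    dr: pd.Series,
    grid: EqualAreaGrid | None = None,
) -> pd.DataFrame:
    """Aggregate per-cell richness, evolutionary time, mean DR and climate.

    richness: distinct species with >= 1 record in the cell;
    evolutionary time: max species age over those species (Ma);
    mean DR: arithmetic mean of their tip DR values (each species counted
    once however many records it has);
    mean climate: record-level mean of extracted MAT/MTWM/MTDQ.
    Species absent from ``ages``/``dr`` count toward richness but are
    excluded from the age/DR aggregates (logged). Cells with no records do
    not appear.
    """
    if grid is None:
        grid = EqualAreaGrid()
    occ = occurrences
    if "cell_col" not in occ.columns:
        occ = grid_index(occ, grid)
    covered = set(ages.index) & set(dr.index)
    uncovered = sorted(set(occ["species"]) - covered)
    if uncovered:
        logger.info(
            "%d species lack tree statistics; counted in richness only: %s",
            len(uncovered), uncovered[:5],
        )
    key = ["cell_col", "cell_row"]
    cell_species = occ[key + ["species"]].drop_duplicates()
    richness = cell_species.groupby(key).size().rename("richness")
    with_stats = cell_species[cell_species["species"].isin(covered)]
    evo = (
        with_stats.assign(age=lambda d: ages.loc[d["species"]].to_numpy())
        .groupby(key)["age"].max().rename("evo_time_ma")
    )
    mean_dr = (
        with_stats.assign(dr=lambda d: dr.loc[d["species"]].to_numpy())
        .groupby(key)["dr"].mean().rename("mean_dr")
    )
    parts = [richness, evo, mean_dr]
    for var in ("mat", "mtwm", "mtdq"):
        if var in occ.columns:
            parts.append(occ.groupby(key)[var].mean().rename(f"present_{var}"))
    cells = pd.concat(parts, axis=1)
    cols = np.array([c for c, _ in cells.index])
    rows = np.array([r for _, r in cells.index])
    lon, lat = grid.cell_centroid(cols, rows)
    cells["centroid_lon"] = lon
    cells["centroid_lat"] = lat
    return cells


def _minmax(col: pd.Series) -> pd.Series:
    lo, hi = col.min(), col.max()
    if not np.isfinite(hi - lo) or hi == lo:
        return pd.Series(0.0, index=col.index)
    return (col - lo) / (hi - lo)


def cell_deviation(
    cells: pd.DataFrame, ancestral_roots: dict[str, float]
) -> pd.DataFrame:
    """Deviation-from-ancestral-niche score per cell.

    For each variable v in MAT/MTWM/MTDQ: delta_v = |present mean -
    ancestral root state|, min-max normalized across all listed cells
    (constant columns normalize to 0); the score is the sum of the three
    normalized deltas. Cells with a missing present-climate mean get NaN.
    """
    out = cells.copy()
    norm_cols = []
    for var in ("mat", "mtwm", "mtdq"):
        pres = f"present_{var}"
        if pres not in out.columns:
            raise KeyError(f"cells table lacks {pres}; aggregate climate first")
        if var not in ancestral_roots:
            raise KeyError(f"no ancestral root state for {var!r}")
        out[f"delta_{var}"] = (out[pres] - float(ancestral_roots[var])).abs()
        out[f"delta_{var}_norm"] = _minmax(out[f"delta_{var}"].dropna()).reindex(out.index)
        norm_cols.append(f"delta_{var}_norm")
    out["deviation"] = out[norm_cols].sum(axis=1, skipna=False)
    return out


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    At each evaluation point the ``ceil(span * n)`` nearest observations
    are fit with a weighted polynomial of the given degree (reduced
    automatically when the window holds too few distinct x values) and the
    fit is evaluated at the point. Exactly reproduces constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for LOESS")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    out = np.empty(np.asarray(x_eval, dtype=float).shape)
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - np.clip(d[idx] / dmax, 0, 1) ** 3) ** 3
        w = np.maximum(w, 1e-12)  # keep the boundary point from zeroing out
        deg = min(degree, len(np.unique(x[idx])) - 1)
        coeffs = np.polyfit(x[idx] - x0, y[idx], deg, w=np.sqrt(w))
        out[i] = coeffs[-1]  # polynomial evaluated at x = x0
    return out


@dataclass
class LatProfile:
    """Latitudinal trend of one cell metric."""

    metric: str
    lat_grid: np.ndarray
    smoothed: np.ndarray
    band_means: pd.DataFrame  # band_center_lat, mean, n_cells (NaN mean if empty)

    @property
    def peak_latitude(self) -> float:
        return float(self.lat_grid[np.nanargmax(self.smoothed)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lat": self.lat_grid, self.metric: self.smoothed})


def latitudinal_profile(
    cells: pd.DataFrame,
    metric: str,
    band_deg: float = 1.0,
    span: float = 0.75,
    degree: int = 2,
    grid_step_deg: float = 0.5,
) -> LatProfile:
    """LOESS trend of a per-cell metric against centroid latitude.

    Raw per-band means (``band_deg`` wide) are reported alongside the
    smooth; bands without cells carry NaN, not zero. Requires >= 5 cells
    with the metric present.
    """
    if metric not in cells.columns:
        raise KeyError(f"no column {metric!r} in the cell table")
    sub = cells[["centroid_lat", metric]].dropna()
    if len(sub) < 5:
        raise ValueError(f"too few cells ({len(sub)}) with metric {metric!r}")
    lat = sub["centroid_lat"].to_numpy()
    val = sub[metric].to_numpy()
    lo = np.floor(lat.min() / band_deg) * band_deg
    hi = np.ceil(lat.max() / band_deg) * band_deg
    edges = np.arange(lo, hi + band_deg, band_deg)
    centers = edges[:-1] + band_deg / 2
    which = np.digitize(lat, edges) - 1
    means = np.full(centers.shape, np.nan)
    counts = np.zeros(centers.shape, dtype=int)
    for b in range(len(centers)):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = val[sel].mean()
    band_means = pd.DataFrame(
        {"band_center_lat": centers, "mean": means, "n_cells": counts}
    )
    lat_grid = np.arange(lat.min(), lat.max() + grid_step_deg / 2, grid_step_deg)
    smoothed = loess(lat, val, lat_grid, span=span, degree=degree)
    return LatProfile(metric=metric, lat_grid=lat_grid, smoothed=smoothed,
                      band_means=band_means)
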