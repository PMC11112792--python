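"""Occurrence-record cleaning, climate extraction, and climate-variable
selection.

Cleaning applies five filters in a fixed order, and a record's flag is the
first filter it triggers:

1. ``missing`` — longitude or latitude absent, unparseable, or outside
   [-180, 180] x [-90, 90];
2. ``equal_latlon`` — latitude exactly equals longitude (the origin (0, 0)
   is left to filter 3, which owns zero coordinates);
3. ``zero_or_integer`` — latitude or longitude is zero, or both are
   integer-valued (the common GBIF-cleaning reading; configurable);
4. ``in_sea`` — the point is not covered by the land mask;
5. ``out_of_range`` — the point falls outside the species' native-range
   polygon (skipped, with a log note, for species without a range).

Variable selection prunes pairwise Pearson collinearity greedily and then
summarizes the retained variables with a PCA on standardized columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union
from shapely.prepared import prep
from sklearn.decomposition import PCA

from .simulate import ClimateField

logger = logging.getLogger(__name__)

__all__ = ["FILTERS", "QCResult", "clean_occurrences", "extract_climate",
           "select_variables", "VariableSelectionReport"]

#: Filter names in application order.
FILTERS = ("missing", "equal_latlon", "zero_or_integer", "in_sea", "out_of_range")


@dataclass
class QCResult:
    """Flagged occurrence table plus per-filter removal counts."""

    table: pd.DataFrame  # all input records with a 'qc_flag' column
    counts: dict[str, int]

    @property
    def clean(self) -> pd.DataFrame:
        out = self.table[self.table["qc_flag"] == "pass"]
        return out.drop(columns=["qc_flag"]).reset_index(drop=True)

    @property
    def flags(self) -> pd.Series:
        return self.table["qc_flag"]


def _as_float(v) -> float:
    try:
        out = float(v)
    except (TypeError, ValueError):
        return np.nan
    return out


def clean_occurrences(
    table: pd.DataFrame,
    land_mask=None,
    ranges: dict | None = None,
    filters: tuple[str, ...] = FILTERS,
    integer_rule: str = "either_zero_or_both_integer",
) -> QCResult:
    """Apply the enabled cleaning filters in canonical order.

    ``integer_rule`` controls filter 3: ``either_zero_or_both_integer``
    (default) removes records with a zero coordinate or with both
    coordinates integer-valued; ``any_integer`` removes records with any
    integer coordinate. Cleaning is idempotent: survivors pass every
    enabled filter.
    """
    unknown = set(filters) - set(FILTERS)
    if unknown:
        raise ValueError(f"unknown filters: {sorted(unknown)}")
    if integer_rule not in ("either_zero_or_both_integer", "any_integer"):
        raise ValueError(f"unknown integer_rule {integer_rule!r}")
    enabled = set(filters)

    land_prep = None
    if land_mask is not None and "in_sea" in enabled:
        land_prep = prep(unary_union(list(land_mask)))
    range_prep = {}
    if ranges is not None and "out_of_range" in enabled:
        range_prep = {sp: prep(poly) for sp, poly in ranges.items()}
    no_range_species: set[str] = set()

    lons = table["lon"].map(_as_float) if len(table) else pd.Series(dtype=float)
    lats = table["lat"].map(_as_float) if len(table) else pd.Series(dtype=float)

    flags = []
    for i in table.index:
        lon, lat = lons[i], lats[i]
        flag = "pass"
        if "missing" in enabled and (
            not np.isfinite(lon) or not np.isfinite(lat)
            or not (-180 <= lon <= 180) or not (-90 <= lat <= 90)
        ):
            flag = "missing"
        elif "equal_latlon" in enabled and lat == lon and lat != 0:
            flag = "equal_latlon"
        elif "zero_or_integer" in enabled and _integer_violation(lon, lat, integer_rule):
            flag = "zero_or_integer"
        elif land_prep is not None and not land_prep.covers(Point(lon, lat)):
            flag = "in_sea"
        elif "out_of_range" in enabled and ranges is not None:
            sp = table.at[i, "species"]
            pr = range_prep.get(sp)
            if pr is None:
                no_range_species.add(sp)
            elif not pr.covers(Point(lon, lat)):
                flag = "out_of_range"
        flags.append(flag)

    if no_range_species:
        logger.info(
            "native-range filter skipped for %d species without a range polygon",
            len(no_range_species),
        )
    out = table.copy()
    out["qc_flag"] = flags
    counts = {f: int(sum(fl == f for fl in flags)) for f in FILTERS}
    return QCResult(table=out, counts=counts)


def _integer_violation(lon: float, lat: float, rule: str) -> bool:
    if lat == 0 or lon == 0:
        return True
    lon_int, lat_int = float(lon).is_integer(), float(lat).is_integer()
    if rule == "any_integer":
        return lon_int or lat_int
    return lon_int and lat_int


def extract_climate(table: pd.DataFrame, climate: ClimateField) -> pd.DataFrame:
    """Nearest-cell extraction of MAT/MTWM/MTDQ for each record.

    Records outside the raster extent or on nodata cells get NaN values
    (logged); downstream means skip them.
    """
    out = table.copy()
    lon = out["lon"].to_numpy(dtype=float)
    lat = out["lat"].to_numpy(dtype=float)
    for var in ("mat", "mtwm", "mtdq"):
        out[var] = np.atleast_1d(climate.value_at(lon, lat, var))
    n_bad = int(out["mat"].isna().sum())
    if n_bad:
        logger.info("%d records out of extent or on nodata cells", n_bad)
    return out


@dataclass
class VariableSelectionReport:
    """Collinearity-pruning and PCA summary of a climate-variable matrix."""

    correlation: pd.DataFrame
    removed: list[tuple[str, tuple[str, str]]]  # (variable, triggering pair)
    retained: list[str]
    pc_variance_fractions: np.ndarray  # all components, non-increasing
    contributions: pd.Series  # share of each variable in PC1+PC2

    @property
    def pc12_variance(self) -> float:
        return float(self.pc_variance_fractions[:2].sum())


def select_variables(
    matrix: pd.DataFrame, threshold: float = 0.75
) -> VariableSelectionReport:
    """Prune collinear variables, then run a PCA on what remains.

    While any pair has |r| >= threshold, the member of the worst pair with
    the larger mean |r| against all other variables is dropped (ties break
    toward the later column). Zero-variance columns are dropped first with
    a warning. PCA is on standardized columns; per-variable contributions
    are squared loadings weighted by the explained variances of PC1-PC2.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("need at least 2 variables and 3 records")
    work = matrix.astype(float).dropna()
    zero_var = [c for c in work.columns if work[c].std(ddof=0) == 0]
    removed: list[tuple[str, tuple[str, str]]] = []
    for c in zero_var:
        logger.warning("variable %r has zero variance; removed", c)
        removed.append((c, (c, c)))
    work = work.drop(columns=zero_var)

    corr_full = work.corr()
    cols = list(work.columns)
    while len(cols) >= 2:
        sub = corr_full.loc[cols, cols].abs()
        np.fill_diagonal(sub.values, 0.0)
        worst = sub.stack().idxmax()
        if sub.loc[worst] < threshold:
            break
        a, b = worst
        mean_a = sub.loc[a].drop([a]).mean()
        mean_b = sub.loc[b].drop([b]).mean()
        drop = a if mean_a > mean_b else b  # tie -> b, the later column
        removed.append((drop, (a, b)))
        cols.remove(drop)

    retained = cols
    if len(retained) < 2:
        raise ValueError("fewer than 2 variables survive collinearity pruning")
    x = work[retained].to_numpy()
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    pca = PCA()
    pca.fit(z)
    fractions = pca.explained_variance_ratio_
    w = pca.explained_variance_[:2]
    load_sq = pca.components_[:2] ** 2  # rows are unit vectors
    contrib = (w[:, None] * load_sq).sum(axis=0) / w.sum()
    return VariableSelectionReport(
        correlation=corr_full,
        removed=removed,
        retained=retained,
        pc_variance_fractions=fractions,
        contributions=pd.Series(contrib, index=retained, name="pc12_contribution"),
    )
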