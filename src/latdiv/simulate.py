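"""Seeded synthetic inputs with the statistical structure the analysis
assumes: birth-death chronograms (optionally paleotemperature-forced),
Brownian-motion thermal niches, a latitudinally structured climate field,
linear paleotemperature curves, and occurrence records with injected
quality-control violations mirroring the five cleaning filters.

Everything returns a :class:`SimTruth` record alongside its product so that
parameter-recovery and filter-recall checks can be scored against ground
truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.ops import unary_union
from shapely.prepared import prep

from .paleo import PaleoCurve, make_paleo_curve
from .divmodels import RateFunctionSpec, env_rate_function
from .trees import Chronogram, _assign_node_ids

logger = logging.getLogger(__name__)

__all__ = [
    "SimTruth",
    "ClimateField",
    "simulate_bd_tree",
    "simulate_bm_traits",
    "make_climate_field",
    "make_paleo_curve",
    "make_land_mask",
    "generate_occurrences",
]

CORRUPTION_MECHANISMS = (
    "missing",
    "equal_latlon",
    "zero_or_integer",
    "in_sea",
    "out_of_range",
)


@dataclass
class SimTruth:
    """Ground truth recorded by the generators; fields are filled by
    whichever generator produced the object."""

    seed: int | None = None
    # birth-death tree truth
    lambda0: float | None = None
    mu0: float | None = None
    alpha_lambda: float | None = None
    alpha_mu: float | None = None
    rate_form: str | None = None
    crown_age: float | None = None
    n_attempts: int | None = None
    # Brownian-motion trait truth
    root_state: float | None = None
    sigma2: float | None = None
    node_states: dict[str, float] | None = None
    # occurrence truth
    niche_optima: Optional[pd.Series] = None
    record_mechanism: Optional[pd.Series] = None  # 'clean' or a filter name
    ranges: dict | None = None


# ---- birth-death chronograms --------------------------------------------


class _Lineage:
    __slots__ = ("idx", "parent", "birth", "death", "children")

    def __init__(self, idx, parent, birth):
        self.idx = idx
        self.parent = parent
        self.birth = birth  # forward time from the crown
        self.death = None  # forward time; None = extant at the present
        self.children = []


def simulate_bd_tree(
    lambda0: float,
    mu0: float,
    crown_age: float,
    paleo: PaleoCurve | None = None,
    alpha: float = 0.0,
    form: str = "constant",
    min_tips: int = 2,
    max_tips: int = 20000,
    seed: int = 0,
    max_retries: int = 1000,
    alpha_mu: float = 0.0,
    mu_form: str | None = None,
) -> tuple[Chronogram, SimTruth]:
    """Forward simulation of a (possibly time-inhomogeneous) birth-death
    tree from two crown lineages, conditioned on both surviving and on at
    least ``min_tips`` extant sampled tips.

    Rates lambda(t), mu(t) are built exactly as the likelihood builds them
    (t in Ma before present). Time-inhomogeneity is handled by thinning:
    candidate event times are drawn at a bounding rate (grid maximum of
    lambda+mu inflated by 5%) and accepted with probability rate/bound.
    Extinct lineages are pruned; output is ultrametric with crown age
    exactly ``crown_age``.
    """
    if lambda0 < 0 or mu0 < 0 or crown_age <= 0:
        raise ValueError("need lambda0 >= 0, mu0 >= 0, crown_age > 0")
    if mu_form is None:
        mu_form = "none" if mu0 == 0 else ("constant" if form == "constant" else form)
    spec = RateFunctionSpec(
        lambda_form=form,
        mu_form=mu_form,
        lambda0=lambda0,
        alpha_lambda=alpha,
        mu0=mu0,
        alpha_mu=alpha_mu,
    )
    lam, mu = env_rate_function(spec, paleo)
    grid = np.linspace(0.0, crown_age, 4097)
    bound = float(np.max(lam(grid) + mu(grid))) * 1.05
    if bound <= 0:
        raise ValueError("total event rate is zero everywhere; no speciation possible")
    rng = np.random.default_rng(seed)

    for attempt in range(1, max_retries + 1):
        lineages = [_Lineage(0, None, 0.0), _Lineage(1, None, 0.0)]
        active = [0, 1]
        s = 0.0
        overflow = False
        while active:
            total_bound = bound * len(active)
            s += rng.exponential(1.0 / total_bound)
            if s >= crown_age:
                break
            t_back = crown_age - s
            li = active[rng.integers(len(active))]
            u = rng.uniform()
            lam_t = float(lam(t_back))
            mu_t = float(mu(t_back))
            if u < lam_t / bound:
                a = _Lineage(len(lineages), li, s)
                lineages.append(a)
                b = _Lineage(len(lineages), li, s)
                lineages.append(b)
                lineages[li].children = [a.idx, b.idx]
                lineages[li].death = s
                active.remove(li)
                active.extend([a.idx, b.idx])
                if len(active) > max_tips:
                    overflow = True
                    break
            elif u < (lam_t + mu_t) / bound:
                lineages[li].death = s
                active.remove(li)
        if overflow:
            continue
        survivors = set(active)
        if len(survivors) < max(min_tips, 2):
            continue
        # both crown lineages must have extant descendants
        def has_survivor(idx):
            stack = [idx]
            while stack:
                j = stack.pop()
                if j in survivors:
                    return True
                stack.extend(lineages[j].children)
            return False

        if not (has_survivor(0) and has_survivor(1)):
            continue
        chrono = _build_chronogram(lineages, survivors, crown_age)
        truth = SimTruth(
            seed=seed,
            lambda0=lambda0,
            mu0=mu0,
            alpha_lambda=alpha,
            alpha_mu=alpha_mu,
            rate_form=form,
            crown_age=crown_age,
            n_attempts=attempt,
        )
        return chrono, truth
    raise RuntimeError(
        f"birth-death simulation failed to meet min_tips={min_tips} with both "
        f"crown lineages surviving after {max_retries} attempts"
    )


def _build_chronogram(lineages, survivors, crown_age) -> Chronogram:
    """Prune extinct lineages and convert to an ultrametric Chronogram."""
    keep = set()

    def mark(idx):
        # mark ancestors of a surviving lineage
        while idx is not None and idx not in keep:
            keep.add(idx)
            idx = lineages[idx].parent

    for idx in survivors:
        mark(idx)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    label_counter = [0]

    def build(idx):
        """Return the dendropy node for lineage idx with unifurcations
        suppressed; ages in Ma before present."""
        ln = lineages[idx]
        kept_children = [c for c in ln.children if c in keep]
        while len(kept_children) == 1:
            ln = lineages[kept_children[0]]
            kept_children = [c for c in ln.children if c in keep]
        nd = dendropy.Node()
        if not kept_children:  # extant tip
            label_counter[0] += 1
            nd.taxon = taxon_ns.new_taxon(label=f"sp{label_counter[0]:04d}")
            nd.age_ma = 0.0
        else:
            nd.age_ma = crown_age - ln.death
            for c in kept_children:
                nd.add_child(build(c))
        return nd

    root = dendropy.Node()
    root.age_ma = float(crown_age)
    root.add_child(build(0))
    root.add_child(build(1))
    tree.seed_node = root
    tree.is_rooted = True
    chrono = Chronogram(tree)
    chrono.copy_with_recomputed_edges()
    _assign_node_ids(tree)
    return chrono


# ---- Brownian-motion traits ---------------------------------------------


def simulate_bm_traits(
    chrono: Chronogram, root_state: float, sigma2: float, seed: int = 0
) -> tuple[pd.Series, SimTruth]:
    """Evolve a trait along the tree under Brownian motion.

    Each branch adds an independent Gaussian increment with mean 0 and
    variance sigma2 * branch length. Returns tip states and, in the truth
    record, every internal node's true state keyed by node id.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    states: dict = {}
    node_states: dict[str, float] = {}
    tips = {}
    for nd in chrono.tree.preorder_node_iter():
        if nd.parent_node is None:
            states[nd] = float(root_state)
        else:
            bl = nd.parent_node.age_ma - nd.age_ma
            states[nd] = states[nd.parent_node] + rng.normal(0.0, np.sqrt(sigma2 * bl))
        if nd.is_leaf():
            tips[nd.taxon.label] = states[nd]
        else:
            node_states[nd.node_id] = states[nd]
    truth = SimTruth(
        seed=seed, root_state=float(root_state), sigma2=float(sigma2),
        node_states=node_states,
    )
    return pd.Series(tips, name="trait").sort_index(), truth


# ---- climate field -------------------------------------------------------


@dataclass
class ClimateField:
    """Regular lon-lat rasters of MAT, MTWM and MTDQ in deg C.

    Row 0 is the northernmost row; cell centers are at
    lon = -180 + (j + 0.5) * cell_deg, lat = 90 - (i + 0.5) * cell_deg.
    """

    mat: np.ndarray
    mtwm: np.ndarray
    mtdq: np.ndarray
    cell_deg: float
    nodata: float = -9999.0

    @property
    def shape(self):
        return self.mat.shape

    def cell_index(self, lon, lat):
        """(row, col) of the cell containing each point; None-safe arrays."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon + 180.0) / self.cell_deg).astype(int)
        row = np.floor((90.0 - lat) / self.cell_deg).astype(int)
        nrow, ncol = self.shape
        col = np.clip(col, None, ncol - 1)  # lon = 180 wraps onto last col
        row = np.clip(row, None, nrow - 1)  # lat = -90 edge
        return row, col

    def in_extent(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90)

    def value_at(self, lon, lat, var: str = "mat"):
        """Nearest-cell lookup; NaN outside the extent or on nodata cells."""
        arr = getattr(self, var)
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        ok = self.in_extent(lon, lat) & np.isfinite(lon) & np.isfinite(lat)
        out = np.full(lon.shape, np.nan)
        if ok.any():
            row, col = self.cell_index(lon[ok], lat[ok])
            vals = arr[row, col]
            vals = np.where(vals == self.nodata, np.nan, vals)
            out[ok] = vals
        return out if out.size > 1 else float(out[0])

    def lat_of_rows(self) -> np.ndarray:
        nrow = self.shape[0]
        return 90.0 - (np.arange(nrow) + 0.5) * self.cell_deg


def make_climate_field(
    equator_temp: float = 27.0,
    lat_gradient: float = 0.55,
    warm_offset: float = 8.0,
    cold_offset: float = 10.0,
    noise_sd: float = 0.5,
    cell_deg: float = 1.0,
    seed: int = 0,
) -> ClimateField:
    """Latitudinally structured temperature surfaces.

    MAT(lat) = equator_temp - lat_gradient * |lat| + noise;
    MTWM = MAT + warm_offset; MTDQ = MAT - cold_offset. The defaults give a
    roughly Earth-like equator-to-pole MAT span (27 to about -22 deg C) and
    seasonal offsets of order 10 deg C.
    """
    if warm_offset <= 0 or cold_offset <= 0:
        raise ValueError("offsets must be > 0")
    if (360.0 / cell_deg) % 1 or (180.0 / cell_deg) % 1:
        raise ValueError("cell_deg must divide 180 and 360")
    nrow = int(round(180.0 / cell_deg))
    ncol = int(round(360.0 / cell_deg))
    lat = 90.0 - (np.arange(nrow) + 0.5) * cell_deg
    rng = np.random.default_rng(seed)
    base = equator_temp - lat_gradient * np.abs(lat)[:, None]
    noise = rng.normal(0.0, noise_sd, size=(nrow, ncol)) if noise_sd > 0 else 0.0
    mat = np.broadcast_to(base + noise, (nrow, ncol)).copy()
    return ClimateField(
        mat=mat,
        mtwm=mat + warm_offset,
        mtdq=mat - cold_offset,
        cell_deg=float(cell_deg),
    )


# ---- land mask and occurrences ------------------------------------------


def make_land_mask():
    """Two rectangular synthetic continents; everything else is sea.

    A western landmass (Americas-like) and a large eastern one
    (Eurasia/Africa-like). Crude by design: the analysis only needs a
    land/sea dichotomy and room for latitudinal structure.
    """
    west = box(-170.0, -55.0, -55.0, 72.0)
    east = box(-20.0, -40.0, 150.0, 75.0)
    return [west, east]


def generate_occurrences(
    chrono: Chronogram,
    niche: pd.Series,
    field: ClimateField,
    n_per_species: int = 30,
    spatial_sd: float = 3.0,
    dirty_fraction: float = 0.1,
    land_mask=None,
    ranges: dict | None = None,
    range_halfwidth: tuple[float, float] = (25.0, 12.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Clustered occurrence records around each species' thermal niche.

    For each species the latitude band (northern hemisphere) whose mean MAT
    best matches its niche optimum is found; a range polygon is centered on
    a random on-land point of that band; clean records are Gaussian
    scatters (sd ``spatial_sd`` degrees) accepted inside land and range. A
    ``dirty_fraction`` of records is then corrupted by one of five
    mechanisms mirroring the cleaning filters: coordinate deleted, latitude
    set equal to longitude, both coordinates rounded to integers, point
    moved into the sea, or point moved outside the species' range polygon
    (but kept on land). The mechanism per record is in the truth table.
    """
    if not (0 <= dirty_fraction < 1):
        raise ValueError("dirty_fraction must be in [0, 1)")
    species = chrono.tip_labels
    missing = [sp for sp in species if sp not in niche.index]
    if missing:
        raise KeyError(f"species missing from the niche map: {missing[:5]}")
    if land_mask is None:
        land_mask = make_land_mask()
    land = unary_union(land_mask)
    land_prep = prep(land)
    rng = np.random.default_rng(seed)

    lat_rows = field.lat_of_rows()
    north = lat_rows >= 0
    row_mean_mat = np.nanmean(np.where(field.mat == field.nodata, np.nan, field.mat), axis=1)

    lon_min, lat_min, lon_max, lat_max = land.bounds
    out_ranges = {}
    rows = []
    mechs = []

    def sample_land_point(center=None, sd=None, within=None, outside=None, max_tries=2000):
        for _ in range(max_tries):
            if center is None:
                lon = rng.uniform(lon_min, lon_max)
                lat = rng.uniform(lat_min, lat_max)
            else:
                lon = rng.normal(center[0], sd)
                lat = rng.normal(center[1], sd)
            if not (-180 <= lon <= 180 and -90 <= lat <= 90):
                continue
            p = Point(lon, lat)
            if not land_prep.covers(p):
                continue
            if within is not None and not within.covers(p):
                continue
            if outside is not None and outside.covers(p):
                continue
            if lat == lon or lat == 0 or lon == 0:
                continue
            if float(lat).is_integer() and float(lon).is_integer():
                continue
            return lon, lat
        raise RuntimeError("rejection sampling for an occurrence point failed")

    def sample_sea_point(max_tries=2000):
        for _ in range(max_tries):
            lon = rng.uniform(-180.0, 180.0)
            lat = rng.uniform(-90.0, 90.0)
            p = Point(lon, lat)
            if land_prep.covers(p):
                continue
            if lat == lon or float(lat).is_integer() and float(lon).is_integer():
                continue
            return lon, lat
        raise RuntimeError("rejection sampling for a sea point failed")

    for sp in species:
        opt = float(niche.loc[sp])
        cand = np.where(north)[0]
        center_row = cand[np.argmin(np.abs(row_mean_mat[cand] - opt))]
        center_lat = float(lat_rows[center_row])
        if ranges is not None and sp in ranges:
            rng_poly = ranges[sp]
            cx, cy = rng_poly.centroid.x, rng_poly.centroid.y
        else:
            # random on-land longitude at the species' latitude band
            cy = center_lat
            for _ in range(2000):
                cx = rng.uniform(lon_min, lon_max)
                if land_prep.covers(Point(cx, cy)):
                    break
            else:
                raise RuntimeError(f"no land found at latitude {cy:.1f}")
            hw, hh = range_halfwidth
            rng_poly = box(
                max(cx - hw, -180.0), max(cy - hh, -90.0),
                min(cx + hw, 180.0), min(cy + hh, 90.0),
            )
        out_ranges[sp] = rng_poly
        for _ in range(n_per_species):
            lon, lat = sample_land_point(
                center=(cx, cy), sd=spatial_sd, within=rng_poly
            )
            mech = "clean"
            if rng.uniform() < dirty_fraction:
                mech = CORRUPTION_MECHANISMS[rng.integers(5)]
                if mech == "missing":
                    if rng.uniform() < 0.5:
                        lon = np.nan
                    else:
                        lat = np.nan
                elif mech == "equal_latlon":
                    if abs(lon) <= 90:
                        lat = lon
                    else:
                        lon = lat
                elif mech == "zero_or_integer":
                    lon, lat = float(round(lon)), float(round(lat))
                elif mech == "in_sea":
                    lon, lat = sample_sea_point()
                elif mech == "out_of_range":
                    lon, lat = sample_land_point(outside=rng_poly)
            rows.append((sp, lon, lat))
            mechs.append(mech)

    table = pd.DataFrame(rows, columns=["species", "lon", "lat"])
    truth = SimTruth(
        seed=seed,
        niche_optima=niche.loc[species].copy(),
        record_mechanism=pd.Series(mechs, index=table.index, name="mechanism"),
        ranges=out_ranges,
    )
    return table, truth
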