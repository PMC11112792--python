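"""Pipeline orchestration: one structured config, seeded determinism,
stage products and a manifest.

Stages run in dependency order: simulate -> clean -> niche -> divrate ->
spatial -> profile. Each stage writes tab-delimited products into the
output directory; the manifest records inputs, derived stage seeds,
package version and per-stage row counts so a run is self-describing.
Identical config and seed give byte-identical products (no timestamps).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from . import io as ldio
from .divmodels import DEFAULT_MODELS, fit_all_models
from .niche import reconstruct_niche, species_climate_means
from .paleo import PaleoCurve, make_paleo_curve
from .qc import clean_occurrences, extract_climate
from .simulate import (
    generate_occurrences,
    make_climate_field,
    make_land_mask,
    simulate_bd_tree,
    simulate_bm_traits,
)
from .spatial import EqualAreaGrid, cell_deviation, cell_metrics, latitudinal_profile
from .trees import Chronogram, dr_statistic, read_chronogram, tip_species_ages, write_chronogram

logger = logging.getLogger(__name__)

STAGES = ("simulate", "clean", "niche", "divrate", "spatial", "profile")


class SimulateConfig(BaseModel):
    """Synthetic-world parameters; defaults emulate a temperate-origin
    clade radiating under Cenozoic-style cooling."""

    lambda0: float = 0.16          # /Ma, speciation scale
    mu0: float = 0.0               # /Ma, extinction scale
    alpha: float = -0.055          # per deg C, temperature dependence
    form: str = "exponential"      # rate form used by the generator
    crown_age: float = 37.44       # Ma
    min_tips: int = 100
    max_tips: int = 4000
    paleo_t0: float = 2.0          # deg C at present
    paleo_slope: float = 0.2       # deg C per Ma (warmer past)
    root_mat: float = 6.66         # deg C, BM root state for the MAT optimum
    sigma2: float = 1.0            # deg C^2 / Ma
    n_per_species: int = 30
    spatial_sd: float = 3.0        # degrees
    dirty_fraction: float = 0.1
    climate_cell_deg: float = 1.0
    climate_noise_sd: float = 0.5
    equator_temp: float = 27.0
    lat_gradient: float = 0.55     # deg C per degree latitude


class CleanConfig(BaseModel):
    filters: list[str] = Field(
        default_factory=lambda: [
            "missing", "equal_latlon", "zero_or_integer", "in_sea", "out_of_range",
        ]
    )
    integer_rule: str = "either_zero_or_both_integer"


class DivrateConfig(BaseModel):
    sampling_fraction: float = 1.0
    starts: int = 2
    models: Optional[list[str]] = None  # subset of registry names; None = all


class SpatialConfig(BaseModel):
    cell_size_m: float = 100_000.0
    standard_parallel_deg: float = 30.0
    band_deg: float = 1.0
    span: float = 0.75
    degree: int = 2
    metrics: list[str] = Field(
        default_factory=lambda: ["richness", "evo_time_ma", "mean_dr", "deviation"]
    )


class InputPaths(BaseModel):
    """External inputs, used by stages whose upstream stage is disabled."""

    tree: Optional[str] = None
    occurrences: Optional[str] = None
    paleo: Optional[str] = None
    climate_dir: Optional[str] = None
    land_mask: Optional[str] = None
    ranges: Optional[str] = None


class RunConfig(BaseModel):
    out_dir: str
    seed: int = 0
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    inputs: InputPaths = Field(default_factory=InputPaths)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    clean: CleanConfig = Field(default_factory=CleanConfig)
    divrate: DivrateConfig = Field(default_factory=DivrateConfig)
    spatial: SpatialConfig = Field(default_factory=SpatialConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


class ConfigError(ValueError):
    """A config that fails cross-field validation; message names the field."""


def _stage_seed(master: int, stage: str) -> int:
    return (int(master) * 1_000_003 + STAGES.index(stage) + 1) % (2**31 - 1)


def validate_config(cfg: RunConfig) -> None:
    bad = set(cfg.stages) - set(STAGES)
    if bad:
        raise ConfigError(f"stages: unknown stage names {sorted(bad)}")
    have_sim = "simulate" in cfg.stages
    if not have_sim:
        if "clean" in cfg.stages and cfg.inputs.occurrences is None:
            raise ConfigError(
                "inputs.occurrences is required when 'clean' runs without 'simulate'"
            )
        if "clean" in cfg.stages and cfg.inputs.climate_dir is None:
            raise ConfigError(
                "inputs.climate_dir is required when 'clean' runs without 'simulate'"
            )
        if ("divrate" in cfg.stages or "niche" in cfg.stages) and cfg.inputs.tree is None:
            raise ConfigError(
                "inputs.tree is required when 'divrate' or 'niche' runs "
                "without 'simulate'"
            )
        if "divrate" in cfg.stages and cfg.inputs.paleo is None:
            raise ConfigError(
                "inputs.paleo is required when 'divrate' runs without 'simulate'"
            )
    for path_field in ("tree", "occurrences", "paleo", "climate_dir", "land_mask", "ranges"):
        p = getattr(cfg.inputs, path_field)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"inputs.{path_field}: path {p!r} does not exist")


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Execute the enabled stages; returns (and writes) the manifest."""
    validate_config(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, str, str]] = [
        ("run", "latdiv_version", __version__),
        ("run", "master_seed", str(cfg.seed)),
    ]
    cfg.to_yaml(out / "config_used.yaml")

    state: dict = {}

    if "simulate" in cfg.stages:
        _run_simulate(cfg, out, state, manifest)
    else:
        _load_inputs(cfg, state)

    if "clean" in cfg.stages:
        _run_clean(cfg, out, state, manifest)
    if "niche" in cfg.stages:
        _run_niche(cfg, out, state, manifest)
    if "divrate" in cfg.stages:
        _run_divrate(cfg, out, state, manifest)
    if "spatial" in cfg.stages:
        _run_spatial(cfg, out, state, manifest)
    if "profile" in cfg.stages:
        _run_profile(cfg, out, state, manifest)

    mdf = pd.DataFrame(manifest, columns=["stage", "key", "value"])
    mdf.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return mdf


def _load_inputs(cfg: RunConfig, state: dict) -> None:
    ins = cfg.inputs
    if ins.tree:
        state["tree"] = read_chronogram(ins.tree)
    if ins.occurrences:
        state["occurrences"] = ldio.read_occurrences(ins.occurrences)
    if ins.paleo:
        state["paleo"] = PaleoCurve.read(ins.paleo)
    if ins.climate_dir:
        state["climate"] = ldio.read_climate_field(ins.climate_dir)
    if ins.land_mask:
        state["land_mask"] = list(ldio.read_polygons(ins.land_mask).values())
    if ins.ranges:
        state["ranges"] = ldio.read_polygons(ins.ranges)


def _run_simulate(cfg, out, state, manifest):
    sc = cfg.simulate
    seed = _stage_seed(cfg.seed, "simulate")
    paleo = make_paleo_curve(sc.paleo_t0, sc.paleo_slope, sc.crown_age * 1.05)
    paleo.write(out / "paleo.tsv")
    tree, bd_truth = simulate_bd_tree(
        lambda0=sc.lambda0, mu0=sc.mu0, crown_age=sc.crown_age, paleo=paleo,
        alpha=sc.alpha, form=sc.form, min_tips=sc.min_tips, max_tips=sc.max_tips,
        seed=seed,
    )
    write_chronogram(tree, out / "tree.nwk")
    traits, bm_truth = simulate_bm_traits(tree, sc.root_mat, sc.sigma2, seed=seed + 1)
    climate = make_climate_field(
        equator_temp=sc.equator_temp, lat_gradient=sc.lat_gradient,
        noise_sd=sc.climate_noise_sd, cell_deg=sc.climate_cell_deg, seed=seed + 2,
    )
    ldio.write_climate_field(climate, out / "climate")
    land = make_land_mask()
    ldio.write_polygons({f"land{i}": p for i, p in enumerate(land)}, out / "land.geojson")
    occ, occ_truth = generate_occurrences(
        tree, traits, climate, n_per_species=sc.n_per_species,
        spatial_sd=sc.spatial_sd, dirty_fraction=sc.dirty_fraction,
        land_mask=land, seed=seed + 3,
    )
    ldio.write_polygons(occ_truth.ranges, out / "ranges.geojson")
    ldio.write_occurrences(occ, out / "occurrences.tsv")
    truth = occ.copy()
    truth["mechanism"] = occ_truth.record_mechanism
    ldio.write_occurrences(truth, out / "occurrences_truth.tsv")
    traits.rename_axis("species").rename("mat_optimum").to_frame().assign(
        root_state=sc.root_mat, sigma2=sc.sigma2
    ).to_csv(out / "niche_truth.tsv", sep="\t")

    state.update(
        tree=tree, paleo=paleo, climate=climate, land_mask=land,
        ranges=occ_truth.ranges, occurrences=occ,
        truth={"bd": bd_truth, "bm": bm_truth, "occ": occ_truth},
    )
    manifest += [
        ("simulate", "seed", str(seed)),
        ("simulate", "n_tips", str(tree.n_tips)),
        ("simulate", "crown_age_ma", str(tree.crown_age)),
        ("simulate", "bd_attempts", str(bd_truth.n_attempts)),
        ("simulate", "n_occurrence_records", str(len(occ))),
    ]


def _run_clean(cfg, out, state, manifest):
    occ = state["occurrences"]
    res = clean_occurrences(
        occ, land_mask=state.get("land_mask"), ranges=state.get("ranges"),
        filters=tuple(cfg.clean.filters), integer_rule=cfg.clean.integer_rule,
    )
    clean = extract_climate(res.clean, state["climate"])
    state["occ_clean"] = clean
    state["qc_counts"] = res.counts
    ldio.write_occurrences(clean, out / "occurrences_clean.tsv")
    pd.Series(res.counts, name="removed").rename_axis("filter").to_frame().to_csv(
        out / "qc_counts.tsv", sep="\t"
    )
    manifest += [("clean", "records_in", str(len(occ)))]
    manifest += [(f"clean", f"removed_{k}", str(v)) for k, v in res.counts.items()]
    manifest += [("clean", "records_out", str(len(clean)))]


def _run_niche(cfg, out, state, manifest):
    niche_tab = species_climate_means(state["occ_clean"])
    tree = state["tree"]
    anc = reconstruct_niche(tree, niche_tab)
    state["species_niche"] = niche_tab
    state["ancestral"] = anc
    state["ancestral_roots"] = {v: a.root_state for v, a in anc.items()}
    niche_tab.rename_axis("species").to_csv(out / "species_niche.tsv", sep="\t")
    for v, a in anc.items():
        a.to_frame().to_csv(out / f"ancestral_{v}.tsv", sep="\t")
    roots = pd.DataFrame(
        {
            "variable": list(anc),
            "root_state": [a.root_state for a in anc.values()],
            "root_variance": [a.root_variance for a in anc.values()],
            "sigma2": [a.sigma2 for a in anc.values()],
        }
    )
    roots.to_csv(out / "ancestral_roots.tsv", sep="\t", index=False)
    manifest += [("niche", "n_species_with_niche", str(len(niche_tab)))]
    manifest += [
        ("niche", f"root_{v}", format(a.root_state, ".6g")) for v, a in anc.items()
    ]


def _run_divrate(cfg, out, state, manifest):
    tree = state["tree"]
    ages = tip_species_ages(tree)
    dr = dr_statistic(tree)
    tips = pd.DataFrame({"age_ma": ages, "dr_per_ma": dr}).rename_axis("species")
    tips.to_csv(out / "tip_stats.tsv", sep="\t")
    state["tip_ages"] = ages
    state["tip_dr"] = dr
    dc = cfg.divrate
    models = DEFAULT_MODELS
    if dc.models is not None:
        models = tuple(m for m in DEFAULT_MODELS if m.name in set(dc.models))
        if not models:
            raise ConfigError("divrate.models selected no model from the registry")
    seed = _stage_seed(cfg.seed, "divrate")
    fits, ranking = fit_all_models(
        tree, state.get("paleo"), sampling_fraction=dc.sampling_fraction,
        models=models, starts=dc.starts, seed=seed,
    )
    ranking.to_csv(out / "model_selection.tsv", sep="\t", index=False)
    state["model_ranking"] = ranking
    manifest += [
        ("divrate", "seed", str(seed)),
        ("divrate", "n_tip_rows", str(len(tips))),
        ("divrate", "best_model", str(ranking["model"].iloc[0])),
        ("divrate", "best_aicc", format(ranking["AICc"].iloc[0], ".6g")),
    ]


def _run_spatial(cfg, out, state, manifest):
    sp = cfg.spatial
    grid = EqualAreaGrid(
        cell_size_m=sp.cell_size_m, standard_parallel_deg=sp.standard_parallel_deg
    )
    ages = state.get("tip_ages")
    dr = state.get("tip_dr")
    if ages is None:
        tree = state["tree"]
        ages, dr = tip_species_ages(tree), dr_statistic(tree)
    cells = cell_metrics(state["occ_clean"], ages, dr, grid)
    if "ancestral_roots" in state:
        cells = cell_deviation(cells, state["ancestral_roots"])
    cells.rename_axis(["cell_col", "cell_row"]).to_csv(out / "cells.tsv", sep="\t")
    state["cells"] = cells
    state["grid"] = grid
    manifest += [
        ("spatial", "projection", f"cea_sp{sp.standard_parallel_deg:g}"),
        ("spatial", "cell_size_m", format(sp.cell_size_m, "g")),
        ("spatial", "n_cells", str(len(cells))),
        ("spatial", "total_richness", str(int(cells["richness"].sum()))),
    ]


def _run_profile(cfg, out, state, manifest):
    sp = cfg.spatial
    cells = state["cells"]
    frames = []
    for metric in sp.metrics:
        if metric not in cells.columns:
            continue
        prof = latitudinal_profile(
            cells, metric, band_deg=sp.band_deg, span=sp.span, degree=sp.degree
        )
        f = prof.to_frame().rename(columns={metric: "value"})
        f.insert(0, "metric", metric)
        frames.append(f)
        manifest.append(
            ("profile", f"peak_lat_{metric}", format(prof.peak_latitude, ".4g"))
        )
    profs = pd.concat(frames, ignore_index=True)
    profs.to_csv(out / "profiles.tsv", sep="\t", index=False)
    state["profiles"] = profs
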