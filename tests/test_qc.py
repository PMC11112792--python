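"""Occurrence cleaning filters, climate extraction and variable selection."""

import numpy as np
import pandas as pd
import pytest
from conftest import SEED
from shapely.geometry import box

from latdiv.qc import FILTERS, clean_occurrences, extract_climate, select_variables
from latdiv.simulate import (
    ClimateField,
    generate_occurrences,
    make_climate_field,
    make_land_mask,
    simulate_bd_tree,
    simulate_bm_traits,
)


@pytest.fixture()
def seven_record_fixture():
    land = [box(-10, -10, 60, 60)]
    ranges = {"sp": box(0.5, 0.5, 30, 50)}
    table = pd.DataFrame(
        {
            "species": ["sp"] * 7,
            "lon": [12.5, 33.3, 0.0, 45.0, -5.5, 40.5, 10.3],
            "lat": [None, 33.3, 0.0, 12.0, -20.5, 55.5, 20.7],
        }
    )
    return table, land, ranges


class TestCleanOccurrences:
    def test_seven_record_fixture_counts(self, seven_record_fixture):
        table, land, ranges = seven_record_fixture
        res = clean_occurrences(table, land_mask=land, ranges=ranges)
        assert res.counts == {
            "missing": 1,
            "equal_latlon": 1,
            "zero_or_integer": 2,
            "in_sea": 1,
            "out_of_range": 1,
        }
        assert len(res.clean) == 1
        assert res.clean.iloc[0]["lon"] == 10.3

    def test_idempotent(self, seven_record_fixture):
        table, land, ranges = seven_record_fixture
        once = clean_occurrences(table, land_mask=land, ranges=ranges).clean
        twice = clean_occurrences(once, land_mask=land, ranges=ranges)
        assert twice.clean.reset_index(drop=True).equals(once)
        assert sum(twice.counts.values()) == 0

    def test_empty_table(self):
        res = clean_occurrences(pd.DataFrame(columns=["species", "lon", "lat"]))
        assert len(res.clean) == 0 and all(v == 0 for v in res.counts.values())

    def test_total_removed_is_order_invariant(self, seven_record_fixture):
        """The removed set equals the union of single-filter removals, so
        total removal cannot depend on filter ordering."""
        table, land, ranges = seven_record_fixture
        union = set()
        for f in FILTERS:
            res = clean_occurrences(table, land_mask=land, ranges=ranges,
                                    filters=(f,))
            union |= set(res.table.index[res.flags != "pass"])
        res_all = clean_occurrences(table, land_mask=land, ranges=ranges)
        assert set(res_all.table.index[res_all.flags != "pass"]) == union

    def test_missing_range_polygon_skips_filter5(self, seven_record_fixture):
        table, land, _ = seven_record_fixture
        res = clean_occurrences(table, land_mask=land, ranges={})
        assert res.counts["out_of_range"] == 0
        assert len(res.clean) == 2  # the out-of-range record now survives

    def test_truth_labels_agree_with_flags(self):
        tree, _ = simulate_bd_tree(0.5, 0.0, 10.0, min_tips=40, max_tips=120,
                                   seed=SEED)
        traits, _ = simulate_bm_traits(tree, 8.0, 1.0, seed=SEED + 1)
        field = make_climate_field(seed=SEED + 2)
        occ, truth = generate_occurrences(
            tree, traits, field, n_per_species=15, dirty_fraction=0.25,
            seed=SEED + 3,
        )
        res = clean_occurrences(occ, land_mask=make_land_mask(),
                                ranges=truth.ranges)
        flags = res.flags.replace({"pass": "clean"})
        assert (flags == truth.record_mechanism).mean() >= 0.99
        # deterministic mechanisms are recalled perfectly
        for mech in ("missing", "equal_latlon", "zero_or_integer"):
            hit = truth.record_mechanism == mech
            if hit.any():
                assert (flags[hit] == mech).mean() == 1.0
        for mech in ("in_sea", "out_of_range"):
            hit = truth.record_mechanism == mech
            if hit.any():
                assert (flags[hit] == mech).mean() >= 0.95


class TestExtractClimate:
    def test_constant_field(self):
        f = make_climate_field(lat_gradient=0.0, noise_sd=0.0, cell_deg=10.0)
        tab = pd.DataFrame({"species": ["a", "b"], "lon": [3.2, -120.0],
                            "lat": [48.9, -10.0]})
        out = extract_climate(tab, f)
        assert (out["mat"] == out["mat"].iloc[0]).all()

    def test_known_cell_lookup(self):
        # 2 x 4 world of 90-degree cells with hand-set values
        mat = np.arange(8, dtype=float).reshape(2, 4)
        f = ClimateField(mat=mat, mtwm=mat + 1, mtdq=mat - 1, cell_deg=90.0)
        tab = pd.DataFrame(
            {"species": list("abcd"),
             "lon": [-135.0, -45.0, 45.0, 135.0],
             "lat": [45.0, 45.0, -45.0, -45.0]}
        )
        out = extract_climate(tab, f)
        assert out["mat"].tolist() == [0.0, 1.0, 6.0, 7.0]
        assert out["mtwm"].tolist() == [1.0, 2.0, 7.0, 8.0]

    def test_out_of_extent_flagged_nan(self):
        f = make_climate_field(cell_deg=10.0, noise_sd=0.0)
        tab = pd.DataFrame({"species": ["a"], "lon": [200.0], "lat": [10.0]})
        out = extract_climate(tab, f)
        assert np.isnan(out["mat"].iloc[0])


class TestSelectVariables:
    def test_duplicate_variable_removed(self):
        rng = np.random.default_rng(SEED)
        a = rng.normal(size=100)
        rep = select_variables(pd.DataFrame({"A": a, "B": a.copy(),
                                             "C": rng.normal(size=100)}))
        assert len(rep.removed) == 1 and rep.removed[0][0] in {"A", "B"}
        assert len(rep.retained) == 2

    def test_mean_abs_r_rule_on_constructed_triplet(self):
        # r(A,B)=0.9, r(A,C)=0.2, r(B,C)~0 -> A has the larger mean |r|
        rng = np.random.default_rng(SEED)
        n = 4000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        c = 0.2 * a + np.sqrt(1 - 0.04) * rng.normal(size=n)
        rep = select_variables(pd.DataFrame({"A": a, "B": b, "C": c}))
        assert [v for v, _ in rep.removed] == ["A"]
        sub = rep.correlation.loc[rep.retained, rep.retained].abs()
        np.fill_diagonal(sub.values, 0)
        assert (sub < 0.75).all().all()

    def test_no_op_below_threshold(self):
        rng = np.random.default_rng(SEED + 1)
        x = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("wxyz"))
        rep = select_variables(x)
        assert rep.removed == [] and rep.retained == list("wxyz")

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(SEED + 2)
        x = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        rep = select_variables(x)
        assert rep.pc_variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(rep.pc_variance_fractions) <= 1e-12)
        assert rep.contributions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_column_removed_first(self):
        rng = np.random.default_rng(SEED + 3)
        x = pd.DataFrame({"flat": np.ones(30), "a": rng.normal(size=30),
                          "b": rng.normal(size=30)})
        rep = select_variables(x)
        assert rep.removed[0][0] == "flat"
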