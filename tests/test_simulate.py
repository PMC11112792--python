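"""Synthetic-data generator: birth-death trees, BM traits, climate field,
paleo curve and occurrence records."""

import numpy as np
import pandas as pd
import pytest
from conftest import SEED, prune_to_size

from latdiv.niche import phylogenetic_independent_contrasts
from latdiv.paleo import make_paleo_curve
from latdiv.simulate import (
    generate_occurrences,
    make_climate_field,
    make_land_mask,
    simulate_bd_tree,
    simulate_bm_traits,
)
from latdiv.trees import read_chronogram


class TestBirthDeathSimulator:
    def test_zero_speciation_exhausts_retries(self):
        with pytest.raises((RuntimeError, ValueError), match="zero|attempts"):
            simulate_bd_tree(0.0, 0.0, 10.0, min_tips=3, seed=SEED, max_retries=5)

    def test_output_is_ultrametric_with_exact_crown_age(self):
        tree, truth = simulate_bd_tree(0.4, 0.15, 12.0, min_tips=10, seed=SEED)
        assert tree.crown_age == 12.0
        tree.copy_with_recomputed_edges()
        depths = []
        for lf in tree.tree.leaf_node_iter():
            d, nd = 0.0, lf
            while nd.parent_node is not None:
                d += nd.edge.length
                nd = nd.parent_node
            depths.append(d)
        assert np.allclose(depths, 12.0, atol=1e-9)
        assert truth.lambda0 == 0.4 and truth.n_attempts >= 1

    def test_determinism(self):
        from latdiv.trees import write_chronogram

        a, _ = simulate_bd_tree(0.5, 0.1, 8.0, min_tips=5, seed=99)
        b, _ = simulate_bd_tree(0.5, 0.1, 8.0, min_tips=5, seed=99)
        assert write_chronogram(a) == write_chronogram(b)

    def test_yule_tip_count_expectation(self):
        # E[N(t)] = 2 exp(lambda t) for a crown Yule process
        lam, t, reps = 0.5, 10.0, 500
        counts = [
            simulate_bd_tree(lam, 0.0, t, min_tips=2, seed=SEED + i)[0].n_tips
            for i in range(reps)
        ]
        expected = 2 * np.exp(lam * t)
        se = np.std(counts, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(counts) - expected) < 3 * se


class TestBMTraits:
    def test_zero_rate_copies_root_state(self):
        tree, _ = simulate_bd_tree(0.5, 0.0, 6.0, min_tips=5, seed=SEED)
        traits, truth = simulate_bm_traits(tree, 7.7, 0.0, seed=1)
        assert (traits == 7.7).all()
        assert set(truth.node_states.values()) == {7.7}

    def test_star_tree_variance_law(self):
        n, depth, s2 = 2000, 5.0, 2.0
        star = read_chronogram(
            "(" + ",".join(f"t{i}:{depth}" for i in range(n)) + ");"
        )
        traits, _ = simulate_bm_traits(star, 0.0, s2, seed=SEED)
        target = s2 * depth
        tol = 4 * target * np.sqrt(2 / n)  # 4 sd of the sample variance
        assert abs(traits.var(ddof=1) - target) < tol

    def test_seed_determinism(self):
        tree, _ = simulate_bd_tree(0.5, 0.0, 6.0, min_tips=8, seed=SEED)
        a, _ = simulate_bm_traits(tree, 1.0, 0.5, seed=4)
        b, _ = simulate_bm_traits(tree, 1.0, 0.5, seed=4)
        c, _ = simulate_bm_traits(tree, 1.0, 0.5, seed=5)
        assert a.equals(b) and not a.equals(c)

    def test_contrasts_standard_normal(self):
        from scipy.stats import kstest

        big, _ = simulate_bd_tree(0.65, 0.0, 10.0, min_tips=1001, seed=SEED)
        tree = prune_to_size(big, 1001, seed=SEED)
        traits, _ = simulate_bm_traits(tree, 0.0, 1.0, seed=SEED)
        u = phylogenetic_independent_contrasts(tree, traits)
        assert len(u) == 1000
        assert kstest(u, "norm").pvalue > 0.01


class TestClimateField:
    def test_flat_gradient_uniform(self):
        f = make_climate_field(lat_gradient=0.0, noise_sd=0.0, cell_deg=5.0)
        assert np.unique(f.mat).size == 1

    def test_linear_gradient_value(self):
        f = make_climate_field(
            equator_temp=25.0, lat_gradient=0.4, noise_sd=0.0, cell_deg=1.0
        )
        # 25 - 0.4 * 45 = 7 at the 45 N cell center (44.5 within the cell)
        assert f.value_at(10.0, 45.0) == pytest.approx(25 - 0.4 * 44.5)

    def test_offsets_ordered_everywhere(self):
        f = make_climate_field(noise_sd=1.0, cell_deg=5.0, seed=3)
        assert (f.mtwm >= f.mat).all() and (f.mat >= f.mtdq).all()

    def test_bad_cell_size_rejected(self):
        with pytest.raises(ValueError, match="cell_deg"):
            make_climate_field(cell_deg=7.0)


class TestPaleoCurve:
    def test_constant_curve(self):
        c = make_paleo_curve(4.0, 0.0, 20.0)
        assert c.at(0) == c.at(13.7) == 4.0

    def test_linear_interpolation(self):
        from latdiv.paleo import PaleoCurve

        c = PaleoCurve([0.0, 10.0], [2.0, 6.0])
        assert c.at(5.0) == pytest.approx(4.0)

    def test_clamped_outside_range(self):
        from latdiv.paleo import PaleoCurve

        c = PaleoCurve([0.0, 10.0], [2.0, 6.0])
        assert c.at(20.0) == 6.0 and c.at(-5.0) == 2.0

    def test_roundtrip(self, tmp_path):
        from latdiv.paleo import PaleoCurve

        c = make_paleo_curve(3.0, 0.25, 40.0, n_points=11)
        c.write(tmp_path / "p.tsv")
        back = PaleoCurve.read(tmp_path / "p.tsv")
        assert np.array_equal(back.ages, c.ages)
        assert np.array_equal(back.temps, c.temps)


@pytest.fixture(scope="module")
def world():
    tree, _ = simulate_bd_tree(0.5, 0.0, 10.0, min_tips=50, max_tips=120,
                               seed=SEED)
    traits, _ = simulate_bm_traits(tree, 8.0, 1.0, seed=SEED + 1)
    field = make_climate_field(seed=SEED + 2)
    return tree, traits, field


class TestOccurrences:

    def test_record_count(self, world):
        tree, traits, field = world
        sub = prune_to_size(tree, 10, seed=1)
        occ, _ = generate_occurrences(
            sub, traits, field, n_per_species=20, dirty_fraction=0.0, seed=SEED
        )
        assert len(occ) == 200

    def test_clean_world_passes_qc(self, world):
        from latdiv.qc import clean_occurrences

        tree, traits, field = world
        sub = prune_to_size(tree, 15, seed=2)
        occ, truth = generate_occurrences(
            sub, traits, field, n_per_species=10, dirty_fraction=0.0, seed=SEED
        )
        res = clean_occurrences(
            occ, land_mask=make_land_mask(), ranges=truth.ranges
        )
        assert len(res.clean) == len(occ)

    def test_niche_signal_recoverable(self, world):
        from latdiv.qc import extract_climate

        tree, traits, field = world
        occ, truth = generate_occurrences(
            tree, traits, field, n_per_species=15, dirty_fraction=0.0, seed=SEED
        )
        ext = extract_climate(occ, field)
        means = ext.groupby("species")["mat"].mean()
        r = np.corrcoef(means[truth.niche_optima.index], truth.niche_optima)[0, 1]
        assert r > 0.8

    def test_unknown_species_rejected(self, world):
        tree, traits, field = world
        with pytest.raises(KeyError, match="missing"):
            generate_occurrences(
                tree, traits.drop(tree.tip_labels[0]), field, seed=SEED
            )
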