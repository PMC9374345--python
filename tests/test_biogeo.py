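"""Presence-absence grids, per-pixel FD, proportional loss, pixel nulls, UIQ."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dielfd.biogeo import (
    PresenceAbsence,
    filter_range_records,
    pixel_fd,
    pixel_null,
    proportion_fd_lost,
    uiq,
)
from dielfd.core import SCENARIO_ORDER
from dielfd.dendro import (
    DistanceMatrix,
    cophenetic_matrix,
    fd_of_subset,
    tree_height,
    upgma,
)
from dielfd.synth import GeneratorParams, generate_dataset
from dielfd.traits import transform_traits
from dielfd.dendro import gower_matrix

from conftest import make_table


class TestFilterRangeRecords:
    def records(self, rows):
        return pd.DataFrame(rows, columns=["species_id", "presence", "origin", "seasonality"])

    def test_fully_coded_record_kept(self):
        recs = self.records([["a", "Extant", "Native", "Resident"]])
        assert len(filter_range_records(recs)) == 1

    def test_possibly_extinct_dropped(self):
        recs = self.records([["a", "possibly extinct", "native", "resident"]])
        assert len(filter_range_records(recs)) == 0

    def test_introduced_origin_dropped(self):
        recs = self.records([["a", "extant", "introduced", "resident"]])
        assert len(filter_range_records(recs)) == 0

    def test_unknown_code_dropped_with_warning(self):
        recs = self.records(
            [["a", "extant", "native", "resident"], ["b", "gibberish", "native", "resident"]]
        )
        with pytest.warns(UserWarning, match="unknown"):
            kept = filter_range_records(recs)
        assert list(kept["species_id"]) == ["a"]


def toy_world(statuses, niches=None, pixels=None, seed=0):
    """Species table + tree + PA matrix for a hand-sized world."""
    n = len(statuses)
    table = make_table(statuses, niches, seed=seed)
    tt = transform_traits(table)
    tree = upgma(gower_matrix(tt))
    if pixels is None:
        pixels = [list(table.species_ids)]
    species = table.species_ids
    M = np.zeros((len(pixels), n), dtype=bool)
    for i, members in enumerate(pixels):
        for s in members:
            M[i, list(species).index(s)] = True
    pa = PresenceAbsence(np.array([f"p{i}" for i in range(len(pixels))]), species, M)
    return table, tree, pa


class TestPixelFd:
    def test_toy_pixel_fd_and_exclusion(self, toy_distance):
        # the hand-traced 3-leaf tree: FD 1.6 but excluded (3 <= 5 species)
        tree = upgma(toy_distance)
        table = make_table(["LC", "LC", "CR"])
        table.df["species_id"] = ["A", "B", "C"]
        table = type(table)(table.df)
        pa = PresenceAbsence(
            np.array(["p0"]), np.array(["A", "B", "C"]), np.ones((1, 3), dtype=bool)
        )
        fd = pixel_fd(pa, tree, table, "nocturnal")
        assert fd["fd_all"].iloc[0] == pytest.approx(1.6)
        assert not fd["included"].iloc[0]

    def test_six_species_pixel_included(self):
        table, tree, pa = toy_world(["LC"] * 6)
        fd = pixel_fd(pa, tree, table, "nocturnal")
        assert fd["included"].iloc[0]

    def test_empty_pixel_excluded_with_nan(self):
        table, tree, pa = toy_world(["LC"] * 6, pixels=[[], ["sp0"] * 1])
        fd = pixel_fd(pa, tree, table, "nocturnal")
        assert np.isnan(fd["fd_all"].iloc[0])
        assert not fd["included"].any()


class TestProportionLost:
    def test_toy_loss_fraction(self, toy_distance):
        tree = upgma(toy_distance)
        df = make_table(["LC", "LC", "CR"]).df
        df["species_id"] = ["A", "B", "C"]
        table = type(make_table(["LC"]))(df)
        pa = PresenceAbsence(
            np.array(["p0"]), np.array(["A", "B", "C"]), np.ones((1, 3), dtype=bool)
        )
        out = proportion_fd_lost(pa, tree, table, "nocturnal", "CR")
        assert out["prop_lost"].iloc[0] == pytest.approx(1 - 0.4 / 1.6)  # 0.75

    def test_no_threatened_species_zero_loss(self):
        table, tree, pa = toy_world(["LC"] * 8)
        out = proportion_fd_lost(pa, tree, table, "nocturnal", "NT")
        assert out["prop_lost"].iloc[0] == 0.0

    def test_single_survivor_loses_everything(self):
        table, tree, pa = toy_world(["CR"] * 7 + ["LC"])
        out = proportion_fd_lost(pa, tree, table, "nocturnal", "CR")
        assert out["prop_lost"].iloc[0] == 1.0

    def test_matches_rebuild_from_scratch(self):
        """Per-pixel losses equal fresh FD computation on a 40-pixel map."""
        params = GeneratorParams(
            n_species=60,
            niche_proportions=(1.0, 0, 0, 0),
            grid_rows=8,
            grid_cols=5,
            baseline_threat_rate=0.35,
            seed=5,
        )
        table, _, pa = generate_dataset(params)
        tt = transform_traits(table)
        tree = upgma(gower_matrix(tt))
        coph = cophenetic_matrix(tree)
        out = proportion_fd_lost(pa, tree, table, "nocturnal", "NT")
        removed = set(
            table.df.loc[
                table.df["iucn_status"].isin(["CR", "EN", "VU", "NT"])
                | (table.df["dd_threatened"] & (table.df["iucn_status"] == "DD")),
                "species_id",
            ]
        )
        for i, row in out.iterrows():
            present = list(pa.species_in_pixel(i))
            if not present:
                continue
            survivors = [s for s in present if s not in removed]
            fd_all = fd_of_subset(coph, present)
            fd_surv = fd_of_subset(coph, survivors)
            if fd_all == 0:
                assert np.isnan(row["prop_lost"])
            else:
                assert row["prop_lost"] == pytest.approx(1 - fd_surv / fd_all)

    def test_loss_monotone_across_nested_scenarios(self):
        params = GeneratorParams(
            n_species=80,
            niche_proportions=(1.0, 0, 0, 0),
            grid_rows=6,
            grid_cols=6,
            seed=6,
        )
        table, _, pa = generate_dataset(params)
        tree = upgma(gower_matrix(transform_traits(table)))
        coph = cophenetic_matrix(tree)
        losses = [
            proportion_fd_lost(pa, coph, table, "nocturnal", s)["prop_lost"]
            for s in SCENARIO_ORDER
        ]
        for a, b in itertools.pairwise(losses):
            ok = np.isnan(a) | np.isnan(b) | (b >= a - 1e-12)
            assert ok.all()


class TestPixelNull:
    def test_zero_threat_pixels_zero_difference(self):
        table, tree, pa = toy_world(["LC"] * 8)
        out = pixel_null(pa, tree, table, "nocturnal", "NT", reps=10, seed=0)
        assert out["obs_minus_null"].iloc[0] == 0.0

    def test_isolated_leaf_removal_exceeds_null(self):
        """7-leaf star-plus-outlier: removing the outlier beats every other
        single removal, so observed minus mean-null is positive (checked
        against exhaustive enumeration)."""
        ids = np.array([f"s{i}" for i in range(7)])
        D = np.full((7, 7), 0.2)
        np.fill_diagonal(D, 0.0)
        D[6, :6] = D[:6, 6] = 0.9  # s6 is functionally dispersed
        dm = DistanceMatrix(ids, D)
        tree = upgma(dm)
        coph = cophenetic_matrix(tree)
        df = make_table(["LC"] * 6 + ["CR"]).df
        df["species_id"] = ids
        table = type(make_table(["LC"]))(df)
        pa = PresenceAbsence(np.array(["p0"]), ids, np.ones((1, 7), dtype=bool))
        out = pixel_null(pa, tree, table, "nocturnal", "CR", reps=200, seed=3)
        assert out["obs_minus_null"].iloc[0] > 0
        # exhaustive single-removal enumeration
        fd_all = tree_height(tree)
        losses = [
            1 - fd_of_subset(coph, np.delete(ids, i)) / fd_all for i in range(7)
        ]
        exact_null = np.mean(losses)
        assert out["null_mean"].iloc[0] == pytest.approx(exact_null, abs=0.02)
        assert out["prop_lost"].iloc[0] == pytest.approx(losses[6])

    def test_fixed_seed_identical_map(self):
        params = GeneratorParams(
            n_species=50,
            niche_proportions=(1.0, 0, 0, 0),
            grid_rows=4,
            grid_cols=4,
            seed=8,
        )
        table, _, pa = generate_dataset(params)
        coph = cophenetic_matrix(upgma(gower_matrix(transform_traits(table))))
        a = pixel_null(pa, coph, table, "nocturnal", "NT", reps=20, seed=11)
        b = pixel_null(pa, coph, table, "nocturnal", "NT", reps=20, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_random_threat_centers_null_difference(self):
        """With trait-independent threat the mean observed-minus-null across
        pixels and generator replicates sits at 0 within Monte-Carlo error."""
        diffs = []
        for seed in range(6):
            params = GeneratorParams(
                n_species=90,
                niche_proportions=(1.0, 0, 0, 0),
                grid_rows=5,
                grid_cols=4,
                baseline_threat_rate=0.3,
                seed=100 + seed,
            )
            table, _, pa = generate_dataset(params)
            coph = cophenetic_matrix(upgma(gower_matrix(transform_traits(table))))
            out = pixel_null(pa, coph, table, "nocturnal", "NT", reps=40, seed=seed)
            diffs.extend(out.loc[out["included"], "obs_minus_null"].dropna())
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 4 * se + 1e-3


class TestUiq:
    def test_linear_interpolation_order_statistic(self):
        assert uiq(np.arange(1, 101)) == pytest.approx(75.25)

    def test_constant_vector(self):
        assert uiq([0.4] * 9) == pytest.approx(0.4)

    def test_two_values(self):
        assert uiq([0.0, 1.0]) == pytest.approx(0.75)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            uiq([])
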