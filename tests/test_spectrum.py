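"""Trait-spectrum PCA, bandwidth selection, KDE, HDR contours, change stats."""

import math

import numpy as np
import pytest

from dielfd.core import SCENARIO_ORDER, SCENARIOS
from dielfd.spectrum import (
    GridSpec,
    density_change,
    fit_kde,
    fit_pca,
    hdr_levels,
    normal_scale_bandwidth,
    plugin_bandwidth,
    spectrum_null,
    spectrum_scenario_stats,
)
from dielfd.synth import GeneratorParams, generate_species
from dielfd.traits import transform_traits

from conftest import make_table


def naive_kde(points, data, H):
    """Brute-force double-loop Gaussian KDE (oracle)."""
    Hinv = np.linalg.inv(H)
    norm = 1.0 / (2 * np.pi * np.sqrt(np.linalg.det(H)))
    out = np.zeros(len(points))
    for i, p in enumerate(points):
        for x in data:
            d = p - x
            out[i] += norm * np.exp(-0.5 * d @ Hinv @ d)
    return out / len(data)


class TestPca:
    def test_uncorrelated_two_trait_input_recovers_axes(self):
        rng = np.random.default_rng(0)
        t = make_table(["LC"] * 200, seed=0)
        tt = transform_traits(t)
        # squash three columns to (almost) nothing, leave two dominant
        vals = tt.values.copy()
        vals.iloc[:, 2:] = rng.normal(0, 1e-6, (200, 3))
        vals.iloc[:, 0] = rng.normal(0, 2.0, 200)
        vals.iloc[:, 1] = rng.normal(0, 1.0, 200)
        tt.values = vals
        basis = fit_pca(tt)
        L = basis.loadings.to_numpy()[:2, :2]
        assert np.abs(L) == pytest.approx(np.eye(2), abs=0.05)

    def test_variance_percentages_sum_to_100(self):
        tt = transform_traits(make_table(["LC"] * 50, seed=1))
        basis = fit_pca(tt)
        assert basis.pct_variation.sum() == pytest.approx(100.0)
        assert (np.diff(basis.pct_variation) <= 1e-12).all()

    def test_scores_match_eigen_oracle(self):
        tt = transform_traits(make_table(["LC"] * 20, seed=2))
        basis = fit_pca(tt)
        X = tt.matrix()
        Xc = X - X.mean(axis=0)
        ev, V = np.linalg.eigh(np.cov(Xc, rowvar=False))
        idx = np.argsort(ev)[::-1][:2]
        expected = np.abs(Xc @ V[:, idx])
        assert np.abs(basis.scores.to_numpy()) == pytest.approx(expected, abs=1e-9)

    def test_body_mass_loading_nonnegative_on_pc1(self):
        tt = transform_traits(make_table(["LC"] * 60, seed=3))
        basis = fit_pca(tt)
        assert basis.loadings.loc["log10_body_mass", "PC1"] >= 0


class TestBandwidth:
    def test_normal_scale_closed_form(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((1000, 2))
        X = (X - X.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(X.T))).T
        # sample covariance now exactly I; n^(-1/3) = 0.1 at n = 1000
        H = normal_scale_bandwidth(X)
        assert H == pytest.approx(0.1 * np.eye(2), abs=1e-9)

    @pytest.mark.parametrize("method", ["plugin", "normal_scale"])
    def test_symmetric_positive_definite(self, method):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 2)) @ np.array([[1.0, 0.4], [0.0, 0.7]])
        H = plugin_bandwidth(X, method=method)
        assert H == pytest.approx(H.T)
        assert (np.linalg.eigvalsh(H) > 0).all()

    def test_plugin_converges_to_normal_reference_on_gaussian(self):
        # for bivariate normal data the AMISE-optimal H is n^(-1/3) Sigma
        rng = np.random.default_rng(6)
        X = rng.standard_normal((5000, 2))
        ratio = np.linalg.det(plugin_bandwidth(X)) / np.linalg.det(
            normal_scale_bandwidth(X)
        )
        assert ratio == pytest.approx(1.0, abs=0.25)

    def test_degenerate_scores_rejected(self):
        X = np.zeros((50, 2))
        with pytest.raises(ValueError, match="jitter|singular"):
            plugin_bandwidth(X, method="normal_scale")


class TestKde:
    def test_single_point_peak_density(self):
        X = np.array([[0.0, 0.0]])
        grid = GridSpec(-3, 3, -3, 3, 61, 61)
        k = fit_kde(X, np.eye(2), grid)
        assert k.density.max() == pytest.approx(1 / (2 * np.pi), rel=1e-12)

    def test_duplicated_points_same_density_as_one(self):
        grid = GridSpec(-3, 3, -3, 3, 31, 31)
        one = fit_kde(np.zeros((1, 2)), np.eye(2), grid)
        many = fit_kde(np.zeros((7, 2)), np.eye(2), grid)
        assert many.density == pytest.approx(one.density, rel=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((500, 2))
        H = normal_scale_bandwidth(X)
        grid = GridSpec.from_scores(X, n=21)
        k = fit_kde(X, H, grid)
        expected = naive_kde(grid.points(), X, H).reshape(21, 21)
        assert np.abs(k.density - expected).max() < 1e-10

    def test_integrates_to_one(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((400, 2)) @ np.array([[1.0, 0.3], [0.0, 0.8]])
        k = fit_kde(X, plugin_bandwidth(X, "normal_scale"), GridSpec.from_scores(X))
        assert k.integral == pytest.approx(1.0, abs=0.02)

    def test_grid_not_covering_data_rejected(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        with pytest.raises(ValueError, match="cover"):
            fit_kde(X, np.eye(2), GridSpec(-1, 1, -1, 1, 11, 11))


class TestHdr:
    def test_levels_ordered_and_cover_species(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((800, 2))
        k = fit_kde(X, normal_scale_bandwidth(X), GridSpec.from_scores(X))
        lv = hdr_levels(k)
        assert lv[0.5] >= lv[0.95] >= lv[0.99]
        dens = k.evaluate(X)
        frac = (dens >= lv[0.5]).mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_standard_normal_closed_form_level(self):
        # P(f(X) >= c) = 1 - 2 pi c  =>  level(q) -> (1-q)/(2 pi)
        rng = np.random.default_rng(10)
        X = rng.standard_normal((4000, 2))
        k = fit_kde(X, normal_scale_bandwidth(X), GridSpec.from_scores(X))
        lv = hdr_levels(k, quantiles=(0.5,))
        assert lv[0.5] == pytest.approx(0.5 / (2 * np.pi), rel=0.05)

    def test_invalid_quantile_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 2))
        k = fit_kde(X, np.eye(2), GridSpec.from_scores(X))
        with pytest.raises(ValueError):
            hdr_levels(k, quantiles=(1.5,))


class TestDensityChange:
    def test_identical_sets_no_change(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((60, 2))
        grid = GridSpec.from_scores(X, n=41)
        H = normal_scale_bandwidth(X)
        a = fit_kde(X, H, grid)
        b = fit_kde(X, H, grid)
        res = density_change(a, b)
        assert res.mean_abs_density_change == 0.0
        assert res.volume_loss == 0.0

    def test_empty_survivor_set_rejected(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((30, 2))
        with pytest.raises(ValueError):
            spectrum_scenario_stats(X, np.ones(30, dtype=bool), "normal_scale")

    def test_matches_brute_force_small_grid(self):
        """30-point toy, 10 clustered 'threatened' removed, 21×21 grid."""
        rng = np.random.default_rng(13)
        X = np.vstack(
            [rng.normal(0, 1, (20, 2)), rng.normal([2.5, 2.5], 0.3, (10, 2))]
        )
        removed = np.zeros(30, dtype=bool)
        removed[20:] = True
        grid = GridSpec.from_scores(X, n=21)
        res = spectrum_scenario_stats(X, removed, "normal_scale", grid=grid)

        # independent recomputation with the naive KDE
        Hf = normal_scale_bandwidth(X)
        Hs = normal_scale_bandwidth(X[~removed])
        df = naive_kde(grid.points(), X, Hf)
        ds = naive_kde(grid.points(), X[~removed], Hs)
        lf = np.quantile(naive_kde(X, X, Hf), 0.01)
        ls = np.quantile(naive_kde(X[~removed], X[~removed], Hs), 0.01)
        region = df >= lf
        delta = ds / ds.max() - df / df.max()
        exp_change = np.abs(delta[region]).mean()
        exp_vol = (region & (ds < ls)).sum() / region.sum()
        assert res.mean_abs_density_change == pytest.approx(exp_change, abs=1e-12)
        assert res.volume_loss == pytest.approx(exp_vol, abs=1e-12)

    def test_volume_loss_monotone_across_nested_scenarios(self):
        params = GeneratorParams(
            n_species=250, niche_proportions=(1.0, 0, 0, 0), beta_mass=1.0, seed=21
        )
        table, _ = generate_species(params)
        tt = transform_traits(table)
        scores = fit_pca(tt).scores.to_numpy()
        grid = GridSpec.from_scores(scores, n=51)
        losses = []
        for name in SCENARIO_ORDER:
            removed = SCENARIOS[name].removal_mask(table)
            losses.append(
                spectrum_scenario_stats(
                    scores, removed, "normal_scale", grid=grid
                ).volume_loss
            )
        assert losses == sorted(losses)

    def test_redundant_cluster_buffers_volume_loss(self):
        # removing one member of a tight cluster of near-duplicates barely
        # moves the spectrum boundary
        rng = np.random.default_rng(22)
        cluster = rng.normal(0, 0.01, (12, 2))
        spread = rng.normal(0, 1.5, (30, 2))
        X = np.vstack([cluster, spread])
        removed = np.zeros(len(X), dtype=bool)
        removed[0] = True
        res = spectrum_scenario_stats(X, removed, "normal_scale")
        assert res.volume_loss < 0.01


class TestSpectrumNull:
    def test_zero_removals_zero_null(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((40, 2))
        res = spectrum_null(
            X, np.zeros(40, dtype=bool), reps=5, seed=1, bandwidth="normal_scale"
        )
        assert res["mean_abs_density_change"].observed == 0.0
        assert (res["volume_loss"].null_values == 0).all()

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((50, 2))
        removed = np.zeros(50, dtype=bool)
        removed[:12] = True
        a = spectrum_null(X, removed, reps=8, seed=99, bandwidth="normal_scale")
        b = spectrum_null(X, removed, reps=8, seed=99, bandwidth="normal_scale")
        assert (
            a["mean_abs_density_change"].null_values
            == b["mean_abs_density_change"].null_values
        ).all()
        assert a["volume_loss"].observed == b["volume_loss"].observed

    def test_removing_all_rejected(self):
        X = np.random.default_rng(16).standard_normal((20, 2))
        with pytest.raises(ValueError):
            spectrum_null(X, np.ones(20, dtype=bool), reps=2, seed=0)
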