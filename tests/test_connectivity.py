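"""Smoothing, Pearson matrices, connected-cell statistics, colour bins."""

import math

import numpy as np
import pytest

from isletpulse import (
    IsletGeometry,
    TraceMatrix,
    analyze_connectivity,
    build_connectivity_map,
    connected_stats,
    pearson_matrix,
    rolling_smooth,
    smooth_traces,
)
from isletpulse.connectivity import COLOR_BINS, _color_bin


class TestRollingSmooth:
    def test_constant_trace_unchanged(self):
        x = np.full(100, 3.7)
        np.testing.assert_allclose(rolling_smooth(x, 0.05), x)

    def test_window_is_five_percent_of_frames(self):
        # N=100, frac=0.05 -> w=5: a central unit impulse spreads to 0.2
        x = np.zeros(100)
        x[50] = 1.0
        sm = rolling_smooth(x, 0.05)
        np.testing.assert_allclose(sm[48:53], 0.2)
        assert sm[47] == 0.0 and sm[53] == 0.0

    def test_matches_convolution_oracle_in_interior(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        sm = rolling_smooth(x, 0.05)  # w = 10
        kernel = np.ones(10) / 10
        conv = np.convolve(x, kernel, mode="same")
        # centred pandas window and 'same' convolution agree away from edges
        np.testing.assert_allclose(sm[10:-10], conv[10:-10], atol=1e-12)

    def test_preserves_length_and_mean_at_edges(self):
        x = np.arange(20, dtype=float)
        sm = rolling_smooth(x, 0.25)  # w = 5
        assert sm.size == 20
        assert sm[0] == pytest.approx(np.mean(x[:3]))  # shrunken edge window


def _tm(values, fs=1.0):
    n = values.shape[1]
    return TraceMatrix(tuple(f"c{i}" for i in range(n)), values, fs=fs)


class TestPearsonMatrix:
    def test_identical_traces_r_one(self):
        x = np.sin(np.linspace(0, 10, 200))
        r = pearson_matrix(_tm(np.column_stack([x, x, x])))
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(r[iu], 1.0)
        assert np.isnan(r[0, 0])

    def test_negated_trace_r_minus_one(self):
        x = np.sin(np.linspace(0, 10, 200))
        r = pearson_matrix(_tm(np.column_stack([x, -x])))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_white_noise_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(2000, 5))
        r = pearson_matrix(_tm(vals))
        for i in range(5):
            for j in range(i + 1, 5):
                xi, xj = vals[:, i], vals[:, j]
                oracle = np.sum((xi - xi.mean()) * (xj - xj.mean())) / math.sqrt(
                    np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2)
                )
                assert r[i, j] == pytest.approx(oracle, abs=1e-12)
                assert abs(r[i, j]) < 0.1  # independent noise, many frames
        assert np.allclose(r, r.T, equal_nan=True)

    def test_zero_variance_cell_flagged_nan(self):
        vals = np.column_stack([np.sin(np.linspace(0, 5, 50)), np.full(50, 2.0)])
        r = pearson_matrix(_tm(vals))
        assert np.isnan(r[0, 1]) and np.isnan(r[1, 0])

    def test_affine_transform_invariance(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(300, 4)) + np.sin(np.linspace(0, 20, 300))[:, None]
        r1 = pearson_matrix(_tm(vals))
        r2 = pearson_matrix(_tm(3.5 * vals + 100.0))
        np.testing.assert_allclose(r1, r2, equal_nan=True, atol=1e-12)


class TestConnectedStats:
    def test_all_pairs_one(self):
        r = np.ones((4, 4))
        np.fill_diagonal(r, np.nan)
        mean_pos, frac = connected_stats(r)
        assert (mean_pos, frac) == (1.0, 100.0)

    def test_all_pairs_zero(self):
        r = np.zeros((4, 4))
        np.fill_diagonal(r, np.nan)
        mean_pos, frac = connected_stats(r)
        assert math.isnan(mean_pos) and frac == 0.0

    def test_three_cell_hand_arithmetic(self):
        # AB=0.5, AC=0.1, BC=-0.3: mean positive = 0.3; per-cell means
        # A=0.3 (connected), B=0.1, C=-0.1 -> 1/3 connected
        r = np.array(
            [
                [np.nan, 0.5, 0.1],
                [0.5, np.nan, -0.3],
                [0.1, -0.3, np.nan],
            ]
        )
        mean_pos, frac = connected_stats(r, threshold=0.2)
        assert mean_pos == pytest.approx(0.3)
        assert frac == pytest.approx(100.0 / 3.0)

    def test_any_pair_rule_is_more_permissive(self):
        r = np.array(
            [
                [np.nan, 0.5, 0.1],
                [0.5, np.nan, -0.3],
                [0.1, -0.3, np.nan],
            ]
        )
        _, frac_any = connected_stats(r, threshold=0.2, cell_rule="any_pair")
        assert frac_any == pytest.approx(200.0 / 3.0)  # A and B have a 0.5 pair


class TestColorBins:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (0.3, "green"),
            (0.8, "red"),
            (0.1, "blue"),
            (0.25, "blue"),
            (0.26, "green"),
            (0.5, "green"),
            (0.51, "yellow"),
            (0.75, "yellow"),
            (0.76, "red"),
            (1.0, "red"),
        ],
    )
    def test_printed_two_decimal_assignment(self, r, expected):
        assert _color_bin(r) == expected

    def test_below_lowest_bin_draws_no_edge(self):
        assert _color_bin(0.05) is None

    def test_no_r_in_two_bins(self):
        for r in np.linspace(0.10, 1.0, 451):
            hits = [name for lo, hi, name in COLOR_BINS if lo <= r < hi]
            assert len(hits) == 1

    def test_map_edges_respect_threshold(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 50, size=(3, 2))
        g = IsletGeometry(("c0", "c1", "c2"), coords)
        r = np.array(
            [
                [np.nan, 0.05, 0.3],
                [0.05, np.nan, 0.8],
                [0.3, 0.8, np.nan],
            ]
        )
        cmap = build_connectivity_map(r, ("c0", "c1", "c2"), g)
        assert len(cmap.edges) == 2
        bins = dict(zip(zip(cmap.edges.cell_i, cmap.edges.cell_j), cmap.edges.color_bin))
        assert bins[("c0", "c2")] == "green"
        assert bins[("c1", "c2")] == "red"


class TestSharedSignalModel:
    """One latent response + independent per-cell noise."""

    @staticmethod
    def _simulate(noise_sd, n_cells=20, n_frames=600, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n_frames)
        latent = np.exp(-0.5 * ((t - 200) / 60.0) ** 2)
        vals = latent[:, None] + rng.normal(0, noise_sd, size=(n_frames, n_cells))
        return _tm(vals)

    def test_low_noise_limit_fully_connected(self):
        res = analyze_connectivity(self._simulate(noise_sd=1e-3))
        assert res.connected_fraction == 100.0
        assert res.mean_positive_r > 0.999

    def test_statistics_decrease_monotonically_in_noise(self):
        fracs, means = [], []
        for sd in (0.05, 0.5, 5.0):
            # average a few seeds so the trend is not a single-draw artefact
            f = m = 0.0
            for seed in range(3):
                res = analyze_connectivity(self._simulate(sd, seed=seed))
                f += res.connected_fraction / 3
                m += res.mean_positive_r / 3
            fracs.append(f)
            means.append(m)
        assert fracs[0] >= fracs[1] >= fracs[2]
        assert means[0] > means[1] > means[2]

    def test_independent_cells_fraction_vanishes_with_frames(self):
        rng = np.random.default_rng(31)
        small = _tm(rng.normal(size=(100, 10)))
        large = _tm(rng.normal(size=(5000, 10)))
        f_small = analyze_connectivity(small).connected_fraction
        f_large = analyze_connectivity(large).connected_fraction
        assert f_large <= f_small
        assert f_large == 0.0
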