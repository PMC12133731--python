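"""Weights construction and autocorrelation statistics against brute-force
formula evaluation and known closed-form cases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gtwrpanel import (
    DegenerateInputError,
    IsolateWarning,
    build_weights,
    generate_city_layout,
    getis_ord_gi_star,
    local_moran,
    min_connectivity_distance,
    morans_i,
    morans_i_by_period,
    percent_change,
    simulate_clustered_field,
    simulate_panel,
)
from gtwrpanel.spatial import read_weights_csv, write_weights_csv
from .conftest import make_config


# -- brute-force oracles (independent of the implementation) -----------------

def brute_morans_i(values, W_dense):
    n = len(values)
    z = values - values.mean()
    s0 = num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += W_dense[i, j]
            num += W_dense[i, j] * z[i] * z[j]
    return n / s0 * num / sum(zi * zi for zi in z)


def brute_local_moran(values, W_dense):
    n = len(values)
    z = values - values.mean()
    m2 = sum(zi * zi for zi in z) / n
    return np.array(
        [z[i] / m2 * sum(W_dense[i, j] * z[j] for j in range(n)) for i in range(n)]
    )


def brute_gi_star(values, W_dense):
    n = len(values)
    xbar = values.mean()
    S = np.sqrt(sum(v * v for v in values) / n - xbar**2)
    out = np.empty(n)
    for i in range(n):
        wsum = sum(W_dense[i])
        w2 = sum(w * w for w in W_dense[i])
        num = sum(W_dense[i, j] * values[j] for j in range(n)) - xbar * wsum
        den = S * np.sqrt((n * w2 - wsum**2) / (n - 1))
        out[i] = num / den
    return out


class TestBuildWeights:
    def test_knn_tie_breaks_by_id_order(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        W = build_weights(coords, scheme="knn", k=1, row_standardize=False)
        # the middle point is equidistant from both ends; lower id wins
        row = W.matrix.toarray()[1]
        assert row[0] == 1.0 and row[2] == 0.0

    def test_knn_exact_neighbor_count(self):
        coords = generate_city_layout(30, "uniform", seed=0)[["u", "v"]].to_numpy()
        W = build_weights(coords, scheme="knn", k=4, row_standardize=False)
        assert (W.neighbor_counts() == 4).all()

    def test_row_standardized_rows_sum_to_one(self):
        coords = generate_city_layout(25, "uniform", seed=1)[["u", "v"]].to_numpy()
        W = build_weights(coords, scheme="inverse_distance", row_standardize=True)
        sums = np.asarray(W.matrix.sum(axis=1)).ravel()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_infinite_band_is_complete_graph(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 100, size=(5, 2))
        W = build_weights(coords, scheme="distance_band", band_distance=np.inf,
                          row_standardize=False)
        assert W.matrix.nnz == 5 * 4  # all n(n-1) directed pairs

    def test_min_connectivity_band_leaves_no_isolates(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [100.0, 100.0]])
        W = build_weights(coords, scheme="distance_band", band_distance=None,
                          row_standardize=False)
        assert W.isolates().size == 0
        assert min_connectivity_distance(coords) == pytest.approx(np.hypot(99, 100))

    def test_small_band_warns_about_isolates(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [100.0, 100.0]])
        with pytest.warns(IsolateWarning):
            build_weights(coords, scheme="distance_band", band_distance=2.0)

    def test_k_too_large_rejected(self):
        coords = np.zeros((3, 2))
        coords[:, 0] = [0, 1, 2]
        with pytest.raises(ValueError):
            build_weights(coords, scheme="knn", k=3)

    def test_triplet_csv_round_trip(self, tmp_path):
        coords = generate_city_layout(12, "uniform", seed=5)[["u", "v"]].to_numpy()
        W = build_weights(coords, scheme="inverse_distance", row_standardize=True)
        path = tmp_path / "w.csv"
        write_weights_csv(W, path)
        W2 = read_weights_csv(path, W.ids)
        np.testing.assert_allclose(W.matrix.toarray(), W2.matrix.toarray(), atol=1e-12)
        assert W2.row_standardized


class TestGlobalMoran:
    def test_checkerboard_is_perfectly_negative(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        values = np.array([1.0, -1.0, -1.0, 1.0])
        W = build_weights(coords, scheme="distance_band", band_distance=1.0,
                          row_standardize=True)
        res = morans_i(values, W, n_permutations=0)
        assert res.statistic == pytest.approx(-1.0, abs=1e-12)

    def test_expected_value_closed_form(self, grid25):
        coords, values = grid25
        W = build_weights(coords, scheme="knn", k=4)
        res = morans_i(values, W, n_permutations=0)
        assert res.expected_value == pytest.approx(-1.0 / 24)

    def test_constant_field_degenerate(self, grid25):
        coords, _ = grid25
        W = build_weights(coords, scheme="knn", k=4)
        with pytest.raises(DegenerateInputError, match="variance"):
            morans_i(np.full(25, 3.0), W)

    def test_matches_brute_force_on_grid(self, grid25):
        coords, values = grid25
        for scheme, kw in [
            ("knn", {"k": 4}),
            ("inverse_distance", {"band_distance": 2.5}),
            ("distance_band", {"band_distance": 1.5}),
        ]:
            W = build_weights(coords, scheme=scheme, row_standardize=True, **kw)
            res = morans_i(values, W, n_permutations=0)
            assert res.statistic == pytest.approx(
                brute_morans_i(values, W.matrix.toarray()), abs=1e-9
            )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_affine_invariance(self, a, b):
        xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        rng = np.random.default_rng(7)
        values = rng.normal(size=16)
        W = build_weights(coords, scheme="knn", k=3)
        i0 = morans_i(values, W, n_permutations=0).statistic
        i1 = morans_i(a * values + b, W, n_permutations=0).statistic
        assert i1 == pytest.approx(i0, rel=1e-9, abs=1e-9)

    def test_permutation_distribution_centers_on_expectation(self, grid25):
        """Mean of the relabeled statistic over 9,999 permutations sits at
        -1/(n-1) to within Monte-Carlo error."""
        coords, values = grid25
        W = build_weights(coords, scheme="knn", k=4)
        rng = np.random.default_rng(0)
        stats = [
            morans_i(rng.permutation(values), W, n_permutations=0).statistic
            for _ in range(9999)
        ]
        mean, se = np.mean(stats), np.std(stats) / np.sqrt(len(stats))
        assert abs(mean - (-1.0 / 24)) < 4 * se

    def test_permutation_p_reproducible(self, grid25):
        coords, values = grid25
        W = build_weights(coords, scheme="knn", k=4)
        p1 = morans_i(values, W, n_permutations=499, seed=5).p_permutation
        p2 = morans_i(values, W, n_permutations=499, seed=5).p_permutation
        assert p1 == p2

    def test_isolates_are_excluded_not_fatal(self):
        coords = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1], [500, 500]])
        values = np.array([1.0, -1.0, -1.0, 1.0, 7.0])
        with pytest.warns(IsolateWarning):
            W = build_weights(coords, scheme="distance_band", band_distance=1.0,
                              row_standardize=True)
        res = morans_i(values, W, n_permutations=0)
        assert res.statistic == pytest.approx(-1.0, abs=1e-12)


class TestMoranByPeriod:
    def test_printed_period_statistics_give_printed_rise(self):
        assert percent_change(0.4589, 0.6063) == pytest.approx(32.1, abs=0.05)

    def test_identical_periods_give_zero_change(self, small_panel):
        # duplicate the panel's first two years as two fake disjoint periods
        df = small_panel.data
        a = df[df["year"] == 2012].copy()
        b = a.copy()
        b["year"] = 2013
        panel = type(small_panel)(
            data=pd.concat([a, b], ignore_index=True),
            variable_names=small_panel.variable_names,
        )
        out = morans_i_by_period(panel, [2012], [2013], n_permutations=0)
        assert out["percent_change"] == pytest.approx(0.0, abs=1e-12)

    def test_simple_arithmetic(self):
        assert percent_change(0.2, 0.1) == pytest.approx(-50.0)

    def test_zero_baseline_undefined(self):
        assert np.isnan(percent_change(0.0, 0.3))

    def test_overlapping_periods_rejected(self, small_panel):
        with pytest.raises(ValueError, match="disjoint"):
            morans_i_by_period(small_panel, [2012, 2013], [2013, 2014])


class TestLocalMoran:
    def test_matches_brute_force_on_grid(self, grid25):
        coords, values = grid25
        W = build_weights(coords, scheme="knn", k=4)
        out = local_moran(values, W, n_permutations=0, alpha=0.05)
        np.testing.assert_allclose(
            out["local_i"].to_numpy(),
            brute_local_moran(values, W.matrix.toarray()),
            atol=1e-9,
        )

    def test_hot_blob_labeled_hh(self):
        layout = generate_city_layout(120, "clustered", 6, seed=3)
        coords = layout[["u", "v"]].to_numpy()
        field = simulate_clustered_field(
            coords, hot_centers=[(250.0, 250.0)], base=10.0, amplitude=6.0,
            noise_sd=0.0, length_scale=120.0,
        )
        W = build_weights(coords)
        out = local_moran(field, W, n_permutations=999, alpha=0.05, seed=11)
        hottest = int(np.argmax(field))
        assert out["label"].iloc[hottest] == "HH"

    def test_alpha_zero_silences_all_labels(self, grid25):
        coords, values = grid25
        W = build_weights(coords, scheme="knn", k=4)
        out = local_moran(values, W, n_permutations=99, alpha=0.0, seed=1)
        assert (out["label"] == "not_significant").all()

    def test_sign_flip_swaps_quadrants(self):
        layout = generate_city_layout(100, "clustered", 5, seed=6)
        coords = layout[["u", "v"]].to_numpy()
        field = simulate_clustered_field(
            coords, hot_centers=[(300.0, 300.0)], cold_centers=[(700.0, 700.0)],
            base=10.0, amplitude=6.0, noise_sd=0.2, seed=2, length_scale=120.0,
        )
        W = build_weights(coords)
        fwd = local_moran(field, W, n_permutations=499, alpha=0.05, seed=4)
        rev = local_moran(-field, W, n_permutations=499, alpha=0.05, seed=4)
        swap = {"HH": "LL", "LL": "HH", "HL": "LH", "LH": "HL",
                "not_significant": "not_significant"}
        assert list(rev["label"]) == [swap[l] for l in fwd["label"]]


class TestGiStar:
    def _self_weights(self, coords, band=None):
        return build_weights(coords, scheme="distance_band", band_distance=band,
                             row_standardize=False, include_self=True)

    def test_constant_field_degenerate(self, grid25):
        coords, _ = grid25
        W = self._self_weights(coords, band=1.5)
        with pytest.raises(DegenerateInputError):
            getis_ord_gi_star(np.full(25, 2.0), W)

    def test_single_spike_attains_max_z(self, grid25):
        # spike at the grid center: the spike city attains the maximal z
        # (tied with its immediate neighbors, whose neighborhoods also
        # contain the spike and have identical weight sums)
        coords, _ = grid25
        values = np.zeros(25)
        values[12] = 10.0
        W = self._self_weights(coords, band=1.0)
        out = getis_ord_gi_star(values, W)
        z = out["gi_star_z"].to_numpy()
        assert z[12] == pytest.approx(z.max(), abs=1e-12)
        assert z[12] > 0

    def test_matches_brute_force_on_grid(self, grid25):
        coords, values = grid25
        W = self._self_weights(coords, band=1.5)
        out = getis_ord_gi_star(values, W)
        np.testing.assert_allclose(
            out["gi_star_z"].to_numpy(), brute_gi_star(values, W.matrix.toarray()),
            atol=1e-9,
        )

    def test_negated_field_negates_z(self, grid25):
        coords, values = grid25
        W = self._self_weights(coords, band=1.5)
        z_fwd = getis_ord_gi_star(values, W)["gi_star_z"].to_numpy()
        z_rev = getis_ord_gi_star(-values, W)["gi_star_z"].to_numpy()
        np.testing.assert_allclose(z_rev, -z_fwd, atol=1e-10)

    def test_requires_self_weight(self, grid25):
        coords, values = grid25
        W = build_weights(coords, scheme="knn", k=4)
        with pytest.raises(ValueError, match="self"):
            getis_ord_gi_star(values, W)
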