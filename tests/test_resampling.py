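"""Unit and property tests for the adaptive-resampling weight ladder."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from scresample.resampling import (combine_and_normalize,
                                   compute_resampling_weights,
                                   estimate_latent_densities,
                                   invert_per_sample, per_sample_probability,
                                   resample_indices, export_weights)

from conftest import naive_weight_ladder

Z4 = np.array([[0.1], [0.2], [0.3], [0.9]])


class TestDensityEstimate:
    def test_hand_example_two_bins(self):
        d = estimate_latent_densities(Z4, n_bins=2)
        np.testing.assert_allclose(d.bin_edges[0], [0.1, 0.5, 0.9])
        np.testing.assert_allclose(d.bin_mass[0], [0.75, 0.25])

    def test_constant_dimension_single_bin(self):
        d = estimate_latent_densities(np.full((3, 1), 2.5), n_bins=7)
        assert len(d.bin_mass[0]) == 1
        np.testing.assert_allclose(d.bin_mass[0], [1.0])

    def test_uniform_occupancy(self):
        d = estimate_latent_densities(np.array([[0.0], [1.0], [2.0], [3.0]]), n_bins=4)
        np.testing.assert_allclose(d.bin_mass[0], [0.25] * 4)

    @pytest.mark.parametrize("bad", [np.array([[np.nan]]), np.array([[np.inf], [0.0]])])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            estimate_latent_densities(bad, n_bins=2)

    def test_bad_bin_count_rejected(self):
        with pytest.raises(ValueError):
            estimate_latent_densities(Z4, n_bins=0)

    def test_mass_sums_to_one_per_dimension(self):
        rng = np.random.default_rng(0)
        d = estimate_latent_densities(rng.normal(size=(40, 3)), n_bins=6)
        for mass in d.bin_mass:
            assert abs(mass.sum() - 1.0) < 1e-12


class TestPerSampleProbability:
    def test_hand_example_alpha_zero(self):
        d = estimate_latent_densities(Z4, n_bins=2)
        p = per_sample_probability(d, Z4, alpha=0.0)
        np.testing.assert_allclose(p[0], [0.3, 0.3, 0.3, 0.1])

    def test_hand_example_small_alpha(self):
        d = estimate_latent_densities(Z4, n_bins=2)
        p = per_sample_probability(d, Z4, alpha=1e-4)
        expected = np.array([0.7501, 0.7501, 0.7501, 0.2501]) / 2.5004
        np.testing.assert_allclose(p[0], expected, atol=1e-12)

    def test_constant_dimension_uniform(self):
        Z = np.full((5, 1), 3.3)
        d = estimate_latent_densities(Z, n_bins=4)
        for alpha in (0.0, 0.5):
            np.testing.assert_allclose(
                per_sample_probability(d, Z, alpha=alpha)[0], [0.2] * 5)

    def test_out_of_range_sample_rejected(self):
        d = estimate_latent_densities(Z4, n_bins=2)
        with pytest.raises(ValueError, match="outside"):
            per_sample_probability(d, np.array([[5.0]]), alpha=0.0)

    def test_negative_alpha_rejected(self):
        d = estimate_latent_densities(Z4, n_bins=2)
        with pytest.raises(ValueError):
            per_sample_probability(d, Z4, alpha=-0.1)


class TestInvertAndCombine:
    def test_inversion_hand_example(self):
        u = invert_per_sample(np.array([[0.3, 0.3, 0.3, 0.1]]))
        np.testing.assert_allclose(u[0], [1 / 6, 1 / 6, 1 / 6, 1 / 2])

    def test_uniform_row_fixed_point(self):
        u = invert_per_sample(np.full((1, 8), 1 / 8))
        np.testing.assert_allclose(u[0], [1 / 8] * 8)

    def test_zero_entry_rejected(self):
        with pytest.raises(ValueError):
            invert_per_sample(np.array([[0.0, 1.0]]))

    def test_combine_single_dimension_passthrough(self):
        u = np.array([[1 / 6, 1 / 6, 1 / 6, 1 / 2]])
        _, w_star = combine_and_normalize(u)
        np.testing.assert_allclose(w_star, u[0])

    def test_combine_two_dimensions_hand_example(self):
        u = np.array([[1 / 6, 1 / 6, 1 / 6, 1 / 2],
                      [1 / 4, 1 / 4, 1 / 4, 1 / 4]])
        w, w_star = combine_and_normalize(u)
        np.testing.assert_allclose(w, [0.25, 0.25, 0.25, 0.5])
        np.testing.assert_allclose(w_star, [0.2, 0.2, 0.2, 0.4])

    def test_all_uniform_gives_uniform(self):
        u = np.full((3, 10), 0.1)
        _, w_star = combine_and_normalize(u)
        np.testing.assert_allclose(w_star, [0.1] * 10)


class TestFullLadder:
    def test_chained_hand_example(self):
        rw = compute_resampling_weights(Z4, alpha=0.0, n_bins=2)
        np.testing.assert_allclose(rw.final, [1 / 6, 1 / 6, 1 / 6, 1 / 2])

    def test_single_sample(self):
        rw = compute_resampling_weights(np.array([[3.0, -1.0]]), n_bins=5)
        np.testing.assert_allclose(rw.final, [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 80))
        k = int(rng.integers(1, 5))
        bins = int(rng.integers(1, 10))
        alpha = float(rng.choice([0.0, 1e-4, 0.01]))
        Z = rng.normal(size=(n, k))
        rw = compute_resampling_weights(Z, alpha=alpha, n_bins=bins)
        p_o, u_o, w_o, ws_o = naive_weight_ladder(Z, alpha, bins)
        np.testing.assert_allclose(rw.smoothed_prob, p_o, atol=1e-10)
        np.testing.assert_allclose(rw.inverted, u_o, atol=1e-10)
        np.testing.assert_allclose(rw.final, ws_o, atol=1e-10)

    def test_monotonicity_within_dimension(self):
        # sample in the sparser bin must get the larger inverted score
        rw = compute_resampling_weights(Z4, alpha=1e-4, n_bins=2)
        assert rw.inverted[0, 3] > rw.inverted[0, 0]

    def test_scale_invariance_of_densities(self):
        # scaling a dimension stretches bins with it: weights unchanged
        rw1 = compute_resampling_weights(Z4, alpha=0.0, n_bins=2)
        rw2 = compute_resampling_weights(Z4 * 100.0, alpha=0.0, n_bins=2)
        np.testing.assert_allclose(rw1.final, rw2.final, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(40, 3))
        perm = rng.permutation(40)
        rw = compute_resampling_weights(Z, alpha=1e-4, n_bins=6)
        rw_p = compute_resampling_weights(Z[perm], alpha=1e-4, n_bins=6)
        np.testing.assert_allclose(rw_p.final, rw.final[perm], atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        Z=arrays(np.float64, shape=st.tuples(st.integers(2, 40), st.integers(1, 4)),
                 elements=st.floats(-50, 50, allow_nan=False)),
        bins=st.integers(1, 12),
    )
    def test_normalization_and_positivity_fuzzed(self, Z, bins):
        rw = compute_resampling_weights(Z, alpha=1e-4, n_bins=bins)
        assert abs(rw.final.sum() - 1.0) < 1e-12
        assert rw.final.min() > 0
        assert abs(rw.smoothed_prob.sum(axis=1) - 1.0).max() < 1e-10
        assert abs(rw.inverted.sum(axis=1) - 1.0).max() < 1e-10

    def test_rarity_enrichment_on_mixture(self, mixture_95_5):
        Z, labels = mixture_95_5
        rw = compute_resampling_weights(Z, alpha=1e-4, n_bins=50)
        assert rw.final[labels == "rare"].mean() > rw.final[labels == "common"].mean()


class TestResampleIndices:
    def test_degenerate_one_hot(self):
        idx = resample_indices(np.array([1.0, 0.0, 0.0]), rng_seed=0)
        assert (idx == 0).all() and len(idx) == 3

    def test_uniform_frequencies_within_binomial_bound(self):
        n = 2000
        idx = resample_indices(np.full(n, 1 / n), rng_seed=1)
        freq = np.bincount(idx, minlength=n) / n
        bound = 4 * np.sqrt((1 / n) * (1 - 1 / n) / n)
        # the 4-SE bound holds per index with p > 0.9999; allow the handful
        # of expected exceedances across all n indices
        # P(violation per index) ~ P(Poisson(1) >= 5) ~ 0.004 -> expect ~7
        violations = int((np.abs(freq - 1 / n) > bound).sum())
        assert violations <= 20
        assert abs(freq.mean() - 1 / n) < 1e-12

    def test_seeded_determinism(self):
        w = np.array([0.2, 0.3, 0.5])
        np.testing.assert_array_equal(resample_indices(w, 7), resample_indices(w, 7))

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError):
            resample_indices(np.array([0.5, 0.1]), rng_seed=0)


def test_export_weights_roundtrip(tmp_path):
    import json
    import pandas as pd

    rw = compute_resampling_weights(Z4, alpha=1e-4, n_bins=2)
    out = tmp_path / "weights.tsv"
    export_weights(rw, out, cell_ids=["a", "b", "c", "d"], epoch=3, seed=11)
    df = pd.read_csv(out, sep="\t")
    np.testing.assert_allclose(df["final_weight"], rw.final)
    assert list(df["cell_id"]) == ["a", "b", "c", "d"]
    sidecar = json.loads((tmp_path / "weights.tsv.json").read_text())
    assert sidecar["alpha"] == 1e-4 and sidecar["epoch"] == 3 and sidecar["seed"] == 11
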