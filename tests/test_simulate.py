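"""Synthetic-data generators: geometries, photophysics, kinetics, drift."""

import numpy as np
import pytest
from scipy import stats

from bagol.simulate import (SimScene, apply_drift, blinks_from_emitters,
                            expected_nn_distance, sim_8mer, sim_cross,
                            sim_density_field, sim_dimer, sim_dstorm_kinetics,
                            sim_line_pair)


class TestGeometries:
    def test_8mer_neighbor_spacing_is_076R(self):
        for R in (2.5, 5.0, 10.0, 20.0):
            scene = sim_8mer(R)
            pos = scene.true_positions
            d = np.linalg.norm(pos - np.roll(pos, 1, axis=0), axis=1)
            np.testing.assert_allclose(d, 2 * R * np.sin(np.pi / 8), rtol=1e-12)
            assert d[0] == pytest.approx(0.765 * R, rel=0.01)

    def test_dimer_separation_exact(self):
        scene = sim_dimer(7.0)
        assert scene.n_emitters == 2
        assert np.linalg.norm(np.diff(scene.true_positions, axis=0)) == pytest.approx(7.0)

    def test_density_field_count_and_nn_distance(self):
        rho = 10_000.0
        nn_means = []
        for seed in range(5):
            scene = sim_density_field(rho, 500.0, rng=seed)
            assert scene.n_emitters == int(round(rho / 1e6 * 500 ** 2))
            from bagol.metrics import nnd_distribution
            nn_means.append(nnd_distribution(scene.true_positions).mean())
        # <r> = 1/(2 sqrt(rho)) = 5 nm at 10,000 per um^2
        expected = expected_nn_distance(rho)
        assert expected == pytest.approx(5.0)
        se = np.std(nn_means, ddof=1) / np.sqrt(len(nn_means))
        assert abs(np.mean(nn_means) - expected) < 3 * se + 0.15

    def test_line_pair_geometry(self):
        scene = sim_line_pair(6.0, length=100.0, n_per_line=70, rng=0)
        pos = scene.true_positions
        assert pos.shape == (140, 2)
        assert set(np.round(np.unique(pos[:, 0]), 9)) == {-3.0, 3.0}
        assert pos[:, 1].min() >= -50.0 and pos[:, 1].max() <= 50.0

    def test_cross_equal_spacing_single_center(self):
        scene = sim_cross(5.0)
        pos = scene.true_positions
        # 21 sites per 100 nm arm, center shared once
        assert pos.shape[0] == 41
        on_x = pos[np.abs(pos[:, 1]) < 1e-9]
        assert np.allclose(np.diff(np.sort(on_x[:, 0])), 5.0)


class TestPaintBlinks:
    def test_precision_follows_psf_photon_law(self):
        scene = sim_8mer(10.0, lam=50)
        locs, alloc = blinks_from_emitters(scene, rng=0)
        np.testing.assert_allclose(locs.sigma_x, 120.0 / np.sqrt(locs.photons))
        # I = 1800 -> sigma = 2.83 nm
        assert 120.0 / np.sqrt(1800.0) == pytest.approx(2.83, abs=0.01)

    def test_blink_counts_poisson_mean(self, rng):
        scene = SimScene(np.zeros((500, 2)), lam=20.0)
        locs, alloc = blinks_from_emitters(scene, rng=1)
        counts = np.bincount(alloc, minlength=500)
        se = counts.std(ddof=1) / np.sqrt(500)
        assert abs(counts.mean() - 20.0) < 3 * se

    def test_position_scatter_matches_reported_sigma(self):
        scene = SimScene(np.zeros((1, 2)), lam=5000.0)
        locs, alloc = blinks_from_emitters(scene, rng=2)
        z = (locs.x - 0.0) / locs.sigma_x
        # standardized deviations should be unit normal
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert z.std(ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_precision_distribution_ks_against_law(self):
        scene = SimScene(np.zeros((200, 2)), lam=50.0)
        locs, _ = blinks_from_emitters(scene, rng=3)
        # sigma = 120/sqrt(I), I ~ Exp(1800) (truncated at 1 photon)
        i_draws = (120.0 / locs.sigma_x) ** 2
        ks = stats.kstest(i_draws, "expon", args=(0, 1800.0))
        assert ks.pvalue > 0.01

    def test_seed_reproducibility(self):
        scene = sim_8mer(10.0, lam=30)
        a, _ = blinks_from_emitters(scene, rng=7)
        b, _ = blinks_from_emitters(sim_8mer(10.0, lam=30), rng=7)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.photons, b.photons)


class TestDstormKinetics:
    def test_blink_count_geometric_with_branching_mean(self):
        scene = SimScene(np.zeros((20000, 2)), k_on=2e-4, k_off=5e-2,
                         k_b=5e-2, n_frames=10**9)
        events = sim_dstorm_kinetics(scene, rng=0)
        counts = np.array([len(e) for e in events])
        mean_expected = (scene.k_off + scene.k_b) / scene.k_b
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - mean_expected) < 3 * se
        # geometric on {1, 2, ...}: P(n) = p (1-p)^(n-1)
        p = scene.k_b / (scene.k_off + scene.k_b)
        vals, freq = np.unique(counts, return_counts=True)
        emp = freq / counts.size
        theo = p * (1 - p) ** (vals - 1)
        assert np.max(np.abs(emp[:5] - theo[:5])) < 0.02

    def test_instant_bleach_gives_single_blink(self):
        scene = SimScene(np.zeros((200, 2)), k_on=1e-2, k_off=1e-9, k_b=1e9,
                         n_frames=10**7)
        events = sim_dstorm_kinetics(scene, rng=1)
        assert all(len(e) == 1 for e in events)

    def test_activation_probability_over_acquisition(self):
        scene = SimScene(np.zeros((5000, 2)), k_on=2e-4, n_frames=100_000)
        events = sim_dstorm_kinetics(scene, rng=2)
        frac = np.mean([len(e) > 0 for e in events])
        # 1 - exp(-k_on * n_frames) > 99.99...%
        assert frac > 0.99

    def test_dstorm_localizations_within_frame_budget(self):
        scene = sim_cross(10.0, n_frames=100_000)
        locs, alloc = blinks_from_emitters(scene, mode="dstorm", rng=3)
        assert locs.frame.max() < 100_000
        assert alloc.max() < scene.n_emitters


class TestDrift:
    def test_zero_drift_is_identity(self, cluster_factory):
        locs = cluster_factory([[0, 0]], 30, 2.0)
        scene = SimScene(np.zeros((1, 2)), drift_velocity=0.0)
        out, vecs = apply_drift(scene, locs, np.zeros(30, dtype=int), rng=0)
        np.testing.assert_array_equal(out.x, locs.x)
        assert np.allclose(vecs, 0)

    def test_endpoint_offset_equals_vector(self):
        from bagol.data import LocalizationSet
        locs = LocalizationSet([0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0],
                               frame=[0, 10])
        scene = SimScene(np.zeros((1, 2)))
        out, vecs = apply_drift(scene, locs, np.zeros(2, dtype=int),
                                drift_vectors=np.array([[3.0, -2.0]]))
        assert out.x[1] - locs.x[1] == pytest.approx(3.0)
        assert out.y[1] - locs.y[1] == pytest.approx(-2.0)
        assert out.x[0] == locs.x[0]  # t = 0 unshifted

    def test_regression_recovers_noiseless_drift(self):
        n = 50
        frames = np.arange(n)
        from bagol.data import LocalizationSet
        locs = LocalizationSet(np.zeros(n), np.zeros(n), np.ones(n),
                               np.ones(n), frame=frames)
        scene = SimScene(np.zeros((1, 2)))
        v = np.array([[4.0, 1.5]])
        out, _ = apply_drift(scene, locs, np.zeros(n, dtype=int),
                             drift_vectors=v)
        t = out.t_normalized()
        slope_x = np.polyfit(t, out.x, 1)[0]
        slope_y = np.polyfit(t, out.y, 1)[0]
        assert slope_x == pytest.approx(4.0, abs=1e-9)
        assert slope_y == pytest.approx(1.5, abs=1e-9)

    def test_random_directions_have_configured_magnitude(self):
        scene = SimScene(np.zeros((100, 2)), lam=5.0, drift_velocity=2.0)
        locs, alloc = blinks_from_emitters(scene, rng=5)
        mags = np.linalg.norm(scene.drift_vectors, axis=1)
        np.testing.assert_allclose(mags, 2.0, rtol=1e-9)
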