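"""Tiling, posterior images, MAPN extraction and stitching."""

import numpy as np
import pytest

from bagol.data import LocalizationSet, RenderSpec
from bagol.model import SamplerConfig
from bagol.outputs import (MAPNResult, make_tiling, mapn_extract,
                           posterior_image, stitch)
from bagol.sampler import Chain, run_chain


def uniform_locs(n, size, rng, sigma=1.0):
    return LocalizationSet(rng.uniform(0, size, n), rng.uniform(0, size, n),
                           np.full(n, sigma), np.full(n, sigma))


class TestTiling:
    def test_zero_overlap_is_partition(self, rng):
        locs = uniform_locs(500, 500.0, rng)
        plan = make_tiling(locs, 50.0, overlap=0.0)
        assert plan.n_boxes == 100
        counts = np.zeros(len(locs), dtype=int)
        for idx in plan.assignments:
            counts[idx] += 1
        assert np.all(counts == 1)

    def test_overlap_duplicates_edge_points(self, rng):
        locs = uniform_locs(300, 100.0, rng)
        plan = make_tiling(locs, 50.0, overlap=10.0)
        # a point 5 nm from an interior core edge must sit in 2 boxes
        multiplicity = sum(
            (45.0 >= b[0]) and (45.0 < b[1]) and (25.0 >= b[2]) and (25.0 < b[3])
            for b in plan.boxes)
        assert multiplicity == 2

    def test_small_field_single_box(self, rng):
        locs = uniform_locs(30, 10.0, rng)
        plan = make_tiling(locs, 50.0, overlap=5.0)
        assert plan.n_boxes == 1
        assert len(plan.assignments[0]) == 30

    def test_cores_cover_field_exactly_once(self, rng):
        locs = uniform_locs(200, 120.0, rng)
        plan = make_tiling(locs, 50.0, overlap=8.0)
        pts = locs.positions
        membership = np.zeros(len(locs), dtype=int)
        for core in plan.cores:
            inside = ((pts[:, 0] >= core[0]) & (pts[:, 0] < core[1])
                      & (pts[:, 1] >= core[2]) & (pts[:, 1] < core[3]))
            membership += inside
        assert np.all(membership == 1)

    def test_extent_restricts_field(self, rng):
        locs = uniform_locs(200, 100.0, rng)
        far = LocalizationSet(np.append(locs.x, 1e4), np.append(locs.y, 1e4),
                              np.append(locs.sigma_x, 1.0),
                              np.append(locs.sigma_y, 1.0))
        plan = make_tiling(far, 50.0, overlap=5.0, extent=(0, 100, 0, 100))
        assert plan.n_boxes == 4
        covered = np.unique(np.concatenate(plan.assignments))
        assert len(far) - 1 not in covered  # the faraway point is dropped

    def test_rejects_overlap_half_of_size(self, rng):
        locs = uniform_locs(50, 100.0, rng)
        with pytest.raises(ValueError):
            make_tiling(locs, 20.0, overlap=10.0)


def chain_with_positions(positions_per_sample, box=(0, 100, 0, 100)):
    """Hand-built chain whose samples have the given emitter positions."""
    n = len(positions_per_sample)
    k_cap = max(1, max(len(p) for p in positions_per_sample))
    K = np.array([len(p) for p in positions_per_sample], dtype=np.int64)
    mu_x = np.zeros((n, k_cap))
    mu_y = np.zeros((n, k_cap))
    counts = np.zeros((n, k_cap), dtype=np.int32)
    for s, pts in enumerate(positions_per_sample):
        if len(pts) == 0:
            continue
        pts = np.atleast_2d(pts)
        mu_x[s, :len(pts)] = pts[:, 0]
        mu_y[s, :len(pts)] = pts[:, 1]
        counts[s, :len(pts)] = 10
    return Chain(K=K, mu_x=mu_x, mu_y=mu_y, a_x=np.zeros_like(mu_x),
                 a_y=np.zeros_like(mu_y), counts=counts, xi=np.full(n, 10.0),
                 proposed={}, accepted={}, z_last=np.zeros(0, dtype=np.int64),
                 config=SamplerConfig(xi=10, xi_mode="fixed", n_samples=n),
                 box=box, n_data=10)


class TestPosteriorImage:
    def test_fixed_single_position_unit_mass(self):
        chain = chain_with_positions([[[10.5, 20.5]]] * 50)
        spec = RenderSpec(1.0, (0, 100, 0, 100))
        img = posterior_image(chain, spec)
        assert img.sum() == pytest.approx(1.0)
        assert img[20, 10] == pytest.approx(1.0)

    def test_alternating_positions_split_mass(self):
        chain = chain_with_positions([[[10.5, 10.5]], [[30.5, 40.5]]] * 25)
        spec = RenderSpec(1.0, (0, 100, 0, 100))
        img = posterior_image(chain, spec)
        assert img[10, 10] == pytest.approx(0.5)
        assert img[40, 30] == pytest.approx(0.5)

    def test_total_mass_equals_mean_k(self):
        chain = chain_with_positions([[[10, 10]], [[10, 10], [20, 20]]] * 20)
        spec = RenderSpec(1.0, (0, 100, 0, 100))
        assert posterior_image(chain, spec).sum() == pytest.approx(1.5)

    def test_second_moment_matches_sample_variance(self, rng):
        draws = rng.normal(50.0, 2.0, size=(400, 1, 2))
        chain = chain_with_positions([d for d in draws])
        spec = RenderSpec(0.5, (0, 100, 0, 100))
        img = posterior_image(chain, spec)
        xs = spec.x_edges()[:-1] + 0.25
        px = img.sum(axis=0) / img.sum()
        mean = (xs * px).sum()
        var = ((xs - mean) ** 2 * px).sum()
        sample_var = draws[:, 0, 0].var()
        assert var == pytest.approx(sample_var, rel=0.1)


class TestMAPN:
    def test_single_stable_emitter_statistics(self, rng):
        draws = rng.normal([40.0, 60.0], [0.8, 0.8], size=(600, 2))
        chain = chain_with_positions([[d] for d in draws])
        res = mapn_extract(chain)
        assert res.K_map == 1
        np.testing.assert_allclose(res.positions[0], [40.0, 60.0], atol=0.15)
        np.testing.assert_allclose(res.precisions[0], 0.8, atol=0.12)

    def test_two_stable_emitters_recovered(self, rng):
        a = rng.normal([20.0, 20.0], 0.5, size=(300, 2))
        b = rng.normal([70.0, 70.0], 0.5, size=(300, 2))
        chain = chain_with_positions([np.vstack([p, q]) for p, q in zip(a, b)])
        res = mapn_extract(chain)
        assert res.K_map == 2
        got = res.positions[np.argsort(res.positions[:, 0])]
        np.testing.assert_allclose(got, [[20, 20], [70, 70]], atol=0.2)

    def test_modal_tie_broken_toward_fewer_emitters(self):
        chain = chain_with_positions([[[10, 10]], [[10, 10], [20, 20]]] * 10)
        assert chain.modal_K() == 1
        assert mapn_extract(chain).K_map == 1

    def test_empty_chain_gives_empty_result(self):
        chain = chain_with_positions([[]])
        chain.K = np.zeros(1, dtype=np.int64)
        res = mapn_extract(chain)
        assert res.K_map == 0


class TestStitch:
    def make_plan(self, rng):
        locs = uniform_locs(200, 100.0, rng)
        return make_tiling(locs, 50.0, overlap=10.0)

    def test_no_overlap_concatenates(self, rng):
        locs = uniform_locs(100, 100.0, rng)
        plan = make_tiling(locs, 50.0, overlap=0.0)
        results = []
        for core in plan.cores:
            cx = (core[0] + core[1]) / 2
            cy = (core[2] + core[3]) / 2
            results.append(MAPNResult([[cx, cy]], [[1.0, 1.0]],
                                      drifts=np.zeros((1, 2)),
                                      n_loc=np.array([5.0])))
        merged, _ = stitch(results, plan)
        assert merged.K_map == plan.n_boxes

    def test_emitter_reported_once_from_core_box(self, rng):
        plan = self.make_plan(rng)
        # an emitter at (55, 25): core of box 1, overlap strip of box 0
        results = [MAPNResult.empty() for _ in range(plan.n_boxes)]
        for b, core in enumerate(plan.cores):
            box = plan.boxes[b]
            if box[0] <= 55.0 < box[1] and box[2] <= 25.0 < box[3]:
                results[b] = MAPNResult([[55.0, 25.0]], [[1.0, 1.0]],
                                        drifts=np.zeros((1, 2)),
                                        n_loc=np.array([3.0]))
        merged, _ = stitch(results, plan)
        assert merged.K_map == 1

    def test_boundary_emitter_assigned_by_half_open_convention(self, rng):
        plan = self.make_plan(rng)
        results = [MAPNResult.empty() for _ in range(plan.n_boxes)]
        # exactly on the boundary x = 50: belongs to the box whose core
        # starts at 50
        for b, core in enumerate(plan.cores):
            box = plan.boxes[b]
            if box[0] <= 50.0 < box[1] and box[2] <= 10.0 < box[3]:
                results[b] = MAPNResult([[50.0, 10.0]], [[1.0, 1.0]],
                                        drifts=np.zeros((1, 2)),
                                        n_loc=np.array([3.0]))
        merged, _ = stitch(results, plan)
        assert merged.K_map == 1

    def test_end_to_end_tiling_invariance_for_separated_emitters(self, rng):
        # well-separated emitters analyzed under two different tilings must
        # produce the same emitter count
        centers = np.array([[x, y] for x in (25, 75, 125) for y in (25, 75)])
        xs, ys = [], []
        for c in centers:
            xs.append(rng.normal(c[0], 1.0, 30))
            ys.append(rng.normal(c[1], 1.0, 30))
        locs = LocalizationSet(np.concatenate(xs), np.concatenate(ys),
                               np.ones(180), np.ones(180))
        from bagol.pipeline import analyze

        cfg = SamplerConfig(xi=30.0, xi_mode="fixed", n_samples=400,
                            rng_seed=4)
        k_counts = []
        for sub in (50.0, 80.0):
            res = analyze(locs, cfg, subregion_size=sub, overlap=10.0)
            k_counts.append(res.mapn.K_map)
        assert k_counts[0] == k_counts[1] == 6
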