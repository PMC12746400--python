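"""Phantom ground-truth consistency: deformation, labels, flows, k-space."""

import numpy as np
import pytest

from cineflow import flow_ops
from cineflow.containers import LABEL_LV_POOL
from cineflow.forward_model import ifft2c
from cineflow.phantom import (PhantomConfig, generate_cine_phantom,
                              generate_coil_maps, generate_kt_mask,
                              simulate_kspace)


class TestConfigValidation:
    def test_rejects_self_intersecting_contraction(self):
        with pytest.raises(ValueError, match="contraction"):
            PhantomConfig(contraction_amplitude=0.5)

    def test_rejects_tiny_grid_and_short_cycle(self):
        with pytest.raises(ValueError):
            PhantomConfig(grid_size=(16, 64))
        with pytest.raises(ValueError):
            PhantomConfig(n_frames=4)


class TestDeformation:
    def test_static_case_all_frames_identical(self, static_phantom):
        gt = static_phantom
        for t in range(1, gt.images.n_frames):
            np.testing.assert_array_equal(gt.images.frames[t],
                                          gt.images.frames[0])
            assert np.abs(gt.true_flow(0, t)).max() == 0.0

    def test_peak_contraction_shrinks_lv_pool(self, phantom64):
        gt = phantom64
        a0 = (gt.labels[0] == LABEL_LV_POOL).sum()
        aes = (gt.labels[gt.es_frame] == LABEL_LV_POOL).sum()
        assert aes < a0
        lam2 = (1 - gt.deformation.alpha(gt.es_frame)) ** 2
        assert aes / a0 == pytest.approx(lam2, rel=0.05)

    def test_seed_determinism(self):
        cfg = PhantomConfig(grid_size=(32, 32), seed=5)
        a = generate_cine_phantom(cfg)
        b = generate_cine_phantom(cfg)
        np.testing.assert_array_equal(a.images.frames, b.images.frames)
        c = generate_cine_phantom(PhantomConfig(grid_size=(32, 32), seed=6))
        assert not np.array_equal(a.images.frames, c.images.frames)

    def test_self_flow_zero_and_roundtrip(self, phantom64):
        gt = phantom64
        assert np.abs(gt.true_flow(3, 3)).max() < 1e-9
        es = gt.es_frame
        resid = flow_ops.compose_flows(gt.true_flow(0, es),
                                       gt.true_flow(es, 0))
        assert np.abs(resid).mean() < 0.5

    def test_flow_warps_between_frames(self, phantom64):
        gt = phantom64
        es = gt.es_frame
        warped = flow_ops.warp_image(gt.noise_free[es], gt.true_flow(0, es))
        err = np.abs(warped - gt.noise_free[0]).mean()
        assert err < 2 * max(gt.config.noise_sigma, 0.005)

    def test_labels_deform_with_intensities(self, phantom64):
        gt = phantom64
        es = gt.es_frame
        warped = flow_ops.warp_image(gt.labels[es], gt.true_flow(0, es),
                                     mode="nearest")
        agree = (warped == gt.labels[0]).mean()
        assert agree > 0.98

    def test_true_flows_are_diffeomorphic(self, phantom64):
        gt = phantom64
        for t in (3, gt.es_frame, 20):
            assert flow_ops.nonpositive_jacobian_fraction(
                gt.true_flow(0, t)) == 0.0

    def test_ef_from_volumes_matches_closed_form(self, phantom64):
        gt = phantom64
        v = gt.true_volumes
        ef = 100 * (v.lv_edv - v.lv_esv) / v.lv_edv
        assert ef == pytest.approx(gt.analytic_ef(), abs=1.0)


class TestCoilMaps:
    def test_single_coil_uniform(self):
        maps = generate_coil_maps(1, (32, 32))
        np.testing.assert_array_equal(maps, np.ones((1, 32, 32)))

    def test_rss_strictly_positive(self):
        maps = generate_coil_maps(8, (48, 40), seed=2)
        rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
        assert rss.min() > 0

    def test_grid_mismatch_raises_downstream(self, phantom32):
        maps = generate_coil_maps(4, (16, 16), seed=0)
        mask = generate_kt_mask((25, 32), R=1)
        with pytest.raises(ValueError):
            simulate_kspace(phantom32.images, maps, mask)


class TestKtMask:
    def test_full_sampling_all_ones(self):
        np.testing.assert_array_equal(generate_kt_mask((25, 64), R=1),
                                      np.ones((25, 64)))

    def test_budget_and_acs(self):
        mask = generate_kt_mask((25, 192), R=8, acs_lines=4, seed=0)
        assert (mask.sum(axis=1) == 24).all()   # round(192/8)
        center = np.arange(94, 98)
        assert mask[:, center].all()
        # realized acceleration within 10% of nominal
        assert mask.size / mask.sum() == pytest.approx(8, rel=0.1)

    def test_incoherent_across_time(self):
        mask = generate_kt_mask((25, 64), R=8, acs_lines=2, seed=1)
        assert len({tuple(row) for row in mask}) > 20

    def test_seed_determinism(self):
        a = generate_kt_mask((10, 64), R=6, seed=3)
        b = generate_kt_mask((10, 64), R=6, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_infeasible_acs_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_kt_mask((10, 32), R=16, acs_lines=4)


class TestSimulatedKspace:
    def test_fully_sampled_single_coil_roundtrip(self, phantom32):
        maps = generate_coil_maps(1, (32, 32))
        mask = generate_kt_mask((25, 32), R=1)
        ks = simulate_kspace(phantom32.images, maps, mask)
        recon = np.abs(ifft2c(ks.y[:, 0]))
        np.testing.assert_allclose(recon, np.abs(phantom32.images.frames),
                                   atol=1e-6)

    def test_masked_energy_not_larger(self, phantom32):
        maps = generate_coil_maps(4, (32, 32), seed=0)
        mask = generate_kt_mask((25, 32), R=4, acs_lines=2, seed=0)
        ks = simulate_kspace(phantom32.images, maps, mask)
        assert np.linalg.norm(ks.y) <= np.linalg.norm(ks.y_full) + 1e-9
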