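"""Volumes, ejection fraction, Green–Lagrange strain, AHA-17 mapping."""

import numpy as np
import pytest

from cineflow.containers import LABEL_LV_POOL, LABEL_MYOCARDIUM
from cineflow.function_analysis import (aha17_bullseye, compute_strain,
                                        ejection_fraction, green_lagrange,
                                        local_coordinates, project_strain,
                                        ventricular_volumes)
from cineflow.phantom import PhantomConfig, generate_slice_stack


class TestVolumes:
    def test_single_slice_arithmetic(self):
        lab = np.zeros((32, 32), dtype=int)
        lab[:10, :10] = LABEL_LV_POOL   # 100 pixels
        vols = ventricular_volumes([[lab]], (2.0, 2.0), 8.0)
        assert vols.lv_ml[0] == pytest.approx(100 * 4 * 8 / 1000.0)  # 3.2 ml

    def test_static_masks_equal_ed_es(self, static_phantom):
        vols = ventricular_volumes([list(static_phantom.labels)],
                                   (1.0, 1.0), 8.0)
        assert vols.lv_edv == vols.lv_esv

    def test_phantom_volumes_match_analytic(self, phantom64):
        gt = phantom64
        vols = ventricular_volumes([list(gt.labels)],
                                   gt.config.pixel_spacing,
                                   gt.config.slice_thickness)
        np.testing.assert_allclose(vols.lv_ml, gt.true_volumes.lv_ml,
                                   rtol=0.03)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ventricular_volumes([[np.zeros((8, 8), dtype=int)]], (1, 1), 8)


class TestEjectionFraction:
    def test_half_emptying(self):
        assert ejection_fraction(100, 50) == 50.0

    def test_no_emptying(self):
        assert ejection_fraction(80, 80) == 0.0

    def test_zero_edv_rejected(self):
        with pytest.raises(ValueError):
            ejection_fraction(0, 0)

    def test_phantom_ef_matches_closed_form(self, phantom64):
        gt = phantom64
        vols = ventricular_volumes([list(gt.labels)],
                                   gt.config.pixel_spacing,
                                   gt.config.slice_thickness)
        ef = ejection_fraction(vols.lv_edv, vols.lv_esv)
        assert ef == pytest.approx(gt.analytic_ef(), abs=2.0)

    def test_invariant_to_image_intensity(self, phantom64):
        # EF depends only on masks: same masks, any images -> same EF
        gt = phantom64
        vols = ventricular_volumes([list(gt.labels)], (1.9, 1.9), 8.0)
        again = ventricular_volumes([list(gt.labels.copy())], (1.9, 1.9), 8.0)
        assert ejection_fraction(vols.lv_edv, vols.lv_esv) == \
            ejection_fraction(again.lv_edv, again.lv_esv)


class TestGreenLagrange:
    def test_zero_displacement(self):
        E = green_lagrange(np.zeros((16, 16, 2)))
        assert np.abs(E).max() == 0.0

    def test_homogeneous_scaling(self):
        H = W = 20
        a = 0.1
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        u = np.stack([a * rr, a * cc], -1).astype(float)
        E = green_lagrange(u)
        expect = a + a * a / 2
        interior = E[2:-2, 2:-2]
        np.testing.assert_allclose(interior[..., 0, 0], expect, atol=1e-6)
        np.testing.assert_allclose(interior[..., 1, 1], expect, atol=1e-6)
        np.testing.assert_allclose(interior[..., 0, 1], 0, atol=1e-6)

    def test_pure_rotation_gives_zero_strain(self):
        H = W = 20
        th = 0.3
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        rel = np.stack([rr - H / 2, cc - W / 2], -1)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        u = rel @ R.T - rel
        E = green_lagrange(u)
        assert np.abs(E[2:-2, 2:-2]).max() < 1e-6

    def test_symmetry(self):
        u = np.random.default_rng(0).standard_normal((12, 12, 2)) * 0.3
        E = green_lagrange(u)
        np.testing.assert_allclose(E, np.swapaxes(E, -1, -2), atol=1e-12)


class TestLocalCoordinates:
    @staticmethod
    def _circular_mask(H=48, center=(24, 24), r_in=8, r_out=14):
        rr, cc = np.meshgrid(np.arange(H), np.arange(H), indexing="ij")
        r = np.hypot(rr - center[0], cc - center[1])
        lab = np.zeros((H, H), dtype=int)
        lab[r <= r_out] = LABEL_MYOCARDIUM
        lab[r <= r_in] = LABEL_LV_POOL
        return lab

    def test_circle_radial_matches_outward_normal(self):
        lab = self._circular_mask()
        r_f, c_f, center = local_coordinates(lab)
        rr, cc = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
        myo = lab == LABEL_MYOCARDIUM
        rel = np.stack([rr - center[0], cc - center[1]], -1)
        rel = rel / np.linalg.norm(rel, axis=-1, keepdims=True)
        dots = np.clip((r_f * rel).sum(-1)[myo], -1, 1)
        assert np.degrees(np.arccos(dots)).max() < 2.0

    def test_orthonormal_frame(self):
        lab = self._circular_mask()
        r_f, c_f, _ = local_coordinates(lab)
        myo = lab == LABEL_MYOCARDIUM
        assert np.abs((r_f * c_f).sum(-1)[myo]).max() < 1e-9
        assert np.abs(np.linalg.norm(r_f, axis=-1)[myo] - 1).max() < 1e-9

    def test_translation_equivariance(self):
        a = self._circular_mask(center=(24, 24))
        b = self._circular_mask(center=(20, 27))
        ra, _, ca = local_coordinates(a)
        rb, _, cb = local_coordinates(b)
        shift = (np.round(cb - ca)).astype(int)
        moved = np.roll(np.roll(ra, shift[0], axis=0), shift[1], axis=1)
        myo_b = b == LABEL_MYOCARDIUM
        inner = myo_b & (np.abs(np.linalg.norm(moved, axis=-1) - 1) < 1e-6)
        assert (np.abs(moved - rb)[inner] < 0.02).all()

    def test_degenerate_contour_rejected(self):
        lab = np.zeros((16, 16), dtype=int)
        lab[8, 8] = LABEL_LV_POOL
        with pytest.raises(ValueError):
            local_coordinates(lab)


class TestProjection:
    def test_isotropic_tensor(self):
        H = 16
        E = np.zeros((H, H, 2, 2))
        E[..., 0, 0] = 0.3
        E[..., 1, 1] = 0.3
        th = np.random.default_rng(1).uniform(0, 2 * np.pi, (H, H))
        r_f = np.stack([np.sin(th), np.cos(th)], -1)
        c_f = np.stack([-r_f[..., 1], r_f[..., 0]], -1)
        err, ecc = project_strain(E, r_f, c_f)
        np.testing.assert_allclose(err, 0.3, atol=1e-12)
        np.testing.assert_allclose(ecc, 0.3, atol=1e-12)

    def test_trace_identity(self):
        rng = np.random.default_rng(2)
        E = rng.standard_normal((8, 8, 2, 2))
        E = 0.5 * (E + np.swapaxes(E, -1, -2))
        th = rng.uniform(0, 2 * np.pi, (8, 8))
        r_f = np.stack([np.sin(th), np.cos(th)], -1)
        c_f = np.stack([-r_f[..., 1], r_f[..., 0]], -1)
        err, ecc = project_strain(E, r_f, c_f)
        np.testing.assert_allclose(err + ecc, E[..., 0, 0] + E[..., 1, 1],
                                   atol=1e-10)


class TestPhantomStrain:
    def test_truth_flow_strain_matches_analytic(self, phantom64):
        gt = phantom64
        sr = compute_strain(gt.true_flow(0, gt.es_frame), gt.labels[0],
                            (1.0, 1.0))
        err_an, ecc_an = gt.analytic_strain_fields()
        myo = gt.labels[0] == LABEL_MYOCARDIUM
        assert sr.mGRS == pytest.approx(np.nanmean(err_an[myo]), rel=0.15)
        assert sr.mGCS == pytest.approx(np.nanmean(ecc_an[myo]), rel=0.15)

    def test_sign_conventions(self, phantom64):
        # thickening wall: radial strain positive, circumferential negative
        sr = compute_strain(phantom64.true_flow(0, phantom64.es_frame),
                            phantom64.labels[0], (1.0, 1.0))
        assert sr.mGRS > 0
        assert sr.mGCS < 0


@pytest.fixture(scope="module")
def stack():
    return generate_slice_stack(PhantomConfig(grid_size=(64, 64), seed=1,
                                              n_slices=4))


class TestBullsEye:

    def test_uniform_field_equal_segments(self, stack):
        fields, masks = [], []
        for g in stack:
            lab = g.labels[0]
            fields.append(np.where(lab == LABEL_MYOCARDIUM, 0.42, np.nan))
            masks.append(lab)
        be = aha17_bullseye(fields, masks)
        np.testing.assert_allclose(be.values, 0.42, atol=1e-12)

    def test_single_sector_hotspot(self, stack):
        from cineflow.function_analysis import (_rv_insertion_angle,
                                                local_coordinates)

        fields, masks = [], []
        for k, g in enumerate(stack):
            lab = g.labels[0]
            f = np.where(lab == LABEL_MYOCARDIUM, 0.1, np.nan)
            if k == 0:   # basal slice: heat exactly one angular sector
                _, _, center = local_coordinates(lab)
                th0 = _rv_insertion_angle(lab, center)
                rr, cc = np.nonzero(lab == LABEL_MYOCARDIUM)
                ang = (np.arctan2(rr - center[0], cc - center[1]) - th0) \
                    % (2 * np.pi)
                hot = ang < (2 * np.pi / 6)
                f[rr[hot], cc[hot]] = 5.0
            fields.append(f)
            masks.append(lab)
        be = aha17_bullseye(fields, masks)
        basal = be.values[:6]
        assert basal.argmax() == 0
        assert (basal[1:] < basal[0]).all()
        np.testing.assert_allclose(be.values[6:], 0.1, atol=1e-9)

    def test_requires_three_slices(self, stack):
        with pytest.raises(ValueError, match="3 slices"):
            aha17_bullseye([np.zeros((8, 8))], [np.zeros((8, 8), int)])
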