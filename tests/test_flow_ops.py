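"""Displacement-field utilities: warping, composition, Jacobian analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cineflow import flow_ops


def bilinear_oracle(src, u):
    """Nested-loop backward warp with edge clamping (independent oracle)."""
    H, W = src.shape
    out = np.zeros_like(src, dtype=float)
    for i in range(H):
        for j in range(W):
            r = min(max(i + u[i, j, 0], 0), H - 1)
            c = min(max(j + u[i, j, 1], 0), W - 1)
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            r1, c1 = min(r0 + 1, H - 1), min(c0 + 1, W - 1)
            fr, fc = r - r0, c - c0
            out[i, j] = (src[r0, c0] * (1 - fr) * (1 - fc)
                         + src[r0, c1] * (1 - fr) * fc
                         + src[r1, c0] * fr * (1 - fc)
                         + src[r1, c1] * fr * fc)
    return out


class TestWarp:
    def test_zero_flow_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((9, 9))
        np.testing.assert_array_almost_equal(
            flow_ops.warp_image(img, np.zeros((9, 9, 2))), img)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((8, 8))
        u = rng.uniform(-2, 2, (8, 8, 2))
        np.testing.assert_allclose(flow_ops.warp_image(img, u),
                                   bilinear_oracle(img, u), atol=1e-10)

    def test_unit_shift_recovers_original(self):
        # source(p) = s(p + 1 column); warping by u = (0, -1) undoes the shift
        rng = np.random.default_rng(2)
        s = rng.standard_normal((8, 8))
        shifted = np.roll(s, -1, axis=1)
        u = np.zeros((8, 8, 2))
        u[..., 1] = -1.0
        rec = flow_ops.warp_image(shifted, u)
        np.testing.assert_allclose(rec[:, 1:-1], s[:, 1:-1], atol=1e-12)

    def test_nearest_preserves_label_values(self):
        labels = np.random.default_rng(3).integers(0, 4, (12, 12))
        u = np.random.default_rng(4).uniform(-3, 3, (12, 12, 2))
        warped = flow_ops.warp_image(labels, u, mode="nearest")
        assert set(np.unique(warped)) <= set(np.unique(labels))
        assert warped.dtype == labels.dtype

    def test_nan_flow_rejected(self):
        u = np.zeros((4, 4, 2))
        u[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            flow_ops.warp_image(np.zeros((4, 4)), u)

    @given(st.floats(-2, 2), st.floats(-2, 2))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_warp_linear_in_intensities(self, a, b):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((6, 6))
        y = rng.standard_normal((6, 6))
        u = rng.uniform(-1, 1, (6, 6, 2))
        lhs = flow_ops.warp_image(a * x + b * y, u)
        rhs = a * flow_ops.warp_image(x, u) + b * flow_ops.warp_image(y, u)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestCompose:
    def test_identity_element(self):
        u = np.random.default_rng(0).uniform(-1, 1, (8, 8, 2))
        z = np.zeros_like(u)
        np.testing.assert_allclose(flow_ops.compose_flows(z, u), u, atol=1e-9)
        # compose(u, 0)(p) = 0 + u(p)
        np.testing.assert_allclose(flow_ops.compose_flows(u, z), u, atol=1e-9)

    def test_inverse_roundtrip_on_phantom(self, phantom64):
        gt = phantom64
        es = gt.es_frame
        resid = flow_ops.compose_flows(gt.true_flow(0, es),
                                       gt.true_flow(es, 0))
        assert np.abs(resid).mean() < 0.5

    def test_chain_matches_direct_phantom_flow(self, phantom64):
        gt = phantom64
        f_06 = gt.true_flow(0, 6)
        f_612 = gt.true_flow(6, 12)
        chained = flow_ops.compose_flows(f_612, f_06)
        direct = gt.true_flow(0, 12)
        interior = np.abs(chained - direct)[4:-4, 4:-4]
        assert interior.mean() < 0.05

    def test_associativity_on_smooth_flows(self):
        rng = np.random.default_rng(6)
        from scipy.ndimage import gaussian_filter

        flows = []
        for _ in range(3):
            u = rng.standard_normal((16, 16, 2))
            u = np.stack([gaussian_filter(u[..., k], 3) for k in (0, 1)], -1)
            flows.append(u.astype(float))
        a, b, c = flows
        lhs = flow_ops.compose_flows(a, flow_ops.compose_flows(b, c))
        rhs = flow_ops.compose_flows(flow_ops.compose_flows(a, b), c)
        assert np.abs(lhs - rhs)[3:-3, 3:-3].max() < 0.05


class TestJacobian:
    def test_zero_flow_unit_determinant(self):
        det = flow_ops.jacobian_determinant(np.zeros((8, 8, 2)))
        np.testing.assert_allclose(det, 1.0)
        assert flow_ops.nonpositive_jacobian_fraction(np.zeros((8, 8, 2))) == 0.0

    def test_uniform_scaling_determinant(self):
        H = W = 16
        alpha = 0.25
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        u = np.stack([alpha * rr, alpha * cc], axis=-1).astype(float)
        det = flow_ops.jacobian_determinant(u)
        np.testing.assert_allclose(det[1:-1, 1:-1], (1 + alpha) ** 2,
                                   atol=1e-9)

    def test_fold_detected(self):
        u = np.zeros((10, 10, 2))
        u[:, :5, 1] = 4.0    # strong opposing shift creates a fold
        u[:, 5:, 1] = -4.0
        frac = flow_ops.nonpositive_jacobian_fraction(u)
        assert frac > 0
        assert 0 <= frac <= 100

    def test_phantom_flows_fold_free(self, phantom64):
        gt = phantom64
        fractions = [flow_ops.nonpositive_jacobian_fraction(gt.true_flow(0, t))
                     for t in (6, gt.es_frame)]
        assert fractions == [0.0, 0.0]
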