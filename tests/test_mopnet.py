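"""Registration network: grouping, correlation oracles, recurrence contracts,
sliding-window inference."""

import numpy as np
import pytest

from cineflow import nn
from cineflow.mopnet import (FlowTable, Mopnet, MopnetConfig, TINY_PROFILE,
                             build_tri_frame_groups, estimate_motion,
                             full_cycle_inference, load_checkpoint,
                             plan_windows, save_checkpoint)
from cineflow.nn.tensor import Tensor


@pytest.fixture(scope="module")
def tiny_model():
    return Mopnet(MopnetConfig(seed=0, **TINY_PROFILE))


class TestTriFrameGrouping:
    def test_overlapping_groups(self):
        frames = np.arange(5)[:, None, None] * np.ones((1, 4, 4))
        g = build_tri_frame_groups(frames)
        assert [int(f[0, 0]) for f in g.bwd] == [0, 1, 2]
        assert [int(f[0, 0]) for f in g.fixed] == [1, 2, 3]
        assert [int(f[0, 0]) for f in g.fwd] == [2, 3, 4]

    def test_identical_frames_identical_groups(self):
        frames = np.ones((5, 4, 4))
        g = build_tri_frame_groups(frames)
        np.testing.assert_array_equal(g.bwd, g.fwd)

    def test_wrong_frame_count_rejected(self):
        with pytest.raises(ValueError, match="5 frames"):
            build_tri_frame_groups(np.ones((4, 4, 4)))


class TestFeatures:
    def test_shared_encoder_and_shapes(self, tiny_model):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 32, 32)).astype(np.float32)
        frames = np.stack([a, b, a, b, a])[None]   # bwd and fwd groups equal
        groups = np.stack([frames[:, 0:3], frames[:, 1:4], frames[:, 2:5]], 1)
        feats, ctx, h_init, att = tiny_model.extract_features(groups)
        ds = tiny_model.cfg.feature_downsample
        assert feats.shape[-2:] == (32 // ds, 32 // ds)
        np.testing.assert_allclose(feats.data[:, 0], feats.data[:, 2],
                                   atol=1e-6)

    def test_attention_rows_normalized(self, tiny_model):
        rng = np.random.default_rng(1)
        groups = rng.standard_normal((2, 3, 3, 32, 32)).astype(np.float32)
        *_, att = tiny_model.extract_features(groups)
        np.testing.assert_allclose(att.data.sum(axis=-1), 1.0, atol=1e-5)


class TestCorrelation:
    def test_matches_bruteforce_dot_products(self):
        rng = np.random.default_rng(2)
        f1 = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32))
        f2 = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32))
        pyr = Mopnet.build_correlation_volumes(f1, f2, n_levels=1)
        corr = pyr[0].data[0]
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    for l in range(4):
                        expect = np.dot(f1.data[0, :, i, j],
                                        f2.data[0, :, k, l]) / np.sqrt(8)
                        assert corr[i, j, k, l] == pytest.approx(expect,
                                                                 abs=1e-5)

    def test_self_correlation_argmax_is_identity(self):
        # unit-norm feature vectors: self-similarity maximal by Cauchy-Schwarz
        rng = np.random.default_rng(3)
        f = rng.standard_normal((1, 16, 6, 6))
        f = f / np.linalg.norm(f, axis=1, keepdims=True)
        f = Tensor(f.astype(np.float32))
        corr = Mopnet.build_correlation_volumes(f, f, n_levels=1)[0].data[0]
        for i in range(6):
            for j in range(6):
                flat = corr[i, j].ravel()
                assert flat.argmax() == i * 6 + j

    def test_pyramid_halves_target_dims(self):
        rng = np.random.default_rng(4)
        f = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        pyr = Mopnet.build_correlation_volumes(f, f, n_levels=3)
        assert [p.shape[-1] for p in pyr] == [8, 4, 2]

    def test_memory_guard(self):
        f = Tensor(np.zeros((1, 4, 80, 80), dtype=np.float32))
        with pytest.raises(MemoryError):
            Mopnet.build_correlation_volumes(f, f, n_levels=1, max_grid=64)


class TestLookup:
    def test_matches_nested_loop_gather(self):
        rng = np.random.default_rng(5)
        N, h, w = 1, 5, 5
        radius, levels = 1, 2
        f1 = Tensor(rng.standard_normal((N, 6, h, w)).astype(np.float32))
        f2 = Tensor(rng.standard_normal((N, 6, h, w)).astype(np.float32))
        pyr = Mopnet.build_correlation_volumes(f1, f2, n_levels=levels)
        flow = Tensor(rng.uniform(-1, 1, (N, h, w, 2)).astype(np.float32))
        out = Mopnet.lookup_correlation(pyr, flow, radius).data

        def sample(vol, r, c):
            hl, wl = vol.shape
            r = min(max(r, 0), hl - 1)
            c = min(max(c, 0), wl - 1)
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            r1, c1 = min(r0 + 1, hl - 1), min(c0 + 1, wl - 1)
            fr, fc = r - r0, c - c0
            return (vol[r0, c0] * (1 - fr) * (1 - fc)
                    + vol[r0, c1] * (1 - fr) * fc
                    + vol[r1, c0] * fr * (1 - fc)
                    + vol[r1, c1] * fr * fc)

        P = (2 * radius + 1) ** 2
        for i in range(h):
            for j in range(w):
                ch = 0
                for lvl in range(levels):
                    vol = pyr[lvl].data[0, i, j]
                    cy = (i + flow.data[0, i, j, 0]) / 2**lvl
                    cx = (j + flow.data[0, i, j, 1]) / 2**lvl
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            expect = sample(vol, cy + dy, cx + dx)
                            assert out[0, ch, i, j] == pytest.approx(
                                expect, abs=1e-5), (i, j, lvl, dy, dx)
                            ch += 1
                assert ch == levels * P


class TestMopRecurrence:
    def test_zero_flow_warp_preserves_states(self, tiny_model):
        rng = np.random.default_rng(6)
        Ch = tiny_model.cfg.hidden_channels
        state = Tensor(rng.standard_normal((3, Ch, 8, 8)).astype(np.float32))
        zero = Tensor(np.zeros((3, 8, 8, 2), dtype=np.float32))
        states = {"fixed": state, "fwd": state, "bwd": state}
        f_corr = Tensor(rng.standard_normal((3, Ch, 8, 8)).astype(np.float32))
        f_flow = Tensor(rng.standard_normal((3, Ch, 8, 8)).astype(np.float32))
        tiny_model.mop_update(states, zero, zero, f_corr, f_flow)
        # after the update the stored fwd/bwd states are the (identity-)warped
        # previous states
        np.testing.assert_allclose(states["fwd"].data, state.data, atol=1e-6)
        np.testing.assert_allclose(states["bwd"].data, state.data, atol=1e-6)

    def test_mop_feature_channel_count(self, tiny_model):
        from cineflow.nn.tensor import concatenate

        Ch = tiny_model.cfg.hidden_channels
        state = Tensor(np.zeros((3, Ch, 8, 8), dtype=np.float32))
        cat = concatenate([state, state, state], axis=1)
        assert cat.shape[1] == 3 * Ch


class TestEstimateMotion:
    def test_zero_iterations_give_exactly_zero_flow(self, tiny_model):
        frames = np.random.default_rng(7).standard_normal((5, 32, 32))
        pair = estimate_motion(frames, tiny_model, K=0)
        assert np.abs(pair.ufwd).max() == 0.0
        assert np.abs(pair.ubwd).max() == 0.0

    def test_output_shapes_and_determinism(self, tiny_model):
        frames = np.random.default_rng(8).standard_normal((5, 32, 32))
        a = estimate_motion(frames, tiny_model)
        b = estimate_motion(frames, tiny_model)
        assert a.ufwd.shape == (3, 32, 32, 2)
        np.testing.assert_array_equal(a.ufwd, b.ufwd)

    def test_nonfinite_input_rejected(self, tiny_model):
        frames = np.zeros((5, 32, 32))
        frames[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            estimate_motion(frames, tiny_model)

    def test_trained_model_static_sequence_near_zero(self, trained_registrar,
                                                     static_phantom):
        from cineflow.unet import normalize_image

        frames = np.stack([normalize_image(f)
                           for f in static_phantom.images.frames])
        pair = estimate_motion(frames, trained_registrar.model_)
        assert np.abs(pair.ufwd).mean() < 0.3

    def test_trained_model_recovers_phantom_motion(self, trained_registrar,
                                                   phantom32):
        from cineflow.unet import normalize_image

        gt = phantom32
        norm = np.stack([normalize_image(f) for f in gt.images.frames])
        idx = [0, 4, 8, 12, 16]
        pair = estimate_motion(norm[idx], trained_registrar.model_)
        for m in range(3):
            truth = gt.true_flow(idx[1 + m], idx[2 + m])
            epe = np.linalg.norm(pair.ufwd[m] - truth, axis=-1).mean()
            assert epe < 1.0


class TestFullCycle:
    def test_window_plan_contracts(self):
        for T in (5, 7, 25):
            emitted = []
            for start, stride in plan_windows(T):
                idx = [(start + k * stride) % T for k in range(5)]
                for m in range(3):
                    emitted.append((idx[1 + m], idx[2 + m]))
            unique = set(emitted)
            # adjacent cyclic pairs all covered, including the wrap
            for i in range(T):
                assert (i, (i + 1) % T) in unique
            assert (T - 1, 0) in unique

    def test_emitted_pairs_unique_and_reach_reference(self, tiny_model):
        frames = np.random.default_rng(9).standard_normal((7, 32, 32))
        table = full_cycle_inference(frames, tiny_model, K=1)
        pairs = table.pairs()
        assert len(pairs) == len(set(pairs))
        for t in range(7):
            assert table.flow(t, 0).shape == (32, 32, 2)

    def test_too_short_sequence_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            full_cycle_inference(np.zeros((4, 32, 32)), tiny_model)

    def test_composition_with_truth_flows(self, phantom64):
        gt = phantom64
        T = gt.images.n_frames
        table = FlowTable(T)
        for start, stride in plan_windows(T):
            idx = [(start + m * stride) % T for m in range(5)]
            for m in range(3):
                i, j = idx[1 + m], idx[2 + m]
                if (i, j) not in table.flows and i != j:
                    table.add(i, j, gt.true_flow(i, j))
        comp = table.to_reference(0)
        truth = gt.flow_to_reference(0)
        assert np.linalg.norm(comp - truth, axis=-1).mean() < 0.05


def test_checkpoint_roundtrip(tmp_path, tiny_model):
    frames = np.random.default_rng(10).standard_normal((5, 32, 32))
    before = estimate_motion(frames, tiny_model)
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, path)
    restored = load_checkpoint(path)
    after = estimate_motion(frames, restored)
    np.testing.assert_array_equal(before.ufwd, after.ufwd)
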