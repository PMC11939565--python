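"""Uncertainty measures, Grad-CAM, and attention maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.transform import resize

from cytomil.data import Bag
from cytomil.interpret import (
    attention_map,
    embedding_norm,
    grad_cam,
    uncertainty_entropy,
    uncertainty_max,
    uncertainty_record,
)
from cytomil.models.tcs_cnn import TCSCNN, TCSCNNConfig


def _simplex(seed, c=4):
    return np.random.default_rng(seed).dirichlet(np.ones(c))


class TestUncertaintyMax:
    def test_uniform(self):
        assert uncertainty_max(np.full(4, 0.25)) == -0.25

    def test_one_hot(self):
        assert uncertainty_max(np.array([0.0, 1.0, 0.0, 0.0])) == -1.0

    def test_direct_readoff(self):
        assert uncertainty_max(np.array([0.7, 0.1, 0.1, 0.1])) == pytest.approx(-0.7)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, seed):
        u = uncertainty_max(_simplex(seed))
        assert -1.0 <= u <= -0.25 + 1e-12


class TestUncertaintyEntropy:
    def test_one_hot_zero(self):
        assert uncertainty_entropy(np.array([0.0, 0.0, 1.0, 0.0])) == 0.0

    def test_uniform_is_maximum(self):
        assert uncertainty_entropy(np.full(4, 0.25)) == pytest.approx(np.log(4))

    def test_scalar_evaluation(self):
        p = np.array([0.7, 0.1, 0.1, 0.1])
        expected = -(0.7 * np.log(0.7) + 3 * 0.1 * np.log(0.1))
        assert uncertainty_entropy(p) == pytest.approx(expected)
        assert round(uncertainty_entropy(p), 4) == 0.9404

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_max_at_uniform(self, seed):
        p = _simplex(seed)
        h = uncertainty_entropy(p)
        assert 0.0 <= h <= np.log(4) + 1e-12
        if not np.allclose(p, 0.25):
            assert h < np.log(4)

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_entropy(np.array([0.5, 0.6]))


class TestEmbeddingNorm:
    def test_zero_vector(self):
        assert embedding_norm(np.zeros(256)) == 0.0

    def test_unit_basis(self):
        z = np.zeros(256)
        z[17] = 1.0
        assert embedding_norm(z) == 1.0

    def test_three_four_five(self):
        z = np.zeros(256)
        z[0], z[1] = 3.0, 4.0
        assert embedding_norm(z) == 5.0


def test_uncertainty_record_triplet():
    rec = uncertainty_record(np.full(4, 0.25), np.zeros(8))
    assert (rec.u_max, rec.u_entropy, rec.z_norm) == (-0.25, pytest.approx(np.log(4)), 0.0)


TINY = TCSCNNConfig(
    conv_channels=(4, 4, 4, 4, 4), fc_sizes=(8, 6), input_size=32, dropout_rate=0.0, seed=0
)


class TestGradCAM:
    def test_shape_and_range(self, rng):
        model = TCSCNN(TINY)
        cam = grad_cam(model, rng.random((32, 32, 3)), 1)
        assert cam.shape == (32, 32)
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_constant_score_gives_zero_map(self, rng):
        model = TCSCNN(TINY)
        model.head.params["W"][...] = 0.0
        cam = grad_cam(model, rng.random((32, 32, 3)), 2)
        assert not cam.any()

    def test_deterministic_gradients(self, rng):
        model = TCSCNN(TINY)
        x = rng.random((32, 32, 3))
        assert np.array_equal(grad_cam(model, x, 0), grad_cam(model, x, 0))

    def test_invalid_class_rejected(self, rng):
        with pytest.raises(ValueError):
            grad_cam(TCSCNN(TINY), rng.random((32, 32, 3)), 9)

    def test_linear_toy_network_matches_chain_rule(self):
        """One-channel delta-kernel network: every conv is an identity,
        so the final conv map A holds block maxima of the input's red
        channel; with identity FC weights and head weights w_c, the
        hand-derived map is ReLU(w_c/4 * A), i.e. proportional to A for
        w_c > 0 and identically zero for w_c < 0."""
        cfg = TCSCNNConfig(
            conv_channels=(1, 1, 1, 1, 1),
            fc_sizes=(1, 1),
            input_size=32,
            dropout_rate=0.0,
            l2_coefficient=0.0,
            seed=0,
        )
        model = TCSCNN(cfg)
        for i, layer in enumerate(model.blocks):
            if hasattr(layer, "k"):
                layer.params["W"][...] = 0.0
                layer.params["W"][1, 1, 0, 0] = 1.0
                layer.params["b"][...] = 0.0
        for layer in model.fc_layers:
            if "W" in layer.params:
                layer.params["W"][...] = 1.0
                layer.params["b"][...] = 0.0
        model.head.params["W"][...] = 0.0
        model.head.params["b"][...] = 0.0
        model.head.params["W"][0, 0] = 1.0
        model.head.params["W"][0, 1] = -1.0

        x = np.zeros((32, 32, 3))
        x[:, :, 0] = (np.arange(32 * 32).reshape(32, 32) + 1) / 1100.0  # strict ramp

        # hand derivation: A[r,c] = block max = bottom-right input of
        # each 16x16 block (ramp is strictly increasing)
        A = np.array(
            [[x[16 * r + 15, 16 * c + 15, 0] for c in range(2)] for r in range(2)]
        )
        expected = (A - A.min()) / (A.max() - A.min())
        expected = resize(expected, (32, 32), order=1, mode="edge", anti_aliasing=False)

        cam_pos = grad_cam(model, x, 0)
        assert np.allclose(cam_pos, expected, atol=1e-10)
        # negative head weight: ReLU kills the whole map
        assert not grad_cam(model, x, 1).any()

    def test_heatmap_concentrates_on_blobs(self, patch_run):
        """On the trained synthetic classifier, mean Grad-CAM mass
        inside ground-truth blob regions exceeds the mass outside."""
        model = patch_run["model"]
        Xv, yv, cv = patch_run["X_val"], patch_run["y_val"], patch_run["centers_val"]
        yy, xx = np.mgrid[0:64, 0:64]
        inside, outside = [], []
        for i in range(len(Xv)):
            if yv[i] == 0 or not cv[i]:
                continue
            cam = grad_cam(model, Xv[i], int(yv[i]))
            m = np.zeros((64, 64), bool)
            for by, bx in cv[i]:
                m |= (yy - by) ** 2 + (xx - bx) ** 2 <= 36
            if m.all() or not m.any():
                continue
            inside.append(cam[m].mean())
            outside.append(cam[~m].mean())
        assert np.mean(inside) > np.mean(outside)


class TestAttentionMap:
    def _bag(self, rng):
        return Bag("b", rng.random((16, 8, 8, 3)).astype(np.float32), np.ones(16, bool), 1)

    def test_uniform_scores_uniform_grid(self, rng):
        grid, overlay = attention_map(self._bag(rng), np.full(16, 1 / 16))
        assert np.allclose(grid, 1 / 16)
        assert overlay.shape == (32, 32, 3) and overlay.dtype == np.uint8

    def test_one_hot_lands_on_correct_cell(self, rng):
        scores = np.zeros(16)
        scores[9] = 1.0  # sp_index 9 -> row 2, col 1
        grid, _ = attention_map(self._bag(rng), scores)
        assert grid[2, 1] == 1.0 and grid.sum() == 1.0

    def test_grid_round_trip(self, rng):
        scores = np.random.default_rng(3).dirichlet(np.ones(16))
        grid, _ = attention_map(self._bag(rng), scores)
        assert np.array_equal(grid.ravel(), scores)

    def test_unnormalized_scores_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_map(self._bag(rng), np.ones(16))
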