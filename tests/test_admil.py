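"""Gated attention pooling and the MIL bag classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytomil.data import Bag
from cytomil.models.admil import (
    ADMIL,
    AttentionPool,
    GatedAttentionParams,
    MILConfig,
    classify_bag,
    extract_instance_embeddings,
    gated_attention,
    pool,
)
from cytomil.models.tcs_cnn import TCSCNNConfig

TINY_BACKBONE = TCSCNNConfig(
    conv_channels=(2, 4, 4, 4, 4), fc_sizes=(8, 6), input_size=32, dropout_rate=0.0, seed=0
)


def _params(rng, L=2, D=2):
    return GatedAttentionParams(
        w=rng.normal(size=L), V=rng.normal(size=(L, D)), U=rng.normal(size=(L, D))
    )


def _bag(rng, label=1, size=32):
    return Bag(
        "b", rng.random((16, size, size, 3)).astype(np.float32), np.ones(16, bool), label
    )


class TestGatedAttention:
    def test_identical_instances_uniform_weights(self, rng):
        H = np.tile(rng.normal(size=3), (16, 1))
        a = gated_attention(H, _params(rng, L=4, D=3))
        assert np.allclose(a, 1 / 16, atol=1e-12)

    def test_single_instance_degenerate_softmax(self, rng):
        a = gated_attention(rng.normal(size=(1, 2)), _params(rng))
        assert a.shape == (1,) and a[0] == 1.0

    def test_matches_scalar_oracle(self, rng):
        """Brute-force evaluation with python scalars: s_n =
        w^T(tanh(V h_n) * sigmoid(U h_n)), a = exp(s)/sum exp(s)."""
        import math

        H = rng.normal(size=(3, 2))
        p = _params(rng, L=2, D=2)
        scores = []
        for n in range(3):
            s = 0.0
            for l in range(2):
                vh = sum(p.V[l][d] * H[n][d] for d in range(2))
                uh = sum(p.U[l][d] * H[n][d] for d in range(2))
                s += p.w[l] * math.tanh(vh) * (1.0 / (1.0 + math.exp(-uh)))
            scores.append(s)
        exp = [math.exp(s) for s in scores]
        expected = np.array([e / sum(exp) for e in exp])
        assert np.allclose(gated_attention(H, p), expected, atol=1e-10)

    def test_empty_bag_rejected(self, rng):
        with pytest.raises(ValueError):
            gated_attention(np.empty((0, 2)), _params(rng))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_positive_and_normalized(self, seed):
        r = np.random.default_rng(seed)
        H = r.normal(scale=5, size=(r.integers(1, 20), 3))
        a = gated_attention(H, _params(r, L=4, D=3))
        assert (a > 0).all() and np.isclose(a.sum(), 1.0, atol=1e-9)

    def test_masked_slots_get_zero_weight(self, rng):
        H = rng.normal(size=(6, 3))
        mask = np.array([True, False, True, True, False, True])
        a = gated_attention(H, _params(rng, L=4, D=3), mask=mask)
        assert np.allclose(a[~mask], 0.0) and np.isclose(a.sum(), 1.0)


class TestPooling:
    def test_one_hot_selects_instance(self, rng):
        H = rng.normal(size=(5, 4))
        a = np.zeros(5)
        a[3] = 1.0
        assert np.allclose(pool(H, a), H[3])

    def test_identical_rows_convexity(self, rng):
        row = rng.normal(size=4)
        H = np.tile(row, (5, 1))
        a = rng.dirichlet(np.ones(5))
        assert np.allclose(pool(H, a), row)

    def test_hand_weighted_sum(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(pool(H, np.array([0.3, 0.7])), [0.3, 0.7])


def test_attention_pool_gradients_match_finite_differences(rng):
    ap = AttentionPool(4, 3, rng)
    H = rng.normal(size=(6, 4))
    g_out = rng.normal(size=4)

    def f():
        z, _ = ap.forward(H)
        return float(z @ g_out)

    ap.zero_grads()
    ap.forward(H)
    dH = ap.backward(g_out)
    for key in ("w", "V", "U"):
        flat = ap.params[key]
        for idx in range(flat.size):
            orig = flat.flat[idx]
            flat.flat[idx] = orig + 1e-6
            lp = f()
            flat.flat[idx] = orig - 1e-6
            lm = f()
            flat.flat[idx] = orig
            assert abs((lp - lm) / 2e-6 - ap.grads[key].flat[idx]) < 1e-6
    for idx in range(H.size):
        orig = H.flat[idx]
        H.flat[idx] = orig + 1e-6
        lp = f()
        H.flat[idx] = orig - 1e-6
        lm = f()
        H.flat[idx] = orig
        assert abs((lp - lm) / 2e-6 - dH.flat[idx]) < 1e-6


class TestInstanceEmbeddings:
    def test_weight_sharing_identical_slots(self, rng):
        model = ADMIL(MILConfig(backbone=TINY_BACKBONE, attention_dim=4, seed=1))
        bag1, bag2 = _bag(rng), _bag(rng)
        bag2.instances[5] = bag1.instances[2]
        H1 = extract_instance_embeddings(model.backbone, bag1)
        H2 = extract_instance_embeddings(model.backbone, bag2)
        assert np.allclose(H1[2], H2[5], atol=1e-12)

    def test_zero_slots_share_one_embedding(self, rng):
        model = ADMIL(MILConfig(backbone=TINY_BACKBONE, attention_dim=4, seed=1))
        bag = _bag(rng)
        bag.instances[3] = 0.0
        bag.instances[9] = 0.0
        H = extract_instance_embeddings(model.backbone, bag)
        assert np.allclose(H[3], H[9], atol=1e-12)

    def test_embedding_dimension(self, rng):
        model = ADMIL(MILConfig(backbone=TINY_BACKBONE, attention_dim=4, seed=1))
        H = extract_instance_embeddings(model.backbone, _bag(rng))
        assert H.shape == (16, TINY_BACKBONE.embedding_dim)


class TestClassifyBag:
    def test_output_simplex_and_attention_normalized(self, rng):
        model = ADMIL(MILConfig(backbone=TINY_BACKBONE, attention_dim=4, seed=2))
        pred = classify_bag(model, _bag(rng))
        assert np.isclose(pred.probabilities.sum(), 1.0, atol=1e-6)
        assert np.isclose(pred.attention.sum(), 1.0, atol=1e-6)
        assert (pred.attention > 0).all()

    def test_permutation_equivariance(self, rng):
        """Permuting bag slots permutes attention identically and leaves
        z and the probabilities unchanged."""
        model = ADMIL(MILConfig(backbone=TINY_BACKBONE, attention_dim=4, seed=3))
        bag = _bag(rng)
        pred = classify_bag(model, bag)
        perm = rng.permutation(16)
        shuffled = Bag("b2", bag.instances[perm], bag.mask[perm], bag.label)
        pred2 = classify_bag(model, shuffled)
        assert np.allclose(pred2.attention, pred.attention[perm], atol=1e-10)
        assert np.allclose(pred2.z, pred.z, atol=1e-10)
        assert np.allclose(pred2.probabilities, pred.probabilities, atol=1e-10)

    def test_masked_mode_excludes_padded_slots(self, rng):
        model = ADMIL(
            MILConfig(backbone=TINY_BACKBONE, attention_dim=4, mask_padded=True, seed=4)
        )
        bag = _bag(rng)
        bag.mask[10:] = False
        bag.instances[10:] = 0.0
        pred = classify_bag(model, bag)
        assert np.allclose(pred.attention[10:], 0.0)
        assert np.isclose(pred.attention.sum(), 1.0)


def test_trained_mil_attends_to_signal_slots(mil_run):
    """On synthetic bags with 4 signal slots the trained model puts more
    attention mass on signal slots than on near-empty slots."""
    model = mil_run["model"]
    sig_means, empty_means = [], []
    for bag, label, slots in zip(
        mil_run["bags"], mil_run["labels"], mil_run["signal_slots"]
    ):
        if label == 0:
            continue
        a = classify_bag(model, bag).attention
        empty = [n for n in range(16) if n not in slots]
        sig_means.append(a[slots].mean())
        empty_means.append(a[empty].mean())
    assert np.mean(sig_means) > np.mean(empty_means)
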