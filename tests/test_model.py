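"""Network contracts: attention oracles, relative positions, layer wiring,
gradient reversal, checkpointing, parameter counts."""

import numpy as np
import pytest

from tsapred.autodiff import Tensor, log_softmax
from tsapred.model import (ModelConfig, MultiHeadAttention, SpatialModel,
                           parameter_count, scaled_dot_attention,
                           sinusoidal_relative_encodings)


def small_cfg(**kw):
    base = dict(encoder_hidden=8, encoder_out=8, n_heads=2, n_layers=1,
                ffn_dim=16, dropout=0.0, window=3)
    base.update(kw)
    return ModelConfig(**base)


# --------------------------------------------------- scaled dot attention
def test_attention_singleton():
    Q = np.array([[1.0, 2.0]])
    V = np.array([[5.0, -1.0, 2.0]])
    out, w = scaled_dot_attention(Q, Q, V)
    assert np.allclose(w.data, [[1.0]])
    assert np.allclose(out.data, V)


def test_attention_orthogonal_uniform():
    Q = np.array([[1.0, 0.0], [2.0, 0.0], [0.5, 0.0]])
    K = np.array([[0.0, 1.0], [0.0, -1.0], [0.0, 3.0]])
    V = np.arange(6.0).reshape(3, 2)
    out, w = scaled_dot_attention(Q, K, V)
    assert np.allclose(w.data, 1.0 / 3.0)
    assert np.allclose(out.data, np.tile(V.mean(axis=0), (3, 1)))


def test_attention_brute_force_oracle():
    # fixed printed values; oracle: exponentiate, normalize, mix by hand
    Q = np.array([[0.3, -1.2], [2.0, 0.5], [-0.7, 0.1]])
    K = np.array([[1.0, 0.0], [0.2, -0.4], [-1.5, 2.2]])
    V = np.array([[1.0, 2.0], [-3.0, 0.5], [0.0, 1.0]])
    logits = (Q @ K.T) / np.sqrt(2.0)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    expected = p @ V
    out, w = scaled_dot_attention(Q, K, V)
    assert np.abs(w.data - p).max() < 1e-6
    assert np.abs(out.data - expected).max() < 1e-6


def test_attention_mask_restricts_support():
    rng = np.random.default_rng(0)
    Q, K, V = (rng.normal(size=(4, 3)) for _ in range(3))
    mask = np.array([True, False, True, False])
    out, w = scaled_dot_attention(Q, K, V, mask)
    assert np.allclose(w.data[:, ~mask], 0.0)
    assert np.allclose(w.data.sum(axis=1), 1.0)


def test_attention_all_masked_raises():
    Q = np.ones((2, 2))
    with pytest.raises(ValueError):
        scaled_dot_attention(Q, Q, Q, np.zeros(2, dtype=bool))


def test_attention_dk_mismatch_raises():
    with pytest.raises(ValueError):
        scaled_dot_attention(np.ones((2, 3)), np.ones((2, 2)), np.ones((2, 2)))


# ------------------------------------------------------------- multi-head
def test_mha_identity_reduces_to_scaled_dot():
    cfg = ModelConfig(encoder_hidden=4, encoder_out=2, n_heads=1, n_layers=1,
                      ffn_dim=8, window=2, relative_position=False)
    rng = np.random.default_rng(0)
    mha = MultiHeadAttention(rng, cfg)
    d = cfg.d_model
    for W in (mha.Wq, mha.Wk, mha.Wv, mha.Wo):
        W.data = np.eye(d)
    x = np.random.default_rng(1).normal(size=(1, 5, d))
    mask = np.ones((1, 5), dtype=bool)
    out = mha(Tensor(x), mask)
    ref, _ = scaled_dot_attention(x[0], x[0], x[0])
    assert np.abs(out.data[0] - ref.data).max() < 1e-10


def test_mha_head_permutation_invariance():
    cfg = small_cfg(relative_position=False)
    rng = np.random.default_rng(0)
    mha = MultiHeadAttention(rng, cfg)
    x = Tensor(np.random.default_rng(1).normal(size=(1, 5, cfg.d_model)))
    mask = np.ones((1, 5), dtype=bool)
    base = mha(x, mask).data.copy()
    # swap the two heads in every projection and the matching rows of Wo
    dk = cfg.d_k

    def swap_cols(W):
        W.data = np.concatenate([W.data[:, dk:], W.data[:, :dk]], axis=1)

    for W in (mha.Wq, mha.Wk, mha.Wv):
        swap_cols(W)
    mha.Wo.data = np.concatenate([mha.Wo.data[dk:], mha.Wo.data[:dk]], axis=0)
    assert np.abs(mha(x, mask).data - base).max() < 1e-10


def test_mha_permutation_equivariance_without_positions():
    cfg = small_cfg(relative_position=False)
    rng = np.random.default_rng(0)
    mha = MultiHeadAttention(rng, cfg)
    x = np.random.default_rng(1).normal(size=(1, 6, cfg.d_model))
    mask = np.ones((1, 6), dtype=bool)
    perm = np.array([3, 0, 5, 1, 4, 2])
    out = mha(Tensor(x), mask).data
    out_p = mha(Tensor(x[:, perm]), mask).data
    assert np.abs(out[:, perm] - out_p).max() < 1e-10


# ------------------------------------------------------ relative positions
def test_relative_encodings_depend_on_offset_only():
    enc5 = sinusoidal_relative_encodings(5, 8)
    enc7 = sinusoidal_relative_encodings(7, 8)
    # offset 0 row is at index L-1; offset +2 at L+1
    assert np.allclose(enc5[4], enc7[6])
    assert np.allclose(enc5[6], enc7[8])


def test_position_bias_toeplitz():
    cfg = small_cfg()
    rng = np.random.default_rng(0)
    mha = MultiHeadAttention(rng, cfg)
    mha.v.data = rng.normal(size=mha.v.data.shape)
    B = mha.position_bias_matrix(6)
    for h in range(cfg.n_heads):
        for off in range(-5, 6):
            diag = np.diagonal(B[h], offset=off)
            assert np.allclose(diag, diag[0], atol=1e-12)


def test_zeroed_position_params_give_content_only_logits():
    cfg = small_cfg()
    rng = np.random.default_rng(0)
    mha = MultiHeadAttention(rng, cfg)
    mha.Wr.data[:] = 0.0
    mha.u.data[:] = 0.0
    mha.v.data[:] = 0.0
    x = np.random.default_rng(1).normal(size=(1, 5, cfg.d_model))
    mask = np.ones((1, 5), dtype=bool)
    _, w = mha(Tensor(x), mask, return_weights=True)
    cfg2 = small_cfg(relative_position=False)
    mha2 = MultiHeadAttention(np.random.default_rng(0), cfg2)
    for a, b in ((mha2.Wq, mha.Wq), (mha2.Wk, mha.Wk), (mha2.Wv, mha.Wv),
                 (mha2.Wo, mha.Wo)):
        a.data = b.data.copy()
    _, w2 = mha2(Tensor(x), mask, return_weights=True)
    assert np.abs(w.data - w2.data).max() < 1e-12


def test_window_shift_leaves_position_terms_unchanged():
    # relative terms depend on j - i only, so the bias matrix is independent
    # of any absolute shift of the window
    cfg = small_cfg()
    mha = MultiHeadAttention(np.random.default_rng(0), cfg)
    b1 = mha.position_bias_matrix(5)
    b2 = mha.position_bias_matrix(5)
    assert np.array_equal(b1, b2)


# ------------------------------------------------------------ full network
def test_forward_determinism_and_range(rng):
    cfg = small_cfg(n_layers=2)
    m = SpatialModel(cfg, seed=0).eval()
    L = cfg.context_len
    seq = rng.normal(size=(3, L, cfg.seq_dim))
    epi = rng.normal(size=(3, L, cfg.epi_dim))
    km = np.ones((3, L), dtype=bool)
    p1 = m.predict(seq, epi, km)
    p2 = m.predict(seq, epi, km)
    assert np.array_equal(p1, p2)
    assert (np.abs(p1) < 1.0).all()


def test_attention_rows_sum_to_one_all_layers(rng):
    cfg = small_cfg(n_layers=2)
    m = SpatialModel(cfg, seed=0).eval()
    L = cfg.context_len
    km = np.ones((2, L), dtype=bool)
    km[:, :2] = False
    _, _, attn = m.forward_tensors(
        Tensor(rng.normal(size=(2, L, cfg.seq_dim))),
        Tensor(rng.normal(size=(2, L, cfg.epi_dim))), km, return_attention=True)
    assert len(attn) == 2
    for w in attn:
        assert np.abs(w.sum(axis=-1) - 1.0).max() < 1e-6
        assert w.min() >= 0
        assert np.abs(w[..., :2]).max() == 0.0  # padded keys get no weight


def test_encoder_subnetworks_are_independent(rng):
    cfg = small_cfg()
    m = SpatialModel(cfg, seed=0).eval()
    L = cfg.context_len
    seq = rng.normal(size=(1, L, cfg.seq_dim))
    epi1 = rng.normal(size=(1, L, cfg.epi_dim))
    epi2 = rng.normal(size=(1, L, cfg.epi_dim))
    e1 = m.encode(Tensor(seq), Tensor(epi1)).data
    e2 = m.encode(Tensor(seq), Tensor(epi2)).data
    half = cfg.encoder_out
    assert np.array_equal(e1[..., :half], e2[..., :half])  # sequence block first
    assert not np.array_equal(e1[..., half:], e2[..., half:])


def test_encoder_zero_input_zero_bias(rng):
    cfg = small_cfg()
    m = SpatialModel(cfg, seed=0)
    for layer in m.seq_enc + m.epi_enc:
        layer.b.data[:] = 0.0
    L = cfg.context_len
    out = m.encode(Tensor(np.zeros((1, L, cfg.seq_dim))),
                   Tensor(np.zeros((1, L, cfg.epi_dim))))
    assert np.all(out.data == 0.0)


def test_encoder_concat_order_probe(rng):
    cfg = small_cfg()
    m = SpatialModel(cfg, seed=0)
    for layer in m.seq_enc:  # zero the sequence subnetwork
        layer.W.data[:] = 0.0
        layer.b.data[:] = 0.0
    L = cfg.context_len
    out = m.encode(Tensor(rng.normal(size=(1, L, cfg.seq_dim))),
                   Tensor(rng.normal(size=(1, L, cfg.epi_dim)))).data
    half = cfg.encoder_out
    assert np.all(out[..., :half] == 0.0)
    assert np.any(out[..., half:] != 0.0)


def test_predict_head_zero_weights(rng):
    cfg = small_cfg()
    m = SpatialModel(cfg, seed=0).eval()
    m.head.W.data[:] = 0.0
    m.head.b.data[:] = 0.0
    L = cfg.context_len
    p = m.predict(rng.normal(size=(1, L, cfg.seq_dim)),
                  rng.normal(size=(1, L, cfg.epi_dim)), np.ones((1, L), bool))
    assert np.allclose(p, 0.0)


def test_predict_head_monotone_in_preactivation():
    z = np.linspace(-3, 3, 50)
    assert (np.diff(np.tanh(z)) > 0).all()


def test_zero_layers_path(rng):
    cfg = small_cfg(n_layers=0)
    m = SpatialModel(cfg, seed=0).eval()
    L = cfg.context_len
    seq = rng.normal(size=(1, L, cfg.seq_dim))
    epi = rng.normal(size=(1, L, cfg.epi_dim))
    km = np.ones((1, L), dtype=bool)
    preds, _, _ = m.forward_tensors(Tensor(seq), Tensor(epi), km)
    emb = m.encode(Tensor(seq), Tensor(epi))
    direct = m.head(emb).tanh().data[0, cfg.window, 0]
    assert np.allclose(preds.data[0], direct)


def test_all_padded_raises(rng):
    cfg = small_cfg()
    m = SpatialModel(cfg, seed=0)
    L = cfg.context_len
    with pytest.raises(ValueError, match="padded"):
        m.forward_tensors(Tensor(np.zeros((1, L, cfg.seq_dim))),
                          Tensor(np.zeros((1, L, cfg.epi_dim))),
                          np.zeros((1, L), dtype=bool))


def test_transformer_layer_zero_weights_is_double_layernorm(rng):
    from tsapred.autodiff import layer_norm
    cfg = small_cfg()
    m = SpatialModel(cfg, seed=0)
    tl = m.layers[0]
    for W in (tl.mha.Wv, tl.mha.Wo, tl.ff1.W, tl.ff1.b, tl.ff2.W, tl.ff2.b):
        W.data[:] = 0.0
    x = Tensor(rng.normal(size=(1, cfg.context_len, cfg.d_model)))
    out = tl(x, np.ones((1, cfg.context_len), bool), lambda t: t)
    ln1 = layer_norm(x, tl.g1, tl.b1)
    ln2 = layer_norm(ln1, tl.g2, tl.b2)
    assert np.abs(out.data - ln2.data).max() < 1e-12


# --------------------------------------------------------- domain head/GRL
def test_domain_logits_softmax_sums_to_one(rng):
    cfg = small_cfg(domain_head=True, n_domains=3)
    m = SpatialModel(cfg, seed=0).eval()
    L = cfg.context_len
    _, dom, _ = m.forward_tensors(Tensor(rng.normal(size=(2, L, cfg.seq_dim))),
                                  Tensor(rng.normal(size=(2, L, cfg.epi_dim))),
                                  np.ones((2, L), bool))
    p = np.exp(log_softmax(dom).data)
    assert np.allclose(p.sum(axis=1), 1.0)


def test_domain_head_requires_two_domains():
    with pytest.raises(ValueError):
        small_cfg(domain_head=True, n_domains=1).validate()


def test_grl_zero_lambda_blocks_transformer_gradients(rng):
    cfg = small_cfg(domain_head=True, n_domains=2)
    m = SpatialModel(cfg, seed=0).train()
    L = cfg.context_len
    seq = rng.normal(size=(4, L, cfg.seq_dim))
    epi = rng.normal(size=(4, L, cfg.epi_dim))
    km = np.ones((4, L), dtype=bool)
    m.zero_grad()
    _, dom, _ = m.forward_tensors(Tensor(seq), Tensor(epi), km, grl_lambda=0.0)
    loss = -log_softmax(dom)[np.arange(4), np.array([0, 1, 0, 1])].mean()
    loss.backward()
    for p in m.transformer_params():
        assert p.grad is None or np.all(p.grad == 0.0)
    # but the classifier itself does receive gradient
    assert any(p.grad is not None and np.any(p.grad != 0)
               for layer in m.domain_clf for p in layer.params())


def test_grl_nonzero_lambda_scales_gradients(rng):
    cfg = small_cfg(domain_head=True, n_domains=2)
    labels = np.array([0, 1])
    grads = {}
    for lam in (1.0, 2.0):
        m = SpatialModel(cfg, seed=0).train()
        L = cfg.context_len
        r2 = np.random.default_rng(5)
        seq = r2.normal(size=(2, L, cfg.seq_dim))
        epi = r2.normal(size=(2, L, cfg.epi_dim))
        m.zero_grad()
        _, dom, _ = m.forward_tensors(Tensor(seq), Tensor(epi),
                                      np.ones((2, L), bool), grl_lambda=lam)
        (-log_softmax(dom)[np.arange(2), labels].mean()).backward()
        grads[lam] = [None if p.grad is None else p.grad.copy()
                      for p in m.transformer_params()]
    for g1, g2 in zip(grads[1.0], grads[2.0]):
        if g1 is not None:
            assert np.allclose(2.0 * g1, g2, atol=1e-10)


# ------------------------------------------------------------- persistence
def test_checkpoint_roundtrip(tmp_path, rng):
    cfg = small_cfg(n_layers=2, domain_head=True, n_domains=2)
    m = SpatialModel(cfg, seed=3).eval()
    path = tmp_path / "model.npz"
    m.save(path)
    m2 = SpatialModel.load(path)
    L = cfg.context_len
    seq = rng.normal(size=(2, L, cfg.seq_dim))
    epi = rng.normal(size=(2, L, cfg.epi_dim))
    km = np.ones((2, L), dtype=bool)
    assert np.array_equal(m.predict(seq, epi, km), m2.predict(seq, epi, km))


def test_checkpoint_refuses_dim_mismatch(tmp_path):
    m = SpatialModel(small_cfg(), seed=0)
    path = tmp_path / "model.npz"
    m.save(path)
    with pytest.raises(ValueError, match="dimension mismatch"):
        SpatialModel.load(path, expect_seq_dim=7)


@pytest.mark.parametrize("kw", [
    {},
    {"n_layers": 3},
    {"relative_position": False},
    {"domain_head": True, "n_domains": 3},
    {"domain_head": True, "n_domains": 2, "domain_hidden": 0},
])
def test_parameter_count_matches_closed_form(kw):
    cfg = small_cfg(**kw)
    assert SpatialModel(cfg, seed=0).n_parameters() == parameter_count(cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(encoder_out=5, n_heads=4).validate()  # d_model=10, h=4
    with pytest.raises(ValueError):
        ModelConfig(prediction_mode="bogus").validate()
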