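"""GCT and CBAM: closed-form cases, loop-based oracles, invariants."""

import numpy as np
import pytest

from gcdetect import attention as at
from gcdetect import nn


# -- independent loop-based oracles -----------------------------------------

def oracle_gct_embed(x, alpha, eps):
    return np.array([alpha[c] * np.sqrt((x[c] ** 2).sum() + eps)
                     for c in range(x.shape[0])])


def oracle_gct_normalize(s, eps):
    c = len(s)
    denom = np.sqrt(sum(v * v for v in s) + eps)
    return np.array([np.sqrt(c) * v / denom for v in s])


def oracle_gct_gate(x, s_hat, gamma, beta):
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        out[c] = x[c] * (1.0 + np.tanh(gamma[c] * s_hat[c] + beta[c]))
    return out


def oracle_cam(x, p):
    c = x.shape[0]
    def mlp(v):
        h = np.maximum(v @ np.asarray(p.w1) + np.asarray(p.b1), 0.0)
        return h @ np.asarray(p.w2) + np.asarray(p.b2)
    mx = np.array([x[i].max() for i in range(c)])
    av = np.array([x[i].mean() for i in range(c)])
    gate = 1.0 / (1.0 + np.exp(-(mlp(mx) + mlp(av))))
    return gate, x * gate[:, None, None]


def oracle_sam(x, p):
    c, h, w = x.shape
    mx = x.max(axis=0)
    av = x.mean(axis=0)
    k = p.kernel_size
    pad = k // 2
    stacked = np.stack([np.pad(mx, pad), np.pad(av, pad)])
    weight = np.asarray(p.weight)[0]
    logits = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            logits[i, j] = (stacked[:, i:i + k, j:j + k] * weight).sum() \
                + float(np.asarray(p.bias)[0])
    gate = 1.0 / (1.0 + np.exp(-logits))
    return gate, x * gate[None]


def random_gct(rng, c):
    return at.GCTParams(alpha=rng.normal(1, 0.3, c), gamma=rng.normal(0, 0.5, c),
                        beta=rng.normal(0, 0.5, c), epsilon=1e-5)


def random_cam(rng, c, r):
    hidden = c // r
    return at.CAMParams(r, rng.normal(0, 0.5, (c, hidden)), rng.normal(0, 0.5, hidden),
                        rng.normal(0, 0.5, (hidden, c)), rng.normal(0, 0.5, c))


def random_sam(rng, k=5):
    return at.SAMParams(k, rng.normal(0, 0.5, (1, 2, k, k)), rng.normal(0, 0.5, 1))


# -- closed-form examples -----------------------------------------------------

def test_gct_embed_closed_forms():
    p = at.GCTParams(np.ones(1), np.zeros(1), np.zeros(1), epsilon=0.0)
    s = at.gct_embed(np.ones((1, 2, 2)), p)
    assert s.data == pytest.approx([2.0])  # L2 norm of four ones
    alpha = np.array([0.5, 2.0])
    p2 = at.GCTParams(alpha, np.zeros(2), np.zeros(2), epsilon=1e-4)
    s2 = at.gct_embed(np.zeros((2, 3, 3)), p2)
    assert np.allclose(s2.data, alpha * np.sqrt(1e-4))


def test_gct_normalize_closed_forms():
    assert np.allclose(at.gct_normalize(np.full(7, 3.2), 0.0).data, np.ones(7))
    assert np.allclose(at.gct_normalize(np.array([5.0, 0, 0, 0]), 0.0).data,
                       [2.0, 0, 0, 0])
    with pytest.raises(ValueError):
        at.gct_normalize(np.zeros(0))


def test_gct_gate_identity_and_suppression(rng):
    x = rng.normal(size=(3, 4, 4))
    p = at.GCTParams.identity(3)
    out = at.gct_gate(x, np.ones(3), p)
    assert np.array_equal(out.data, x)  # tanh(0) = 0 exactly
    # gamma*s + beta -> -inf drives the channel to zero
    p2 = at.GCTParams(np.ones(3), np.zeros(3), np.full(3, -40.0))
    assert np.abs(at.gct_gate(x, np.ones(3), p2).data).max() < 1e-12


def test_gct_channel_mismatch_raises(rng):
    with pytest.raises(ValueError, match="channel"):
        at.gct_embed(rng.normal(size=(4, 2, 2)), at.GCTParams.identity(3))


@pytest.mark.parametrize("seed", range(6))
def test_gct_stages_match_loop_oracles(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(8, 5, 5))
    p = random_gct(rng, 8)
    s = at.gct_embed(x, p)
    assert np.abs(s.data - oracle_gct_embed(x, p.alpha, p.epsilon)).max() < 1e-6
    s_hat = at.gct_normalize(s.data, p.epsilon)
    assert np.abs(s_hat.data - oracle_gct_normalize(s.data, p.epsilon)).max() < 1e-6
    out = at.gct_gate(x, s_hat.data, p)
    assert np.abs(out.data - oracle_gct_gate(x, s_hat.data, p.gamma, p.beta)).max() < 1e-6
    full = at.gct_forward(x, p)
    chained = oracle_gct_gate(x, oracle_gct_normalize(
        oracle_gct_embed(x, p.alpha, p.epsilon), p.epsilon), p.gamma, p.beta)
    assert np.abs(full.data - chained).max() < 1e-6


def test_gct_forward_identity_and_boundedness(rng):
    x = rng.normal(size=(2, 6, 3, 3))
    assert np.array_equal(at.gct_forward(x, at.GCTParams.identity(6)).data, x)
    p = random_gct(rng, 6)
    out = at.gct_forward(x, p).data
    assert (np.abs(out) <= 2.0 * np.abs(x) + 1e-12).all()  # 1 + tanh in (0, 2)


def test_gct_channel_permutation_equivariance(rng):
    x = rng.normal(size=(6, 4, 4))
    p = random_gct(rng, 6)
    perm = rng.permutation(6)
    pp = at.GCTParams(np.asarray(p.alpha)[perm], np.asarray(p.gamma)[perm],
                      np.asarray(p.beta)[perm], p.epsilon)
    assert np.allclose(at.gct_forward(x[perm], pp).data,
                       at.gct_forward(x, p).data[perm])


def test_cam_closed_forms(rng):
    x = rng.normal(size=(8, 4, 4))
    gate, out = at.cam_forward(x, at.CAMParams.zeros(8, 2))
    assert np.allclose(gate.data, 0.5) and np.allclose(out.data, 0.5 * x)
    # spatially constant input: max pool equals avg pool, gate = sigmoid(2 MLP(v))
    v = rng.normal(size=8)
    xc = np.broadcast_to(v[:, None, None], (8, 3, 3)).copy()
    p = random_cam(rng, 8, 2)
    gate2, _ = at.cam_forward(xc, p)
    def mlp(u):
        return np.maximum(u @ p.w1 + p.b1, 0) @ p.w2 + p.b2
    assert np.allclose(gate2.data, 1 / (1 + np.exp(-2 * mlp(v))), atol=1e-10)
    with pytest.raises(ValueError):
        at.CAMParams.zeros(8, 3)


def test_sam_closed_forms(rng):
    x = rng.normal(size=(4, 6, 6))
    gate, out = at.sam_forward(x, at.SAMParams.zeros(7))
    assert np.allclose(gate.data, 0.5) and np.allclose(out.data, 0.5 * x)
    # spatially constant input -> spatially constant gate
    xc = np.broadcast_to(rng.normal(size=4)[:, None, None], (4, 6, 6)).copy()
    g2, _ = at.sam_forward(xc, random_sam(rng))
    inner = g2.data[2:-2, 2:-2]  # away from padding effects
    assert np.ptp(inner) < 1e-12
    with pytest.raises(ValueError):
        at.SAMParams.zeros(4)


@pytest.mark.parametrize("seed", range(4))
def test_cam_sam_cbam_match_loop_oracles(seed):
    rng = np.random.default_rng(100 + seed)
    x = rng.normal(size=(8, 6, 6))
    cam = random_cam(rng, 8, 2)
    sam = random_sam(rng)
    g_ref, out_ref = oracle_cam(x, cam)
    g, out = at.cam_forward(x, cam)
    assert np.abs(g.data - g_ref).max() < 1e-6
    assert np.abs(out.data - out_ref).max() < 1e-6
    gs_ref, outs_ref = oracle_sam(x, sam)
    gs, outs = at.sam_forward(x, sam)
    assert np.abs(gs.data - gs_ref).max() < 1e-6
    assert np.abs(outs.data - outs_ref).max() < 1e-6
    chained = oracle_sam(out_ref, sam)[1]
    assert np.abs(at.cbam_forward(x, cam, sam).data - chained).max() < 1e-6


def test_cbam_gates_open_and_preserve_sign(rng):
    x = rng.normal(size=(8, 5, 5))
    cam, sam = random_cam(rng, 8, 4), random_sam(rng)
    g_c, _ = at.cam_forward(x, cam)
    g_s, _ = at.sam_forward(x, sam)
    assert (0 < g_c.data).all() and (g_c.data < 1).all()
    assert (0 < g_s.data).all() and (g_s.data < 1).all()
    out = at.cbam_forward(x, cam, sam).data
    assert (np.sign(out) == np.sign(x))[x != 0].all()
    assert np.abs(at.cbam_forward(np.zeros((8, 5, 5)), cam, sam).data).max() == 0


def test_cam_channel_permutation_equivariance(rng):
    x = rng.normal(size=(8, 4, 4))
    p = random_cam(rng, 8, 2)
    perm = rng.permutation(8)
    pp = at.CAMParams(p.reduction_ratio, np.asarray(p.w1)[perm], p.b1,
                      np.asarray(p.w2)[:, perm], np.asarray(p.b2)[perm])
    _, out = at.cam_forward(x, p)
    _, out_p = at.cam_forward(x[perm], pp)
    assert np.allclose(out_p.data, out.data[perm])


@pytest.mark.parametrize("kind", ["gct", "cam", "sam"])
def test_attention_ops_are_differentiable(kind, rng):
    if kind == "gct":
        p = random_gct(rng, 4)
        fn = lambda x: at.gct_forward(x, p)
    elif kind == "cam":
        p = random_cam(rng, 4, 2)
        fn = lambda x: at.cam_forward(x, p)[1]
    else:
        p = random_sam(rng, 3)
        fn = lambda x: at.sam_forward(x, p)[1]
    x = nn.Tensor(rng.normal(size=(4, 4, 4)), requires_grad=True)
    assert nn.gradcheck(fn, [x]) < 1e-3


def test_gct_module_initializes_to_identity(rng):
    m = at.GCT(5)
    nn.initialize(m, 0)
    x = nn.Tensor(rng.normal(size=(2, 5, 3, 3)))
    assert np.array_equal(m(x).data, x.data)
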