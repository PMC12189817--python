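"""Core network operations: hand-computed oracles, gate properties,
causality and the ablation variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pathcare as pc
from pathcare.autograd import Tensor
from pathcare.data import Batch
from pathcare.model import (compute_gate_logits, encode_future, encode_task,
                            predict_next_visit, project)


def _params(nr=3, nh=4, ng=4, variant="full", seed=0):
    return pc.ModelParams(pc.ModelConfig(n_features=nr, hidden_dim=nh,
                                         gate_dim=ng, variant=variant,
                                         init_seed=seed))


def _batch(values: np.ndarray, lengths=None, labels=None) -> Batch:
    B, T, _ = values.shape
    lengths = np.asarray(lengths if lengths is not None else [T] * B)
    return Batch([f"p{i}" for i in range(B)], np.asarray(values, float),
                 lengths, labels or {})


# ---------------------------------------------------------------------------
# covariance / decorrelation oracles
# ---------------------------------------------------------------------------

def _cov_oracle(G: np.ndarray) -> np.ndarray:
    """Explicit double loop over activation pairs."""
    B, n = G.shape
    mu = [sum(G[b, i] for b in range(B)) / B for i in range(n)]
    C = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = sum((G[b, i] - mu[i]) * (G[b, j] - mu[j])
                          for b in range(B)) / B
    return C


def _decorr_oracle(G: np.ndarray) -> float:
    C = _cov_oracle(G)
    return 0.5 * sum(C[i, j] ** 2 for i in range(C.shape[0])
                     for j in range(C.shape[1]) if i != j)


def test_covariance_hand_case():
    G = np.array([[1.0, 1.0], [-1.0, -1.0]])
    assert np.allclose(pc.covariance_matrix(G), [[1.0, 1.0], [1.0, 1.0]])
    assert pc.decorrelation_loss(G) == pytest.approx(1.0)


def test_covariance_identical_rows_is_zero():
    G = np.tile([[2.0, -3.0, 0.5]], (5, 1))
    assert np.allclose(pc.covariance_matrix(G), 0.0)
    assert pc.decorrelation_loss(G) == pytest.approx(0.0)


def test_covariance_matches_pairwise_oracle_and_is_psd():
    rng = np.random.default_rng(0)
    for _ in range(20):
        G = rng.normal(size=(rng.integers(2, 17), rng.integers(1, 9)))
        C = pc.covariance_matrix(G)
        assert np.allclose(C, _cov_oracle(G), atol=1e-10)
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-10


def test_decorrelation_matches_double_loop_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        G = rng.normal(size=(rng.integers(2, 17), rng.integers(1, 9)))
        assert abs(pc.decorrelation_loss(G) - _decorr_oracle(G)) < 1e-10


def test_decorrelation_zero_for_orthogonal_centered_columns():
    G = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
    assert pc.decorrelation_loss(G) == pytest.approx(0.0, abs=1e-12)


def test_covariance_rejects_single_case():
    with pytest.raises(ValueError):
        pc.covariance_matrix(np.ones((1, 3)))


# ---------------------------------------------------------------------------
# cumax and gates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("v,expected", [
    ((0.0, 0.0), (0.5, 1.0)),
    ((0.0, 0.0, 0.0, 0.0), (0.25, 0.5, 0.75, 1.0)),
])
def test_cumax_uniform_logits(v, expected):
    assert np.allclose(pc.cumax(np.array(v)), expected)


def test_cumax_front_loads_mass():
    out = pc.cumax(np.array([10.0, -10.0]))
    assert out[0] > 1 - 1e-8
    assert out[1] == pytest.approx(1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=1, max_size=32))
def test_gate_properties_hold_for_any_logits(logits):
    gf, gt = pc.gate_masks(np.array(logits))
    assert np.all(gf >= 0) and np.all(gf <= 1 + 1e-12)
    assert np.all(np.diff(gf) >= -1e-12)          # non-decreasing
    assert gf[-1] == pytest.approx(1.0, abs=1e-6)  # terminal element
    assert np.allclose(gf + gt, 1.0)               # complementarity
    assert np.all(np.diff(gt) <= 1e-12)            # complement monotone
    assert gt[-1] == pytest.approx(0.0, abs=1e-6)


def test_gate_logits_zero_record_gives_uniform_gate():
    params = _params(nr=3, ng=4)
    logits = compute_gate_logits(params, np.zeros((1, 3)))
    gf, _ = pc.gate_masks(logits)
    assert np.allclose(gf.data, [0.25, 0.5, 0.75, 1.0])


def test_gate_logits_hand_product():
    params = _params(nr=2, ng=2)
    params["W_gate"].data = np.array([[1.0, 2.0], [3.0, 4.0]])
    out = compute_gate_logits(params, np.array([[1.0, 1.0]]))
    assert np.allclose(out.data, [[3.0, 7.0]])


# ---------------------------------------------------------------------------
# projections, fusion, heads
# ---------------------------------------------------------------------------

def test_project_identity_and_zero():
    params = _params(nr=3, nh=2, ng=2)
    params["W_f"].data = np.eye(2)
    params["W_t"].data = np.array([[1.0, 2.0], [3.0, 4.0]])
    h_f = Tensor(np.array([[0.3, -0.7]]))
    h = Tensor(np.array([[1.0, 1.0]]))
    gf, gt = project(params, h_f, h)
    assert np.allclose(gf.data, h_f.data)          # identity projection
    assert np.allclose(gt.data, [[3.0, 7.0]])      # hand product
    zero = Tensor(np.zeros((1, 2)))
    gf0, _ = project(params, zero, zero)
    assert np.allclose(gf0.data, 0.0)              # linearity, no bias


def test_fuse_limits_and_convexity():
    g_f = Tensor(np.array([[1.0, 2.0, 3.0]]))
    g_t = Tensor(np.array([[-1.0, 0.0, 5.0]]))
    ones, zeros = np.ones((1, 3)), np.zeros((1, 3))
    assert np.allclose(pc.fuse(g_f, g_t, ones, zeros).data, g_f.data)
    assert np.allclose(pc.fuse(g_f, g_t, zeros, ones).data, g_t.data)
    gate = np.array([[0.2, 0.5, 0.9]])
    same = pc.fuse(g_f, g_f, gate, 1 - gate)
    assert np.allclose(same.data, g_f.data)        # convex-combination
    with pytest.raises(ValueError):
        pc.fuse(g_f, Tensor(np.ones((1, 2))), ones, zeros)


def test_predict_next_visit_affine():
    params = _params(nr=1, nh=1)
    params["future_head.W"].data = np.array([[2.0]])
    params["future_head.b"].data = np.array([1.0])
    out = predict_next_visit(params, Tensor(np.array([[3.0]])))
    assert out.data == pytest.approx(7.0)
    # zero weights give a zero vector, output dim is Nr
    p2 = _params(nr=5, nh=3)
    p2["future_head.W"].data[:] = 0
    out2 = predict_next_visit(p2, Tensor(np.ones((2, 3))))
    assert out2.shape == (2, 5)
    assert np.allclose(out2.data, 0.0)


def test_predict_target_logistic():
    params = _params(ng=1, nh=1, nr=1)
    params["target_head.W"].data = np.array([[1.0]])
    params["target_head.b"].data = np.array([0.0])
    s = Tensor(np.array([[0.847]]))
    y = pc.predict_target(params, s)
    assert y.data == pytest.approx(1 / (1 + np.exp(-0.847)))
    params["target_head.W"].data[:] = 0
    assert pc.predict_target(params, s).data == pytest.approx(0.5)
    # monotone in the pre-activation
    params["target_head.W"].data = np.array([[1.0]])
    lo = pc.predict_target(params, Tensor(np.array([[0.0]]))).data
    hi = pc.predict_target(params, Tensor(np.array([[1.0]]))).data
    assert hi > lo


# ---------------------------------------------------------------------------
# encoders: causality and separation
# ---------------------------------------------------------------------------

def test_encoders_are_causal():
    rng = np.random.default_rng(2)
    params = _params(nr=3, nh=4)
    x = rng.normal(size=(2, 5, 3))
    for encode in (encode_future, encode_task):
        h = encode(params, _batch(x))
        x2 = x.copy()
        x2[:, 3, :] += 10.0   # perturb visit 4
        h2 = encode(params, _batch(x2))
        for t in range(3):
            assert np.allclose(h[t].data, h2[t].data)
        assert not np.allclose(h[3].data, h2[3].data)


def test_encoder_parameter_separation():
    rng = np.random.default_rng(3)
    params = _params()
    x = rng.normal(size=(2, 4, 3))
    h_task_before = encode_task(params, _batch(x))[-1].data.copy()
    params["future_encoder.W_ir"].data += 1.0
    assert np.allclose(encode_task(params, _batch(x))[-1].data,
                       h_task_before)


def test_identical_patients_get_identical_embeddings():
    params = _params()
    row = np.random.default_rng(4).normal(size=(1, 4, 3))
    x = np.concatenate([row, row], axis=0)
    h = encode_future(params, _batch(x))
    assert np.allclose(h[-1].data[0], h[-1].data[1])


def test_single_visit_batch():
    params = _params()
    h = encode_future(params, _batch(np.ones((3, 1, 3))))
    assert len(h) == 1 and h[0].shape == (3, 4)


# ---------------------------------------------------------------------------
# forward pass and variants
# ---------------------------------------------------------------------------

def _random_batch(seed=0, B=6, T=5, nr=3):
    rng = np.random.default_rng(seed)
    lengths = rng.integers(1, T + 1, size=B)
    lengths[0] = T
    values = rng.normal(size=(B, T, nr))
    for i, L in enumerate(lengths):
        values[i, L:] = 0.0
    return _batch(values, lengths, {"mortality": rng.integers(0, 2, B)})


def test_forward_diagnostics_invariants():
    params = _params()
    for seed in range(5):
        d = pc.forward(params, _random_batch(seed))
        gf, gt = d.gate_future.data, d.gate_task.data
        assert np.all((gf >= 0) & (gf <= 1 + 1e-12))
        assert np.all(np.diff(gf, axis=1) >= -1e-12)
        assert np.allclose(gf + gt, 1.0)
        assert np.allclose(gf[:, -1], 1.0, atol=1e-6)
        assert np.all((d.y_hat.data > 0) & (d.y_hat.data < 1))
        assert d.r_hat_seq[0].shape == (6, 3)


def test_forward_invariant_to_batch_permutation_and_padding():
    params = _params()
    batch = _random_batch(1)
    d = pc.forward(params, batch)
    perm = np.array([3, 1, 5, 0, 2, 4])
    pbatch = _batch(batch.values[perm], batch.lengths[perm],
                    {"mortality": batch.labels["mortality"][perm]})
    dp = pc.forward(params, pbatch)
    assert np.allclose(dp.y_hat.data, d.y_hat.data[perm], atol=1e-10)
    # changing padding content must not change predictions
    noisy = batch.values.copy()
    for i, L in enumerate(batch.lengths):
        noisy[i, L:] = 99.0
    dn = pc.forward(params, _batch(noisy, batch.lengths, batch.labels))
    assert np.allclose(dn.y_hat.data, d.y_hat.data, atol=1e-12)


def test_context_minus_ignores_future_branch():
    params = _params(variant="context_minus")
    batch = _random_batch(2)
    y1 = pc.forward(params, batch).y_hat.data.copy()
    params["future_encoder.W_in"].data += 5.0
    params["future_head.W"].data += 5.0
    y2 = pc.forward(params, batch).y_hat.data
    assert np.allclose(y1, y2)


def test_gate_minus_concatenates():
    params = _params(variant="gate_minus")
    d = pc.forward(params, _random_batch(3))
    assert d.s.shape == (6, 8)          # 2 * N_g
    assert d.gate_future is None


def test_full_matches_gate_minus_under_saturated_gate():
    """A gate_minus head built from the full head's weights with a hard
    0/1 gate reproduces the full model's prediction when the gate
    saturates."""
    ng = 4
    params = _params(nr=3, nh=4, ng=ng, variant="full")
    batch = _random_batch(4)
    # give every patient the same final record so the gate logits agree,
    # and craft W_gate so the softmax saturates on the last neuron
    v = np.array([1.0, -0.5, 2.0])
    for i, L in enumerate(batch.lengths):
        batch.values[i, L - 1] = v
    params["W_gate"].data[:] = 0.0
    params["W_gate"].data[-1] = 100.0 * v / (v @ v)
    d_full = pc.forward(params, batch)
    gf = d_full.gate_future.data
    hard = np.round(gf)
    assert np.allclose(gf, hard, atol=1e-6)   # saturated indeed
    assert np.allclose(hard, hard[0])         # identical across the batch
    # construct the concatenation head emulating the hard gate
    params_cat = _params(nr=3, nh=4, ng=ng, variant="gate_minus")
    for name in params.names():
        if not name.startswith("target_head"):
            params_cat._params[name].data = params[name].data.copy()
    W = params["target_head.W"].data[:, 0]
    params_cat["target_head.W"].data = np.concatenate(
        [W * hard[0], W * (1 - hard[0])])[:, None]
    params_cat["target_head.b"].data = params["target_head.b"].data.copy()
    d_cat = pc.forward(params_cat, batch)
    assert np.allclose(d_cat.y_hat.data, d_full.y_hat.data, atol=1e-5)


def test_forward_rejects_unknown_variant():
    params = _params()
    with pytest.raises(ValueError):
        pc.forward(params, _random_batch(0), variant="bogus")
    with pytest.raises(ValueError):
        pc.ModelConfig(n_features=3, variant="bogus")


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def test_checkpoint_round_trip_restores_bit_identical_outputs(tmp_path):
    params = _params(seed=9)
    batch = _random_batch(5)
    y = pc.forward(params, batch).y_hat.data.copy()
    path = str(tmp_path / "ckpt.npz")
    params.save(path, rng_state={"note": 7})
    loaded, rng_state = pc.ModelParams.load(path)
    assert rng_state == {"note": 7}
    assert loaded.config == params.config
    y2 = pc.forward(loaded, batch).y_hat.data
    assert np.array_equal(y, y2)
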