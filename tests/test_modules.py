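"""Behavioural and oracle tests for the dual-branch operator."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seafec import nn
from seafec import tensor as T
from seafec.modules import (
    ConfigError,
    ContractError,
    ECAGate,
    MEFE,
    MEFESpec,
    SCARF,
    SCARFSpec,
    SEAFEC,
    SEAFECSpec,
    eca_kernel_size,
    edge_response,
)
from seafec.tensor import Tensor

from oracles import scarf_forward_ref


# ----------------------------------------------------------------------
# ECA
# ----------------------------------------------------------------------

def _eca_bruteforce(C, gamma, b):
    """Nearest candidate odd width to |log2(C)/gamma + b/gamma| by enumeration."""
    t = abs(math.log2(C) / gamma + b / gamma)
    t_int = int(t)
    return max(3, t_int if t_int % 2 == 1 else t_int + 1)


def test_eca_kernel_size_rule():
    assert eca_kernel_size(64, 2, 1) == 3
    assert eca_kernel_size(256, 2, 1) == 5
    for C in range(8, 1025):
        assert eca_kernel_size(C, 2, 1) == _eca_bruteforce(C, 2, 1)


def test_eca_zero_weights_gate_half(rng):
    gate = ECAGate(8, rng=np.random.default_rng(0))
    gate.weight.data[:] = 0.0
    x = Tensor(rng.standard_normal((2, 8, 4, 4)).astype(np.float32))
    y = gate(x)
    np.testing.assert_allclose(y.data, 0.5 * x.data, rtol=1e-6)


def test_eca_constant_channels_stay_constant(rng):
    gate = ECAGate(4, rng=np.random.default_rng(0))
    vals = np.arange(4, dtype=np.float32).reshape(1, 4, 1, 1)
    x = Tensor(np.broadcast_to(vals, (1, 4, 5, 5)).copy())
    y = gate(x)
    assert np.ptp(y.data, axis=(2, 3)).max() < 1e-6


def test_eca_rejects_wrong_rank():
    gate = ECAGate(4)
    with pytest.raises(ContractError):
        gate(Tensor(np.zeros((4, 4, 4), np.float32)))


# ----------------------------------------------------------------------
# SCARF attention
# ----------------------------------------------------------------------

def test_attention_uniform_when_expansion_is_zero(feature_map):
    scarf = SCARF(SCARFSpec(4, 4), rng=np.random.default_rng(0))
    scarf.attn_conv.weight.data[:] = 0.0
    A = scarf.attention(feature_map)
    np.testing.assert_allclose(A.data, 1.0 / 9.0, rtol=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), stride=st.sampled_from([1, 2]))
def test_attention_normalises_over_receptive_axis(seed, stride):
    rng = np.random.default_rng(seed)
    scarf = SCARF(SCARFSpec(4, 4, stride=stride), rng=np.random.default_rng(seed))
    x = Tensor(rng.standard_normal((2, 4, 6, 6)).astype(np.float32) * 3)
    A = scarf.attention(x)
    assert A.data.min() >= 0
    np.testing.assert_allclose(A.data.sum(axis=2), 1.0, atol=1e-5)


def test_attention_single_position_scalar_oracle():
    """H = W = B = C = 1: the pooled context is the pixel itself, the nine
    logits are w_t * x + b_t, and the attention is their softmax."""
    scarf = SCARF(SCARFSpec(1, 1), rng=np.random.default_rng(3))
    w = np.linspace(-1, 1, 9, dtype=np.float32)
    b = np.linspace(0.5, -0.5, 9, dtype=np.float32)
    scarf.attn_conv.weight.data = w.reshape(9, 1, 1, 1)
    scarf.attn_conv.bias.data = b
    xval = 0.7
    A = scarf.attention(Tensor(np.full((1, 1, 1, 1), xval, np.float32)))
    logits = w * xval + b
    expect = np.exp(logits - logits.max())
    expect /= expect.sum()
    np.testing.assert_allclose(A.data[0, 0, :, 0, 0], expect, rtol=1e-5)


def test_attention_groups_must_divide_channels():
    with pytest.raises(ConfigError):
        SCARFSpec(6, 6, attention_groups=4)


# ----------------------------------------------------------------------
# SCARF forward
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "shape,stride,cout,expect",
    [((2, 8, 12, 12), 1, 8, (2, 8, 12, 12)), ((2, 8, 12, 12), 2, 16, (2, 16, 6, 6))],
)
def test_scarf_shape_contract(rng, shape, stride, cout, expect):
    scarf = SCARF(SCARFSpec(shape[1], cout, stride=stride), rng=np.random.default_rng(0))
    y = scarf(Tensor(rng.standard_normal(shape).astype(np.float32)))
    assert y.shape == expect


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    b=st.integers(1, 2),
    c=st.sampled_from([1, 2, 4]),
    hw=st.integers(3, 6),
    stride=st.sampled_from([1, 2]),
)
def test_scarf_matches_enumerated_weighted_sum_oracle(seed, b, c, hw, stride):
    rng = np.random.default_rng(seed)
    scarf = SCARF(SCARFSpec(c, c + 1, stride=stride), rng=np.random.default_rng(seed)).eval()
    x = rng.standard_normal((b, c, hw, hw)).astype(np.float32)
    with T.no_grad():
        y = scarf(Tensor(x))
    ref = scarf_forward_ref(scarf, x.astype(np.float64))
    np.testing.assert_allclose(y.data, ref, atol=1e-5, rtol=1e-4)


# ----------------------------------------------------------------------
# edge response
# ----------------------------------------------------------------------

def test_edge_response_kills_constants_exactly():
    for val in (0.0, -3.5, 1e4):
        e = edge_response(np.full((1, 2, 5, 7), val, np.float32))
        assert np.abs(e.data).max() == 0.0


def test_edge_response_is_linear(rng):
    f = rng.standard_normal((1, 3, 6, 6)).astype(np.float32)
    e1 = edge_response(f).data
    e2 = edge_response(2.5 * f).data
    np.testing.assert_allclose(e2, 2.5 * e1, rtol=1e-5, atol=1e-6)


def test_edge_response_unit_impulse():
    f = np.zeros((1, 1, 5, 5), np.float32)
    f[0, 0, 2, 2] = 1.0
    e = edge_response(f).data[0, 0]
    assert e[2, 2] == pytest.approx(1 - 1 / 9, rel=1e-6)
    for di, dj in ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)):
        assert e[2 + di, 2 + dj] == pytest.approx(-1 / 9, rel=1e-6)


# ----------------------------------------------------------------------
# MEFE
# ----------------------------------------------------------------------

def test_mefe_shape_contract(rng):
    mefe = MEFE(MEFESpec(8, 8, pool_sizes=(20, 18, 8)), rng=np.random.default_rng(0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y = mefe(Tensor(rng.standard_normal((2, 8, 32, 32)).astype(np.float32)))
    assert y.shape == (2, 8, 32, 32)


def test_mefe_stride_downsamples(rng):
    mefe = MEFE(MEFESpec(4, 6, pool_sizes=(4, 2), stride=2), rng=np.random.default_rng(0))
    y = mefe(Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32)))
    assert y.shape == (1, 6, 4, 4)


def test_mefe_pool_clamp_warns(rng):
    mefe = MEFE(MEFESpec(4, 4, pool_sizes=(20,)), rng=np.random.default_rng(0))
    with pytest.warns(UserWarning, match="clamped"):
        mefe(Tensor(rng.standard_normal((1, 4, 6, 6)).astype(np.float32)))


def test_mefe_constant_input_stays_spatially_constant():
    mefe = MEFE(MEFESpec(4, 4, pool_sizes=(3, 2)), rng=np.random.default_rng(0)).eval()
    vals = np.array([1.0, -2.0, 0.5, 3.0], np.float32).reshape(1, 4, 1, 1)
    x = Tensor(np.broadcast_to(vals, (1, 4, 6, 6)).copy())
    with T.no_grad():
        y = mefe(x)
    assert np.ptp(y.data, axis=(2, 3)).max() < 1e-5


def test_mefe_parameter_count_closed_form():
    """Single branch, C=4, r=2, s=2, C_out=4: reduction (4*2) + depthwise-
    separable (2*9 + 2*2) + two-layer refiner 2*(2*9 + 2*2) + fusion
    (2*4 + 4 bias) = 86 learnable scalars."""
    mefe = MEFE(MEFESpec(4, 4, pool_sizes=(2,), reduction_ratio=2), rng=np.random.default_rng(0))
    total = sum(p.data.size for p in mefe.parameters())
    reduction = 4 * 2
    dsconv = 2 * 9 + 2 * 2
    refiner = 2 * (2 * 9 + 2 * 2)
    fusion = 2 * 4 + 4
    assert total == reduction + dsconv + refiner + fusion == 86


def test_mefe_reduction_must_divide_channels():
    with pytest.raises(ConfigError):
        MEFESpec(6, 6, reduction_ratio=4)


# ----------------------------------------------------------------------
# SEAFEC fusion
# ----------------------------------------------------------------------

def _small_seafec(alpha=0.6, seed=0):
    spec = SEAFECSpec.create(4, 4, pool_sizes=(3, 2), alpha_init=alpha)
    return SEAFEC(spec, rng=np.random.default_rng(seed))


def test_alpha_initialisation_inverse_sigmoid():
    m = _small_seafec(alpha=0.6)
    assert float(m.alpha_logit.data) == pytest.approx(math.log(0.6 / 0.4), rel=1e-5)
    assert m.alpha == pytest.approx(0.6, rel=1e-5)


def test_alpha_saturation_recovers_single_branch(feature_map):
    m = _small_seafec().eval()
    m.alpha_logit.data = np.float32(100.0)
    with T.no_grad():
        y = m(feature_map)
        ys = m.scarf(feature_map)
    np.testing.assert_allclose(y.data, ys.data, atol=1e-6)


def test_fusion_is_affine_in_alpha(feature_map):
    m = _small_seafec().eval()
    outs = {}
    for a in (0.001, 0.999, 0.37):
        m.alpha_logit.data = np.float32(math.log(a / (1 - a)))
        with T.no_grad():
            outs[a] = m(feature_map).data
    lerp = outs[0.001] + (0.37 - 0.001) / (0.999 - 0.001) * (outs[0.999] - outs[0.001])
    np.testing.assert_allclose(outs[0.37], lerp, atol=1e-4)


def test_fusion_lies_between_branches(feature_map):
    m = _small_seafec(alpha=0.4).eval()
    with T.no_grad():
        y = m(feature_map).data
        ys = m.scarf(feature_map).data
        ym = m.mefe(feature_map).data
    lo, hi = np.minimum(ys, ym), np.maximum(ys, ym)
    assert (y >= lo - 1e-5).all() and (y <= hi + 1e-5).all()
    assert 0.0 < m.alpha < 1.0


def test_every_learnable_tensor_receives_gradient(feature_map):
    m = _small_seafec(seed=7)
    y = m(feature_map)
    y.sum().backward()
    for name, p in m.named_parameters():
        assert p.grad is not None, name
        assert np.abs(p.grad).max() > 0, f"zero gradient for {name}"


def test_branch_channel_mismatch_rejected():
    with pytest.raises(ConfigError):
        SEAFECSpec(scarf=SCARFSpec(4, 4), mefe=MEFESpec(4, 8, pool_sizes=(2,)))


def test_alpha_init_bounds():
    with pytest.raises(ConfigError):
        SEAFECSpec.create(4, 4, pool_sizes=(2,), alpha_init=1.0)


# ----------------------------------------------------------------------
# determinism, serialization
# ----------------------------------------------------------------------

def test_seeded_rebuild_is_bit_identical(feature_map):
    m1 = _small_seafec(seed=42)
    m2 = _small_seafec(seed=42)
    for (n1, p1), (n2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
        assert n1 == n2
        np.testing.assert_array_equal(p1.data, p2.data)
    with T.no_grad():
        y1 = m1.eval()(feature_map)
        y2 = m2.eval()(feature_map)
    np.testing.assert_array_equal(y1.data, y2.data)


def test_spec_yaml_round_trip():
    spec = SEAFECSpec.create(16, 32, kernel_size=3, pool_sizes=(18, 14, 8),
                             reduction_ratio=4, alpha_init=0.5, stride=2)
    text = spec.to_yaml()
    for key in ("kernel_size", "pool_sizes", "reduction_ratio", "alpha_init",
                "stride", "in_channels", "out_channels"):
        assert key in text
    back = SEAFECSpec.from_yaml(text)
    assert back == spec


def test_checkpoint_round_trip(tmp_path, feature_map):
    m1 = _small_seafec(seed=1)
    m2 = _small_seafec(seed=2)
    path = str(tmp_path / "op.npz")
    nn.save_checkpoint(m1, path)
    nn.load_checkpoint(m2, path)
    with T.no_grad():
        y1 = m1.eval()(feature_map)
        y2 = m2.eval()(feature_map)
    np.testing.assert_array_equal(y1.data, y2.data)


def test_rank_contract_errors():
    m = _small_seafec()
    with pytest.raises(ContractError):
        m.scarf(Tensor(np.zeros((4, 6, 6), np.float32)))
    with pytest.raises(ContractError):
        m.mefe(Tensor(np.zeros((1, 4, 6), np.float32)))
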