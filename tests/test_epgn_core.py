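"""Unrolled network phases: encoder/decoder structure, receptive fields,
parameter audit, checkpointing, and equivalence with the classical solver."""

import numpy as np
import pytest

from epgn import (
    NetworkConfig,
    SolverState,
    StepSchedule,
    channel_shrink,
    count_parameters,
    decode,
    encode,
    extra_prox_step,
    identity_prox,
    init_parameters,
    load_checkpoint,
    make_gaussian_operator,
    network_forward,
    phase_forward,
    residual_update,
    save_checkpoint,
)
from epgn._autodiff import Tensor
from epgn.epgn_core import Network, zero_phase_params


def _impulse_support(response, tol=1e-12):
    """Bounding-box side lengths of the nonzero region of a 2-D response."""
    nz = np.argwhere(np.abs(response) > tol)
    if len(nz) == 0:
        return 0, 0
    return (nz[:, 0].max() - nz[:, 0].min() + 1,
            nz[:, 1].max() - nz[:, 1].min() + 1)


def _positive_phase(config, seed):
    """Phase whose kernels are strictly positive so ReLU never clips and
    the impulse response attains the full receptive field."""
    rng = np.random.default_rng(seed)
    net = init_parameters(config, seed)
    phase = net.phases[0]
    for name in ("D", "A", "B", "Btil", "Atil", "Dtil"):
        t = getattr(phase, name)
        t.data = np.abs(t.data) + 0.05
    return phase


class TestEncoder:
    def test_zero_kernels_give_zero_features(self):
        cfg = NetworkConfig(K=1, Nf=8)
        phase = zero_phase_params(cfg)
        out = encode(phase, np.random.default_rng(0).random((5, 5)))
        assert np.abs(out.data).max() == 0.0

    def test_receptive_field_is_seven_by_seven(self):
        cfg = NetworkConfig(K=1, Nf=8)
        phase = _positive_phase(cfg, 3)
        impulse = np.zeros((15, 15))
        impulse[7, 7] = 1.0
        out = encode(phase, impulse)
        h, w = _impulse_support(out.data[0].sum(axis=0))
        assert (h, w) == (7, 7)

    def test_feature_map_shape_and_channels(self, rng):
        cfg = NetworkConfig(K=1, Nf=16)
        net = init_parameters(cfg, 0)
        out = encode(net.phases[0], rng.random((9, 11)))
        assert out.data.shape == (1, 16, 9, 11)


class TestChannelShrink:
    def test_zero_threshold_is_identity(self, rng):
        z = rng.standard_normal((1, 4, 5, 5))
        out = channel_shrink(z, np.zeros(4))
        np.testing.assert_allclose(out.data, z, atol=1e-15)

    def test_scalar_example(self):
        z = np.full((1, 1, 1, 1), 3.0)
        out = channel_shrink(z, np.array([1.0]))
        assert out.data[0, 0, 0, 0] == pytest.approx(2.0)

    def test_sparsity_nondecreasing_in_threshold(self, rng):
        z = rng.standard_normal((1, 4, 8, 8))
        zero_fracs = []
        for th in [0.0, 0.2, 0.5, 1.0, 2.0]:
            out = channel_shrink(z, np.full(4, th))
            zero_fracs.append(np.mean(out.data == 0))
        assert np.all(np.diff(zero_fracs) >= 0)


class TestDecoder:
    def test_zero_kernels_give_zero_image(self, rng):
        cfg = NetworkConfig(K=1, Nf=8)
        phase = zero_phase_params(cfg)
        out = decode(phase, rng.standard_normal((1, 8, 6, 6)))
        assert np.abs(out.data).max() == 0.0

    def test_output_is_single_channel_same_shape(self, rng):
        cfg = NetworkConfig(K=1, Nf=8)
        net = init_parameters(cfg, 1)
        out = decode(net.phases[0], rng.standard_normal((2, 8, 7, 9)))
        assert out.data.shape == (2, 1, 7, 9)

    def test_decode_encode_impulse_support_at_most_13(self):
        cfg = NetworkConfig(K=1, Nf=8)
        phase = _positive_phase(cfg, 5)
        impulse = np.zeros((27, 27))
        impulse[13, 13] = 1.0
        out = decode(phase, encode(phase, impulse))
        h, w = _impulse_support(out.data[0, 0])
        assert h <= 13 and w <= 13


class TestResidualUpdate:
    def test_zero_kernels_return_input(self, rng):
        cfg = NetworkConfig(K=1, Nf=8)
        phase = zero_phase_params(cfg)
        b = rng.random((9, 9))
        out = residual_update(phase, b)
        np.testing.assert_allclose(out.data[0, 0], b, atol=1e-15)

    def test_huge_thresholds_return_input(self, rng):
        cfg = NetworkConfig(K=1, Nf=8)
        net = init_parameters(cfg, 2)
        phase = net.phases[0]
        phase.theta.data = np.full(8, 1e6)
        b = rng.random((9, 9))
        out = residual_update(phase, b)
        np.testing.assert_allclose(out.data[0, 0], b, atol=1e-12)

    def test_matches_stepwise_composition(self, rng):
        cfg = NetworkConfig(K=1, Nf=8)
        net = init_parameters(cfg, 4)
        phase = net.phases[0]
        b = rng.random((9, 9))
        out = residual_update(phase, b)
        z = channel_shrink(encode(phase, b), phase.theta)
        expected = b + decode(phase, z).data[0, 0]
        np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-14)


class TestPhaseForward:
    def test_zero_kernel_phase_matches_classical_step(self, rng):
        """Oracle equivalence: with zero kernels the learned residual is the
        identity prox, so a phase must equal the classical iteration."""
        op = make_gaussian_operator(64, 0.5, seed=1, image_shape=(8, 8))
        cfg = NetworkConfig(K=1, Nf=8)
        phase = zero_phase_params(cfg)
        phase.gamma.data = np.array(0.3)
        phase.alpha.data = np.array(0.7)
        phase.beta.data = np.array(0.9)
        x0 = rng.standard_normal((8, 8))
        xh = rng.standard_normal((8, 8))
        y = op.forward(rng.standard_normal((8, 8)))
        st = extra_prox_step(
            SolverState(x_current=x0, x_half_prev=xh), op, y,
            StepSchedule(alpha=0.7, beta=0.9, gamma=0.3), identity_prox)
        x_next, x_half = phase_forward(phase, x0, xh, op, y)
        np.testing.assert_allclose(x_next.data[0, 0], st.x_current, atol=1e-12)
        np.testing.assert_allclose(x_half.data[0, 0], st.x_half_prev, atol=1e-12)

    def test_identity_phase(self, rng):
        """Zero kernels + zero momentum + (near) zero steps leave x unchanged
        when the residual is zero: measured with a consistent y."""
        op = make_gaussian_operator(64, 0.5, seed=1, image_shape=(8, 8))
        cfg = NetworkConfig(K=1, Nf=8)
        phase = zero_phase_params(cfg)
        x0 = rng.standard_normal((8, 8))
        y = op.forward(x0)
        phase.alpha.data = np.array(1.0)
        phase.beta.data = np.array(1.0)
        x_next, _ = phase_forward(phase, x0, x0, op, y)
        np.testing.assert_allclose(x_next.data[0, 0], x0, atol=1e-12)

    def test_stages_share_one_parameter_set(self):
        """Both stages of a phase draw from the same tensors: one phase holds
        exactly the single-stage parameter budget."""
        cfg = NetworkConfig(K=1, Nf=32)
        net = init_parameters(cfg, 0)
        assert net.phases[0].n_parameters() == 37475


class TestNetworkForward:
    def test_single_phase_network_equals_phase_forward(self, rng):
        op = make_gaussian_operator(64, 0.5, seed=1, image_shape=(8, 8))
        cfg = NetworkConfig(K=1, Nf=8)
        net = init_parameters(cfg, 6)
        y = op.forward(rng.random((8, 8)))
        out = network_forward(cfg, net.phases, op, y)
        x0 = op.batch_adjoint(y[None])
        x_next, _ = phase_forward(net.phases[0], x0, x0, op, y)
        np.testing.assert_allclose(out.data, x_next.data, atol=1e-14)

    def test_zero_network_returns_initial_iterate(self, rng):
        op = make_gaussian_operator(64, 0.5, seed=1, image_shape=(8, 8))
        cfg = NetworkConfig(K=3, Nf=8)
        phases = [zero_phase_params(cfg) for _ in range(3)]
        y = op.forward(rng.random((8, 8)))
        x0 = rng.random((8, 8))
        out = network_forward(cfg, phases, op, y, x0=x0)
        np.testing.assert_allclose(out.data[0, 0], x0, atol=1e-15)

    def test_output_shape_matches_input_shape(self, rng):
        for shape, ratio in [((33, 33), 0.25), ((16, 16), 0.4)]:
            n = shape[0] * shape[1]
            op = make_gaussian_operator(n, ratio, seed=2, image_shape=shape)
            cfg = NetworkConfig(K=2, Nf=4)
            net = init_parameters(cfg, 7)
            out = net.forward(op, op.forward(rng.random(shape)))
            assert out.data.shape == (1, 1, *shape)

    def test_phase_count_mismatch_rejected(self):
        cfg = NetworkConfig(K=2, Nf=4)
        with pytest.raises(ValueError):
            Network(cfg, [zero_phase_params(cfg)])


class TestParameterAudit:
    @pytest.mark.parametrize("k,nonlocal_,per_phase,total", [
        (1, False, 37475, 37475),
        (9, False, 37475, 337275),
        (1, True, 41571, 41571),
        (7, True, 41571, 290997),
    ])
    def test_reference_configuration_counts(self, k, nonlocal_, per_phase, total):
        cfg = NetworkConfig(K=k, Nf=32, nonlocal_=nonlocal_)
        assert count_parameters(cfg) == (per_phase, total)

    @pytest.mark.parametrize("k,nf,nonlocal_", [
        (1, 8, False), (3, 8, True), (2, 16, False), (4, 4, True)])
    def test_analytic_count_matches_tensor_enumeration(self, k, nf, nonlocal_):
        cfg = NetworkConfig(K=k, Nf=nf, nonlocal_=nonlocal_)
        net = init_parameters(cfg, 0)
        _, total = count_parameters(cfg)
        assert net.n_parameters() == total

    def test_odd_feature_count_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(K=1, Nf=7)


def test_checkpoint_roundtrip_bit_exact(tmp_path, rng):
    cfg = NetworkConfig(K=2, Nf=8, nonlocal_=True)
    net = init_parameters(cfg, 9)
    p = tmp_path / "ck.npz"
    save_checkpoint(p, net)
    net2 = load_checkpoint(p)
    assert net2.config == cfg
    for ph1, ph2 in zip(net.phases, net2.phases):
        for name, t in ph1.tensors().items():
            np.testing.assert_array_equal(t.data, ph2.tensors()[name].data)
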