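"""Neural-mass forward model: physics, identities and fast-path consistency."""

import numpy as np
import pytest

from dcmpeb import build_network, default_priors
from dcmpeb.features import hermitian_features
from dcmpeb.networks import Node, NetworkSpec
from dcmpeb.nmm import (
    CsdModel,
    ErpConstants,
    ErpParameters,
    StabilityError,
    default_frequencies,
    jacobian,
    predict_csd,
    transfer_matrices,
    transfer_matrix,
)
from dcmpeb.synthetic import random_gain
from dcmpeb.vl import finite_difference_jacobian


def one_source_spec():
    return NetworkSpec(nodes=[Node("S", (0.0, 0.0, 0.0), 1)], edges=[])


@pytest.mark.parametrize("preset", ["dmn", "sal"])
def test_stability_at_prior_mean(preset):
    spec = build_network(preset)
    J = jacobian(ErpParameters.prior_mean(spec), spec)
    assert np.linalg.eigvals(J).real.max() < 0.0


def test_default_priors_shrinkage_block():
    spec = build_network("dmn")
    prior = default_priors(spec)
    assert prior.dim == spec.n_params
    assert np.allclose(prior.mean, np.concatenate([np.zeros(12), prior.mean[12:]]))
    assert np.allclose(prior.mean[: spec.n_edges], 0.0)
    # extrinsic log-gain block of the prior covariance is (1/16) I_12
    block = prior.cov[:12, :12]
    assert np.allclose(block, np.eye(12) / 16.0)


def test_one_source_transfer_matches_resolvent_oracle():
    """|T(f)| equals the modulus of the hand-assembled rational transfer function."""
    spec = one_source_spec()
    c = ErpConstants(delay_intrinsic=0.0, delay_extrinsic=0.0)
    params = ErpParameters.prior_mean(spec, c)
    ke, ki, He, Hi = c.kappa_e, c.kappa_i, c.H_e, c.H_i
    g1, g2, g3, g4 = c.gamma
    s = c.slope
    # states [v_s, v_s', v_pe, v_pe', v_pi, v_pi', v_i, v_i'] written out by hand
    J = np.zeros((8, 8))
    for i, k in ((0, ke), (2, ke), (4, ki), (6, ke)):
        J[i, i + 1] = 1.0
        J[i + 1, i] = -k * k
        J[i + 1, i + 1] = -2.0 * k
    J[1, 2] += ke * He * g1 * s
    J[1, 4] -= ke * He * g1 * s
    J[3, 0] += ke * He * g2 * s
    J[5, 6] += ki * Hi * g4 * s
    J[7, 2] += ke * He * g3 * s
    J[7, 4] -= ke * He * g3 * s
    B = np.zeros(8)
    B[1] = ke * He * c.drive
    C = np.zeros(8)
    C[2], C[4] = 1.0, -1.0
    for f in (2.0, 7.0, 13.0, 30.0):
        expected = C @ np.linalg.solve(2j * np.pi * f * np.eye(8) - J, B)
        got = transfer_matrix(params, spec, f)[0, 0]
        assert abs(abs(got) - abs(expected)) < 1e-10 * abs(expected)


def test_transfer_conjugate_symmetry(chain2):
    params = ErpParameters.prior_mean(chain2)
    for f in (3.0, 11.0):
        assert np.allclose(transfer_matrix(params, chain2, -f), transfer_matrix(params, chain2, f).conj())


def test_decoupled_sources_have_zero_cross_transfer(chain2):
    params = ErpParameters.prior_mean(chain2)
    params.log_gains = np.full(chain2.n_edges, -np.inf)  # baseline couplings forced to 0
    T = transfer_matrices(params, chain2, np.arange(2.0, 40.0, 5.0))
    off = T.copy()
    off[:, range(2), range(2)] = 0.0
    assert np.abs(off).max() == 0.0
    # and the source-level CSD is block-diagonal to machine precision
    pred = predict_csd(params, chain2, np.eye(2), np.arange(2.0, 40.0, 5.0))
    assert np.abs(pred.neuronal[:, 0, 1]).max() < 1e-15


def test_unstable_parameters_raise(chain2):
    params = ErpParameters.prior_mean(chain2)
    params.log_gains = np.full(chain2.n_edges, 4.0)
    with pytest.raises(StabilityError):
        transfer_matrices(params, chain2, np.array([10.0]))


def test_csd_hermitian_psd_over_prior_draws(chain2, gain2, freqs):
    """Stable prior draws always yield Hermitian PSD spectral matrices."""
    prior = default_priors(chain2)
    rng = np.random.default_rng(42)
    sd = np.sqrt(np.diag(prior.cov))
    n_stable = 0
    for _ in range(100):
        theta = prior.mean + rng.standard_normal(prior.dim) * sd
        params = ErpParameters.from_vector(theta, chain2)
        try:
            pred = predict_csd(params, chain2, gain2, freqs)
        except StabilityError:
            continue
        n_stable += 1
        S = pred.total
        assert np.allclose(S, S.conj().transpose(0, 2, 1), atol=1e-12)
        assert np.all(S.diagonal(0, 1, 2).real >= 0.0)
        assert min(np.linalg.eigvalsh(S).min(), 0.0) > -1e-12
        assert np.allclose(pred.neuronal + pred.noise, S)
    assert n_stable >= 80  # the prior mass is overwhelmingly in the stable regime


def test_zero_gain_matrix_leaves_only_noise(chain2, freqs):
    params = ErpParameters.prior_mean(chain2)
    pred = predict_csd(params, chain2, np.zeros((2, 2)), freqs)
    assert np.abs(pred.neuronal).max() == 0.0
    expected = (np.exp(params.b0) + np.exp(params.b1) / freqs)[:, None, None] * np.eye(2)
    assert np.allclose(pred.total, expected)


def test_innovation_amplitude_scales_neuronal_csd(chain2, gain2, freqs):
    params = ErpParameters.prior_mean(chain2)
    base = predict_csd(params, chain2, gain2, freqs)
    params.a0 = params.a0 + np.log(2.0)
    doubled = predict_csd(params, chain2, gain2, freqs)
    assert np.allclose(doubled.neuronal, 2.0 * base.neuronal)
    assert np.allclose(doubled.noise, base.noise)


def test_forward_gain_monotonically_increases_power(chain2, gain2, freqs):
    """More forward coupling pumps more power through the 2-node chain."""
    j = chain2.edge_indices("forward")[0]
    powers = []
    for dg in (-0.3, 0.0, 0.3, 0.6):
        theta = ErpParameters.prior_mean(chain2).to_vector()
        theta[j] += dg
        pred = predict_csd(ErpParameters.from_vector(theta, chain2), chain2, gain2, freqs)
        powers.append(pred.total.diagonal(0, 1, 2).real.sum())
    assert np.all(np.diff(powers) > 0.0)


def test_csdmodel_matches_reference_path():
    spec = build_network("dmn")
    gain = random_gain(4, 4, seed=9)
    freqs = default_frequencies()[::4]
    model = CsdModel(spec, gain, freqs)
    rng = np.random.default_rng(1)
    for _ in range(3):
        theta = ErpParameters.prior_mean(spec).to_vector() + rng.standard_normal(spec.n_params) * 0.1
        ref = hermitian_features(predict_csd(ErpParameters.from_vector(theta, spec), spec, gain, freqs).total)
        assert np.allclose(model.features(theta), ref, atol=1e-10)


def test_csdmodel_jacobian_matches_generic_fd(chain2, gain2, freqs):
    model = CsdModel(chain2, gain2, freqs)
    theta = ErpParameters.prior_mean(chain2).to_vector()
    J_fast = model.jacobian(theta)
    J_ref = finite_difference_jacobian(model.features, theta)
    assert np.allclose(J_fast, J_ref, atol=1e-7)
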