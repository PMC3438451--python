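"""Canonical-microcircuit dynamics: wiring, equilibrium, integration."""

import numpy as np
import pytest

from gaindcm.dynamics import (
    DP,
    SP,
    SS,
    CMCParameters,
    DivergenceError,
    StimulusInput,
    default_time_grid,
    integrate_erp,
    linearize,
    sigmoid,
    simulate_batch,
    state_derivative,
)
from gaindcm.model_space import Area, build_architecture
from gaindcm.network import make_model


@pytest.fixture(scope="module")
def serial_model():
    return make_model(build_architecture(5), "none", 1)


@pytest.fixture(scope="module")
def system(serial_model):
    return serial_model.assemble(0)


@pytest.mark.parametrize("v", [0.1, 1.0, 10.0])
def test_sigmoid_is_odd_bounded_centred(v):
    assert sigmoid(0.0) == 0.0
    assert sigmoid(-v) == pytest.approx(-sigmoid(v))
    assert abs(sigmoid(v)) < 0.5
    assert sigmoid(1e3) == pytest.approx(0.5, abs=1e-12)
    assert sigmoid(-1e3) == pytest.approx(-0.5, abs=1e-12)


def test_sigmoid_slope_at_zero():
    eps = 1e-6
    slope = (sigmoid(eps, 2.0) - sigmoid(-eps, 2.0)) / (2 * eps)
    assert slope == pytest.approx(2.0 / 4.0, rel=1e-6)


def test_resting_state_is_a_fixed_point(system):
    # stimulus far in the past: evaluate at a time with negligible input
    dx = state_derivative(system, np.zeros(system.n_states), t_ms=-1e6)
    assert np.allclose(dx, 0.0, atol=1e-300)


def test_input_routes_only_to_input_area_stellates(serial_model):
    system = serial_model.assemble(0)
    dx = state_derivative(system, np.zeros(system.n_states), t_ms=64.0)
    n = system.coupling.shape[0]
    du = dx[n:]
    nonzero = np.flatnonzero(np.abs(du) > 0)
    iog_ss = [
        i * 4 + SS
        for i, a in enumerate(serial_model.areas)
        if a.name == "IOG"
    ]
    assert set(nonzero) == set(iog_ss)
    assert np.allclose(dx[:n], 0.0)


def test_forward_wiring_routes_sp_perturbation(serial_model):
    """A perturbed IOG sp population drives ss of the forward targets only."""
    system = serial_model.assemble(0)
    n = system.coupling.shape[0]
    x = np.zeros(2 * n)
    areas = serial_model.areas
    i_iog = next(i for i, a in enumerate(areas) if a.label == "L-IOG")
    x[i_iog * 4 + SP] = 0.1  # perturb L-IOG superficial pyramidal voltage
    dx = state_derivative(system, x, t_ms=-1e6)
    du = dx[n:]
    forward_targets = {
        serial_model._index[b] * 4 + SS
        for a, b in serial_model.architecture.forward_edges
        if a.label == "L-IOG"
    }
    # within-area consequences of the perturbation
    intra = {i_iog * 4 + SS, i_iog * 4 + SP, i_iog * 4 + II_IDX}
    nonzero = set(np.flatnonzero(np.abs(du) > 1e-15))
    assert forward_targets <= nonzero
    # no backward influence until dp is perturbed
    backward_targets = {
        serial_model._index[b] * 4 + SP
        for a, b in serial_model.architecture.backward_edges
        if a.label == "L-IOG"
    }
    assert not (backward_targets & nonzero)
    assert nonzero <= forward_targets | intra
    # forward drive is positive (excitatory)
    for t in forward_targets:
        assert du[t] > 0


II_IDX = 2


def test_nonfinite_state_rejected_with_location(system):
    x = np.zeros(system.n_states)
    x[5] = np.nan
    with pytest.raises(ValueError, match="index 5"):
        state_derivative(system, x, 0.0)
    with pytest.raises(ValueError, match="index 5"):
        linearize(system, x)


def test_analytic_jacobian_matches_finite_differences(system):
    rng = np.random.default_rng(0)
    x = rng.normal(0, 0.1, system.n_states)
    J = linearize(system, x)
    eps = 1e-6
    scale = max(1.0, np.abs(J).max())
    for k in rng.choice(system.n_states, size=16, replace=False):
        e = np.zeros_like(x)
        e[k] = eps
        col = (
            state_derivative(system, x + e, -1e6)
            - state_derivative(system, x - e, -1e6)
        ) / (2 * eps)
        assert np.max(np.abs(col - J[:, k])) < 1e-5 * scale


def test_jacobian_block_sparsity_follows_wiring(serial_model):
    """No coupling between areas without an extrinsic edge."""
    system = serial_model.assemble(0)
    J = linearize(system, np.zeros(system.n_states))
    n = system.coupling.shape[0]
    areas = serial_model.areas
    connected = set()
    for a, b in serial_model.architecture.forward_edges:
        connected |= {(a, b), (b, a)}
    for i, ai in enumerate(areas):
        for j, aj in enumerate(areas):
            if i == j or (aj, ai) in connected:
                continue
            block = J[n + i * 4 : n + (i + 1) * 4, j * 4 : (j + 1) * 4]
            assert np.allclose(block, 0.0)


def test_rest_is_stable_at_prior_means(system):
    eig = np.linalg.eigvals(linearize(system, np.zeros(system.n_states)))
    assert np.all(eig.real < 0)


def test_zero_input_integrates_to_zero(serial_model):
    quiet = make_model(
        build_architecture(5), "none", 1,
        stimulus=StimulusInput(amplitude=0.0),
    )
    resp = integrate_erp(quiet, 0)
    assert np.allclose(resp, 0.0, atol=1e-300)


def test_default_response_is_a_decaying_transient(serial_model):
    resp = integrate_erp(serial_model, 0)
    assert np.abs(resp).max() > 1e-3  # non-trivial response
    # returns toward rest by the end of the epoch
    assert np.abs(resp[:, -1]).max() < 0.2 * np.abs(resp).max()


def test_step_halving_converges(serial_model):
    r1 = integrate_erp(serial_model, 0, step_ms=0.5)
    r2 = integrate_erp(serial_model, 0, step_ms=0.25)
    rel = np.linalg.norm(r1 - r2) / np.linalg.norm(r2)
    assert rel < 1e-3


def test_divergent_trajectory_is_rejected():
    # absurdly strong excitatory coupling destabilises the network
    bad = make_model(build_architecture(5), "none", 1, forward_strength=5e4)
    theta = np.zeros(bad.n_params)
    fam = np.array(bad.param_families)
    theta[fam == "extrinsic"] = 3.0
    with pytest.raises(DivergenceError):
        bad.simulate_sources(theta[None])


def test_gain_modulation_raises_peak_response():
    """Lower sp self-inhibition (higher gain) -> larger sp response."""
    model = make_model(build_architecture(5), "sp_self", 2, covariate=(0.0, 1.0))
    theta = np.zeros(model.n_params)
    theta[np.array(model.param_families) == "beta"] = -0.4
    resp = model.simulate_sources(theta[None])[0]  # (8, T, 2)
    low, high = resp[:, :, 0], resp[:, :, 1]
    i_bottom = 0  # L-IOG, a modulated area
    assert np.abs(high[i_bottom]).max() > np.abs(low[i_bottom]).max()


def test_time_grid_matches_200hz_epoch():
    t = default_time_grid()
    assert t.size == 101
    assert t[0] == -100.0 and t[-1] == 400.0
    assert np.allclose(np.diff(t), 5.0)
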