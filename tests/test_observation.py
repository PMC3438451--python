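"""Lead field projection and spatial-mode reduction."""

import numpy as np
import pytest

from gaindcm.observation import (
    compute_modes,
    empirical_covariance,
    make_leadfield,
    predicted_covariance,
    project_to_sensors,
    reduce,
)


@pytest.fixture(scope="module")
def leadfield():
    return make_leadfield(32, 8, rng=np.random.default_rng(42))


def test_leadfield_is_well_conditioned(leadfield):
    assert leadfield.shape == (32, 8)
    assert np.linalg.matrix_rank(leadfield) == 8
    assert np.allclose(np.linalg.norm(leadfield, axis=0), 1.0)
    G = np.abs(leadfield.T @ leadfield) - np.eye(8)
    assert G.max() <= 0.6


def test_projection_is_linear(leadfield):
    rng = np.random.default_rng(0)
    a = rng.standard_normal((8, 50, 3))
    b = rng.standard_normal((8, 50, 3))
    pa = project_to_sensors(a, leadfield)
    pb = project_to_sensors(b, leadfield)
    assert pa.shape == (32, 50, 3)
    assert np.allclose(
        project_to_sensors(2.0 * a + b, leadfield), 2.0 * pa + pb
    )
    assert np.allclose(project_to_sensors(np.zeros((8, 50, 3)), leadfield), 0.0)


def test_identity_leadfield_passes_sources_through():
    src = np.random.default_rng(1).standard_normal((8, 20))
    assert np.allclose(project_to_sensors(src, np.eye(8)), src)


def test_doubling_one_source_adds_its_column_twice(leadfield):
    src = np.random.default_rng(2).standard_normal((8, 30))
    base = project_to_sensors(src, leadfield)
    src2 = src.copy()
    src2[3] *= 2.0
    diff = project_to_sensors(src2, leadfield) - base
    expected = np.outer(leadfield[:, 3], src[3])
    assert np.allclose(diff, expected)


def test_projection_dimension_mismatch_rejected(leadfield):
    with pytest.raises(ValueError, match="sources"):
        project_to_sensors(np.zeros((5, 10)), leadfield)
    with pytest.raises(ValueError, match="sensors"):
        reduce(np.zeros((5, 10)), np.eye(8, 32))


def test_modes_are_orthonormal_descending_and_sign_fixed():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((12, 500))
    scales = np.linspace(5, 1, 12)
    C = np.cov(X * scales[:, None])
    modes = compute_modes(C, 4)
    assert modes.shape == (4, 12)
    assert np.allclose(modes @ modes.T, np.eye(4), atol=1e-12)
    var = np.einsum("mi,ij,mj->m", modes, C, modes)
    assert np.all(np.diff(var) <= 1e-9)  # descending captured variance
    for row in modes:
        assert row[np.argmax(np.abs(row))] > 0


def test_rank1_covariance_gives_the_principal_direction():
    v = np.array([3.0, 0.0, 4.0])
    C = np.outer(v, v)
    modes = compute_modes(C, 1)
    assert np.allclose(np.abs(modes[0]), np.abs(v) / 5.0)


def test_modes_beyond_rank_rejected():
    C = np.outer(np.ones(4), np.ones(4))
    with pytest.raises(ValueError, match="rank"):
        compute_modes(C, 2)
    with pytest.raises(ValueError, match="sensors"):
        compute_modes(np.eye(4), 5)


def test_full_basis_preserves_variance_and_span_reduction_is_exact():
    rng = np.random.default_rng(4)
    C = empirical_covariance(rng.standard_normal((6, 300)))
    modes = compute_modes(C, 6)
    X = rng.standard_normal((6, 100))
    Y = reduce(X, modes)
    assert np.sum(Y**2) == pytest.approx(np.sum(X**2))  # Parseval
    # data lying in the span of a subset reconstruct exactly
    sub = modes[:3]
    Xs = sub.T @ rng.standard_normal((3, 50))
    assert np.allclose(sub.T @ reduce(Xs, sub), Xs)


def test_mode_projection_idempotent_on_own_span():
    rng = np.random.default_rng(5)
    C = empirical_covariance(rng.standard_normal((10, 400)))
    modes = compute_modes(C, 4)
    X = rng.standard_normal((10, 20))
    once = reduce(X, modes)
    again = reduce(modes.T @ once, modes)
    assert np.allclose(once, again)


def test_white_noise_retains_mode_fraction_of_variance():
    """8 of 32 orthonormal modes keep ~ 8/32 of white-noise variance."""
    rng = np.random.default_rng(6)
    C = empirical_covariance(rng.standard_normal((32, 2000)))
    modes = compute_modes(C, 8)
    ratios = []
    noise_rng = np.random.default_rng(7)
    for _ in range(100):
        X = noise_rng.standard_normal((32, 101))
        ratios.append(np.sum(reduce(X, modes) ** 2) / np.sum(X**2))
    assert np.mean(ratios) == pytest.approx(8 / 32, abs=0.02)


def test_predicted_modes_capture_most_signal_variance(small_dataset, small_modes):
    """Default 8 modes capture >= 95% of the noiseless signal variance."""
    sig = small_dataset.signal  # (S, n_sens, T, C)
    total = np.sum(sig**2)
    kept = 0.0
    for s in range(sig.shape[0]):
        kept += np.sum(reduce(sig[s], small_modes) ** 2)
    assert kept / total >= 0.95
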