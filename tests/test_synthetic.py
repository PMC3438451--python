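"""Synthetic study generator: determinism, SNR, averages, ground truth."""

import numpy as np
import pytest

from gaindcm.model_space import build_architecture
from gaindcm.network import make_model
from gaindcm.synthetic import (
    SyntheticStudyConfig,
    bandpass_filter,
    generating_model,
    preprocess,
    sample_subject_parameters,
    simulate_dataset,
    true_beta_table,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticStudyConfig(n_subjects=0)
    with pytest.raises(ValueError):
        SyntheticStudyConfig(snr=-1.0)


def test_subject_parameters_deterministic_and_zero_sd_identical():
    cfg = SyntheticStudyConfig(seed=9)
    a = sample_subject_parameters(cfg, 3)
    b = sample_subject_parameters(cfg, 3)
    assert np.array_equal(a, b)
    flat = SyntheticStudyConfig(seed=9, subject_sd=0.0, beta_subject_sd=0.0)
    t0 = sample_subject_parameters(flat, 0)
    t1 = sample_subject_parameters(flat, 1)
    model = generating_model(flat)
    fam = np.array(model.param_families)
    assert np.array_equal(t0[fam != "beta"], t1[fam != "beta"])
    assert np.array_equal(t0[fam == "beta"], t1[fam == "beta"])


def test_sampled_perturbations_are_centred():
    cfg = SyntheticStudyConfig(seed=10)
    model = generating_model(cfg)
    fam = np.array(model.param_families)
    draws = np.stack(
        [sample_subject_parameters(cfg, s, model=model) for s in range(1000)]
    )
    non_beta = draws[:, fam != "beta"].ravel()
    se = cfg.subject_sd / np.sqrt(non_beta.size)
    assert abs(non_beta.mean()) < 3 * se


def test_beta_profile_follows_levels():
    cfg = SyntheticStudyConfig(seed=4, beta_subject_sd=0.0)
    model = generating_model(cfg)
    theta = sample_subject_parameters(cfg, 0, model=model)
    betas = model.beta_values(theta)
    by_label = dict(zip(model.beta_names(), betas))
    assert by_label["beta:L-IOG"] == pytest.approx(cfg.gain_profile[0])
    assert by_label["beta:R-SOrbG"] == pytest.approx(cfg.gain_profile[3])
    # 4:3:2:1 magnitude profile decreasing with level
    mags = [abs(by_label[f"beta:L-{n}"]) for n in ("IOG", "SOG", "IPC", "SOrbG")]
    assert np.all(np.diff(mags) < 0)


def test_noiseless_single_subject_equals_forward_simulation():
    cfg = SyntheticStudyConfig(
        n_subjects=1, snr=1e12, subject_sd=0.0, beta_subject_sd=0.0, seed=2
    )
    ds = simulate_dataset(cfg)
    model = generating_model(cfg)
    theta = ds.ground_truth[0].theta
    src = model.simulate_sources(theta[None], step_ms=cfg.step_ms)[0]
    from gaindcm.observation import project_to_sensors

    expected = preprocess(project_to_sensors(src, ds.leadfield), ds.time_ms)
    assert np.allclose(ds.epochs[0], expected, atol=1e-5 * np.abs(expected).max())


def test_epoch_geometry_matches_200hz_window(small_dataset):
    assert small_dataset.epochs.shape[2] == 101  # -100..400 ms at 200 Hz
    assert small_dataset.time_ms[0] == -100.0
    assert small_dataset.time_ms[-1] == 400.0
    # baseline window has zero mean per channel after correction
    pre = small_dataset.time_ms <= 0
    base = small_dataset.epochs[:, :, pre, :].mean(axis=2)
    assert np.allclose(base, 0.0, atol=1e-12)


def test_ground_truth_round_trip_bit_exact(small_dataset):
    """The stored ground truth regenerates the noiseless signal exactly."""
    cfg = small_dataset.config
    model = generating_model(cfg)
    gt = small_dataset.ground_truth[1]
    src = model.simulate_sources(gt.theta[None], step_ms=cfg.step_ms)[0]
    from gaindcm.observation import project_to_sensors

    sig = project_to_sensors(src, small_dataset.leadfield)
    assert np.array_equal(sig, small_dataset.signal[1])


def test_average_types_are_consistent(small_dataset):
    grand = small_dataset.grand_average()
    assert np.allclose(
        grand, small_dataset.subject_condition_averages().mean(axis=0)
    )
    assert np.allclose(
        small_dataset.subject_averages(), small_dataset.epochs.mean(axis=-1)
    )


def test_realised_snr_near_target_over_seeds():
    snrs = [
        simulate_dataset(
            SyntheticStudyConfig(n_subjects=2, seed=s)
        ).realised_snr()
        for s in range(10)
    ]
    assert np.mean(snrs) == pytest.approx(8.0, rel=0.10)


def test_condition_difference_attenuates_up_the_hierarchy():
    """High-minus-low contrast response energy decreases with level."""
    cfg = SyntheticStudyConfig(n_subjects=1, subject_sd=0.0,
                               beta_subject_sd=0.0, seed=1)
    model = generating_model(cfg)
    theta = sample_subject_parameters(cfg, 0, model=model)
    src = model.simulate_sources(theta[None])[0]  # (8, T, 3)
    diff = np.sqrt(((src[:, :, 2] - src[:, :, 0]) ** 2).mean(axis=1))
    left = diff[:4]  # hemisphere-major, bottom-up ordering
    right = diff[4:]
    assert np.all(np.diff(left) < 0)
    assert np.all(np.diff(right) < 0)


def test_preprocess_constant_offset_and_idempotence():
    t = np.arange(-100.0, 401.0, 5.0)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((4, t.size, 2)) + 5.0
    y = preprocess(x, t)
    pre = t <= 0
    assert np.allclose(y[:, pre, :].mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(preprocess(y, t), y)
    const = np.full((3, t.size, 1), 7.7)
    assert np.allclose(preprocess(const, t), 0.0)


def test_preprocess_requires_baseline_window():
    t = np.arange(10.0, 200.0, 5.0)
    with pytest.raises(ValueError, match="baseline"):
        preprocess(np.zeros((2, t.size, 1)), t)


def test_bandpass_attenuates_out_of_band_power():
    rng = np.random.default_rng(3)
    fs = 200.0
    x = rng.standard_normal(int(fs) * 60)
    y = bandpass_filter(x, fs_hz=fs)
    f = np.fft.rfftfreq(x.size, 1 / fs)
    px = np.abs(np.fft.rfft(x)) ** 2
    py = np.abs(np.fft.rfft(y)) ** 2
    out_band = f >= 80.0
    atten_db = 10 * np.log10(px[out_band].sum() / py[out_band].sum())
    assert atten_db >= 20.0


def test_true_beta_table_shape_and_null(small_dataset):
    tab = true_beta_table(small_dataset)
    assert tab.shape == (3, 8)
    assert np.all(tab < 0)  # gain increases with contrast
    null_ds = simulate_dataset(
        SyntheticStudyConfig(n_subjects=2, effect_target="none", seed=6)
    )
    assert np.all(true_beta_table(null_ds) == 0)


def test_dataset_determinism():
    a = simulate_dataset(SyntheticStudyConfig(n_subjects=2, seed=21))
    b = simulate_dataset(SyntheticStudyConfig(n_subjects=2, seed=21))
    assert np.array_equal(a.epochs, b.epochs)
    assert np.array_equal(a.leadfield, b.leadfield)
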