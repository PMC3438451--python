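"""Synthetic multi-subject, three-condition ERP study generator.

Emulates the statistical structure the analysis assumes: eight sources
(four bilateral areas) coupled in a serial hierarchy with diagonal
interhemispheric connections, three stimulus-contrast conditions, a
contrast-dependent reduction of superficial-pyramidal self-inhibition
whose magnitude decreases with hierarchical level, a fixed synthetic
lead field, and additive white sensor noise scaled to a target
signal-to-noise ratio.  Epochs span -100..400 ms peristimulus at
200 Hz and are baseline-corrected on the pre-stimulus window.

Each dataset carries its complete ground truth, sufficient to
recompute the noiseless signal bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as ssignal

from .dynamics import DivergenceError, default_time_grid
from .model_space import (
    DEFAULT_CONTRASTS,
    GroundTruth,
    build_architecture,
    default_covariate,
)
from .network import NetworkModel, make_model
from .observation import make_leadfield, project_to_sensors

logger = logging.getLogger(__name__)

#: ground-truth gain profile: beta by hierarchical level 1..4, proportional
#: to 4:3:2:1 (negative beta = self-inhibition falls as contrast rises,
#: i.e. superficial-pyramidal gain rises with contrast)
DEFAULT_GAIN_PROFILE = (-0.5, -0.375, -0.25, -0.125)


@dataclass
class SyntheticStudyConfig:
    """Generating conditions of a synthetic study."""

    n_subjects: int = 18
    contrasts: Tuple[float, ...] = DEFAULT_CONTRASTS
    architecture_id: int = 5
    effect_target: str = "sp_self"
    gain_profile: Tuple[float, ...] = DEFAULT_GAIN_PROFILE
    subject_sd: float = 0.1
    beta_subject_sd: float = 0.2
    snr: float = 8.0
    n_sensors: int = 32
    n_modes: int = 8
    seed: int = 0
    step_ms: float = 0.5
    bandpass_noise: bool = False
    noise_color: str = "white"  # or "pink"

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if len(self.gain_profile) != 4:
            raise ValueError("gain profile has one entry per hierarchical level")

    @property
    def n_conditions(self) -> int:
        return len(self.contrasts)

    def covariate(self) -> Tuple[float, ...]:
        return default_covariate(self.contrasts)


@dataclass
class StudyDataset:
    """A simulated study: per-subject sensor epochs plus ground truth."""

    config: SyntheticStudyConfig
    time_ms: np.ndarray  # (T,)
    leadfield: np.ndarray  # (n_sensors, 8)
    epochs: np.ndarray  # (n_subjects, n_sensors, T, C), baseline-corrected
    signal: np.ndarray  # noiseless sensor signal, same shape
    ground_truth: List[GroundTruth]
    noise_sd: float

    @property
    def n_subjects(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.epochs.shape[-1]

    # the three average types used by the analysis
    def grand_average(self) -> np.ndarray:
        """Average per condition over all subjects: (n_sensors, T, C)."""
        return self.epochs.mean(axis=0)

    def subject_condition_averages(self) -> np.ndarray:
        """Per subject and condition (the epochs themselves)."""
        return self.epochs

    def subject_averages(self) -> np.ndarray:
        """Average over conditions per subject: (n_subjects, n_sensors, T)."""
        return self.epochs.mean(axis=-1)

    def realised_snr(self) -> float:
        noise = self.epochs - _baseline_correct(self.signal, self.time_ms)
        return float(np.mean(self.signal**2) / np.mean(noise**2))


def generating_model(config: SyntheticStudyConfig) -> NetworkModel:
    """The NetworkModel the study is generated from."""
    arch = build_architecture(config.architecture_id)
    return make_model(
        arch,
        effect_target=config.effect_target,
        n_conditions=config.n_conditions,
        covariate=config.covariate() if config.effect_target != "none" else None,
    )


def sample_subject_parameters(
    config: SyntheticStudyConfig,
    subject: int,
    rng: Optional[np.random.Generator] = None,
    model: Optional[NetworkModel] = None,
) -> np.ndarray:
    """Draw one subject's true parameter vector (log-scale factors).

    Non-modulation parameters get independent Gaussian log-perturbations
    with SD ``subject_sd``; per-area modulation parameters are the
    level-wise gain profile scaled by one subject-level factor with SD
    ``beta_subject_sd``.  Deterministic given the config seed and the
    subject index.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1, subject])
    if model is None:
        model = generating_model(config)
    theta = np.zeros(model.n_params)
    families = np.array(model.param_families)
    non_beta = families != "beta"
    theta[non_beta] = rng.normal(0.0, config.subject_sd, size=int(non_beta.sum()))
    if config.effect_target != "none":
        scale = 1.0 + rng.normal(0.0, config.beta_subject_sd)
        profile = np.asarray(config.gain_profile, dtype=float)
        beta_idx = np.flatnonzero(families == "beta")
        for k, name in zip(beta_idx, model.beta_names()):
            area = next(
                a for a in model.effect.affected_areas
                if name == f"beta:{a.label}"
            )
            theta[k] = profile[area.level - 1] * scale
    return theta


def _baseline_correct(epochs: np.ndarray, time_ms: np.ndarray) -> np.ndarray:
    pre = time_ms <= 0.0
    if not np.any(pre):
        raise ValueError("epochs lack a pre-stimulus baseline window")
    baseline = epochs[..., pre, :].mean(axis=-2, keepdims=True)
    return epochs - baseline


def preprocess(
    raw_epochs: np.ndarray,
    time_ms: np.ndarray,
) -> np.ndarray:
    """Baseline-correct epochs: subtract the pre-stimulus mean per channel.

    ``raw_epochs`` has shape (..., n_sensors, T, C); the pre-stimulus
    window is every sample at or before 0 ms.  Idempotent on data whose
    baseline already has zero mean.
    """
    raw_epochs = np.asarray(raw_epochs, dtype=float)
    if raw_epochs.shape[-2] != time_ms.size:
        raise ValueError("time axis length mismatch")
    return _baseline_correct(raw_epochs, np.asarray(time_ms))


def bandpass_filter(
    data: np.ndarray,
    fs_hz: float = 200.0,
    low_hz: float = 0.5,
    high_hz: float = 45.0,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase 0.5-45 Hz band-pass (4th-order Butterworth)."""
    sos = ssignal.butter(
        4, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos"
    )
    return ssignal.sosfiltfilt(sos, data, axis=axis)


def _sensor_noise(
    rng: np.random.Generator,
    shape: Tuple[int, ...],
    sd: float,
    config: SyntheticStudyConfig,
) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if config.noise_color == "pink":
        # 1/f amplitude shaping along the time axis (axis -2)
        T = shape[-2]
        freqs = np.fft.rfftfreq(T, d=1.0 / 200.0)
        weights = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, freqs[1])), 1.0)
        spec = np.fft.rfft(noise, axis=-2) * weights[:, None]
        noise = np.fft.irfft(spec, n=T, axis=-2)
        noise /= noise.std()
    if config.bandpass_noise:
        noise = bandpass_filter(noise, axis=-2)
        noise /= noise.std()
    return sd * noise


def simulate_dataset(config: SyntheticStudyConfig) -> StudyDataset:
    """Simulate a full study: subjects x sensors x time x conditions.

    Per subject and condition the CMC network is integrated, projected
    through the lead field, degraded with sensor noise scaled to the
    target SNR, and baseline-corrected.  Subjects whose sampled
    parameters give divergent dynamics are redrawn (bounded retries).
    """
    model = generating_model(config)
    time_ms = default_time_grid()
    lf_rng = np.random.default_rng([config.seed, 0])
    leadfield = make_leadfield(config.n_sensors, 8, rng=lf_rng)

    thetas = []
    for s in range(config.n_subjects):
        for attempt in range(5):
            rng = np.random.default_rng([config.seed, 1, s, attempt])
            theta = sample_subject_parameters(config, s, rng=rng, model=model)
            try:
                src = model.simulate_sources(
                    theta[None], time_grid_ms=time_ms, step_ms=config.step_ms
                )[0]
                break
            except DivergenceError:
                logger.warning(
                    "subject %d draw %d gave divergent dynamics; resampling",
                    s, attempt,
                )
        else:
            raise DivergenceError(
                f"subject {s}: no stable parameter draw in 5 attempts"
            )
        thetas.append((theta, src))

    signal = np.stack(
        [project_to_sensors(src, leadfield) for _, src in thetas], axis=0
    )  # (S, n_sensors, T, C)

    noise_sd = float(np.sqrt(np.mean(signal**2) / config.snr))
    noise_rng = np.random.default_rng([config.seed, 2])
    noise = _sensor_noise(noise_rng, signal.shape, noise_sd, config)
    epochs = preprocess(signal + noise, time_ms)

    covariate = config.covariate()
    ground_truth = [
        GroundTruth(
            architecture_id=config.architecture_id,
            effect_target=config.effect_target,
            theta=theta,
            param_names=list(model.param_names),
            noise_sd=noise_sd,
            covariate=covariate,
        )
        for theta, _ in thetas
    ]
    return StudyDataset(
        config=config,
        time_ms=time_ms,
        leadfield=leadfield,
        epochs=epochs,
        signal=signal,
        ground_truth=ground_truth,
        noise_sd=noise_sd,
    )


def true_beta_table(dataset: StudyDataset) -> np.ndarray:
    """(n_subjects, 8) matrix of true modulation parameters (0 if none)."""
    model = generating_model(dataset.config)
    out = np.zeros((dataset.n_subjects, 8))
    if dataset.config.effect_target == "none":
        return out
    for s, gt in enumerate(dataset.ground_truth):
        out[s] = model.beta_values(gt.theta)
    return out
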