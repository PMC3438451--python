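"""HDF5/CSV/JSON persistence for datasets, posteriors and reports."""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .model_space import GroundTruth
from .synthetic import StudyDataset, SyntheticStudyConfig
from .vl import FreeEnergyTerms, Posterior


def save_dataset(dataset: StudyDataset, path) -> None:
    """Write a study (epochs, time, lead field, ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(
            dataclasses.asdict(dataset.config), default=list
        )
        f.create_dataset("time_ms", data=dataset.time_ms)
        f.create_dataset("leadfield", data=dataset.leadfield)
        f.create_dataset("epochs", data=dataset.epochs)
        f.create_dataset("signal", data=dataset.signal)
        f.attrs["noise_sd"] = dataset.noise_sd
        g = f.create_group("ground_truth")
        for s, gt in enumerate(dataset.ground_truth):
            gs = g.create_group(f"subject{s}")
            gs.create_dataset("theta", data=gt.theta)
            gs.attrs["param_names"] = json.dumps(gt.param_names)
            gs.attrs["architecture_id"] = gt.architecture_id
            gs.attrs["effect_target"] = gt.effect_target
            gs.attrs["noise_sd"] = gt.noise_sd
            gs.attrs["covariate"] = json.dumps(list(gt.covariate))


def load_dataset(path) -> StudyDataset:
    with h5py.File(path, "r") as f:
        cfg_d = json.loads(f.attrs["config"])
        for key in ("contrasts", "gain_profile"):
            cfg_d[key] = tuple(cfg_d[key])
        config = SyntheticStudyConfig(**cfg_d)
        gts = []
        g = f["ground_truth"]
        for s in range(len(g)):
            gs = g[f"subject{s}"]
            gts.append(
                GroundTruth(
                    architecture_id=int(gs.attrs["architecture_id"]),
                    effect_target=str(gs.attrs["effect_target"]),
                    theta=gs["theta"][()],
                    param_names=json.loads(gs.attrs["param_names"]),
                    noise_sd=float(gs.attrs["noise_sd"]),
                    covariate=tuple(json.loads(gs.attrs["covariate"])),
                )
            )
        return StudyDataset(
            config=config,
            time_ms=f["time_ms"][()],
            leadfield=f["leadfield"][()],
            epochs=f["epochs"][()],
            signal=f["signal"][()],
            ground_truth=gts,
            noise_sd=float(f.attrs["noise_sd"]),
        )


def export_grand_averages_csv(dataset: StudyDataset, path) -> None:
    """Per-condition grand averages as a long channels x time CSV."""
    grand = dataset.grand_average()
    rows = []
    for c in range(grand.shape[-1]):
        df = pd.DataFrame(
            grand[:, :, c],
            columns=[f"t{t:+.0f}ms" for t in dataset.time_ms],
        )
        df.insert(0, "channel", np.arange(grand.shape[0]))
        df.insert(0, "condition", c)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def save_source_responses(
    responses: np.ndarray,
    time_ms: np.ndarray,
    path,
    theta: Optional[np.ndarray] = None,
    param_names: Optional[list] = None,
) -> None:
    """Simulated source responses (area x time x condition) to HDF5.

    Optionally stores the generating parameter vector as a table.
    """
    responses = np.asarray(responses, dtype=float)
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=responses)
        f.create_dataset("time_ms", data=np.asarray(time_ms, dtype=float))
        if theta is not None:
            g = f.create_group("parameters")
            g.create_dataset("theta", data=np.asarray(theta, dtype=float))
            if param_names is not None:
                g.attrs["names"] = json.dumps(list(param_names))


def export_source_responses_csv(
    responses: np.ndarray, time_ms: np.ndarray, path, area_labels=None
) -> None:
    """Long-format CSV of source responses (area, condition, time, value)."""
    responses = np.asarray(responses, dtype=float)
    n_areas, n_t, n_c = responses.shape
    if area_labels is None:
        area_labels = [f"source{i}" for i in range(n_areas)]
    frames = []
    for c in range(n_c):
        df = pd.DataFrame(
            responses[:, :, c],
            columns=[f"{t:+.0f}" for t in time_ms],
        )
        df.insert(0, "area", list(area_labels))
        df.insert(0, "condition", c)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_posterior(post: Posterior, path) -> None:
    """Posterior means, covariance and free-energy trace to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mean", data=post.mean)
        f.create_dataset("cov", data=post.cov)
        f.create_dataset("trace", data=np.asarray(post.trace))
        f.attrs.update(
            {
                "lam": post.lam,
                "lam_var": post.lam_var,
                "free_energy": post.free_energy,
                "accuracy": post.terms.accuracy,
                "complexity_theta": post.terms.complexity_theta,
                "complexity_lambda": post.terms.complexity_lambda,
                "converged": post.converged,
                "n_iter": post.n_iter,
            }
        )
        if post.param_names:
            f.attrs["param_names"] = json.dumps(post.param_names)
        if post.model_id is not None:
            f.attrs["model_id"] = str(post.model_id)
        if post.subject_id is not None:
            f.attrs["subject_id"] = str(post.subject_id)


def posterior_summary_line(post: Posterior) -> str:
    """One-line JSON summary for the model-comparison stage."""
    return json.dumps(
        {
            "model": post.model_id,
            "subject": post.subject_id,
            "free_energy": post.free_energy,
            "converged": post.converged,
            "n_iter": post.n_iter,
        },
        default=str,
    )
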