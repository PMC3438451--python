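"""Fixed-effects Bayesian model selection over log evidences.

Under the fixed-effects assumption (all subjects share one model), the
group log evidence of a model is the sum of its per-subject log
evidences.  Pairwise log Bayes factors are differences of pooled
evidences, and posterior model probabilities under a uniform model
prior are the softmax of the pooled evidences.  All quantities are in
nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .vl import LogEvidence

#: pooled evidences closer than this are reported as a tie (nats)
TIE_TOLERANCE = 1e-9


@dataclass
class ModelComparisonResult:
    """Pooled evidences, Bayes factors and posterior model probabilities."""

    model_ids: List[Hashable]
    pooled_evidence: np.ndarray  # nats, aligned with model_ids
    posterior_prob: np.ndarray
    winner: Hashable
    tie: bool

    def log_bayes_factor(self, i: Hashable, j: Hashable) -> float:
        """Pooled log evidence of model i minus model j (nats)."""
        ei = self.pooled_evidence[self.model_ids.index(i)]
        ej = self.pooled_evidence[self.model_ids.index(j)]
        return float(ei - ej)

    def to_frame(self) -> pd.DataFrame:
        best = self.pooled_evidence.max()
        return pd.DataFrame(
            {
                "model": self.model_ids,
                "pooled_log_evidence_nats": self.pooled_evidence,
                "delta_to_best_nats": self.pooled_evidence - best,
                "posterior_probability": self.posterior_prob,
            }
        )

    def report(self) -> str:
        lines = [
            "Fixed-effects Bayesian model comparison (log evidences in nats)",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v: .3f}"),
            f"winner: {self.winner}" + ("  [tie]" if self.tie else ""),
        ]
        return "\n".join(lines)


def pool_evidence(
    evidences: Iterable[LogEvidence],
) -> Dict[Hashable, float]:
    """Sum log evidences over subjects for each model.

    Every model must have exactly one evidence per subject; gaps are
    rejected with a listing of the missing (model, subject) cells.
    """
    by_model: Dict[Hashable, Dict[Hashable, float]] = {}
    subjects = set()
    for e in evidences:
        by_model.setdefault(e.model_id, {})[e.subject_id] = e.value
        subjects.add(e.subject_id)
    gaps = [
        (m, s)
        for m, cells in by_model.items()
        for s in subjects
        if s not in cells
    ]
    if gaps:
        raise ValueError(
            "missing (model, subject) evidences: "
            + ", ".join(f"({m}, {s})" for m, s in sorted(gaps, key=str))
        )
    return {m: float(sum(cells.values())) for m, cells in by_model.items()}


def compare(pooled: Dict[Hashable, float]) -> ModelComparisonResult:
    """Posterior model probabilities from pooled evidences (uniform prior)."""
    if len(pooled) < 2:
        raise ValueError("model comparison needs at least 2 models")
    model_ids = list(pooled.keys())
    F = np.array([pooled[m] for m in model_ids], dtype=float)
    z = F - F.max()  # shift invariance
    prob = np.exp(z) / np.exp(z).sum()
    best = F.max()
    at_best = np.flatnonzero(F >= best - TIE_TOLERANCE)
    tie = at_best.size > 1
    # ties broken by lowest model id (string order as fallback)
    winner = sorted((model_ids[i] for i in at_best), key=lambda m: (str(type(m)), m))[0]
    return ModelComparisonResult(
        model_ids=model_ids,
        pooled_evidence=F,
        posterior_prob=prob,
        winner=winner,
        tie=tie,
    )


def compare_evidences(evidences: Iterable[LogEvidence]) -> ModelComparisonResult:
    """Pool per-subject evidences and compare in one call."""
    return compare(pool_evidence(evidences))
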