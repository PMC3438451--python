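"""Generative network models: architecture + gain modulation + parameters.

A :class:`NetworkModel` binds an extrinsic architecture and a
condition-effect hypothesis to the canonical-microcircuit sources and
defines the free-parameter vector used for inversion.  Every free
parameter is a log-scale factor on its baseline value (effective =
baseline * exp(theta)), which preserves the structural signs of all
connections; condition-effect parameters ``beta`` act multiplicatively
on the targeted self-connection as ``exp(beta * covariate_c)``.

Free parameters, in packing order:

* four intrinsic self-connections per area (gamma1, gamma4, gamma7,
  gamma10) — the gain parameters;
* one strength per extrinsic forward and backward edge;
* one input gain per input area;
* one modulation parameter ``beta`` per affected area (sp/dp effect
  models only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dynamics import (
    BASE_RATE_PER_MS,
    DEFAULT_BACKWARD_STRENGTH,
    DEFAULT_FORWARD_STRENGTH,
    DP,
    N_POP,
    SP,
    SS,
    AssembledSystem,
    CMCParameters,
    StimulusInput,
    default_time_grid,
    simulate_batch,
)
from .model_space import (
    Architecture,
    ConditionEffectSpec,
    all_areas,
    build_effect_model,
)

#: prior variances of the log-scale factors, by parameter family
PRIOR_VARIANCES = {
    "intrinsic": 1.0 / 16.0,
    "extrinsic": 1.0 / 16.0,
    "input": 1.0 / 8.0,
    "beta": 1.0 / 16.0,
}

#: gamma indices (0-based) of the free intrinsic self-connections
FREE_GAMMA = {"g1": 0, "g4": 3, "g7": 6, "g10": 9}

_TARGET_POP = {"sp_self": SP, "dp_self": DP}
_TARGET_GAMMA = {"sp_self": 6, "dp_self": 9}


@dataclass
class NetworkModel:
    """A parameterised generative model of the eight-source network."""

    architecture: Architecture
    effect: ConditionEffectSpec
    cmc: CMCParameters = field(default_factory=CMCParameters)
    stimulus: StimulusInput = field(default_factory=StimulusInput)
    forward_strength: float = DEFAULT_FORWARD_STRENGTH
    backward_strength: float = DEFAULT_BACKWARD_STRENGTH

    def __post_init__(self):
        self.areas = all_areas()
        self._index = {a: i for i, a in enumerate(self.areas)}
        self._build_tables()

    # -- parameter bookkeeping ---------------------------------------------

    def _build_tables(self) -> None:
        names: List[str] = []
        families: List[str] = []
        entries: List[Tuple[int, int]] = []  # coupling entry scaled by theta_k

        n = len(self.areas) * N_POP
        W0 = np.zeros((n, n))
        for i, a in enumerate(self.areas):
            W0[i * N_POP : (i + 1) * N_POP, i * N_POP : (i + 1) * N_POP] = (
                self.cmc.intrinsic_matrix()
            )
        for a, b in self.architecture.forward_edges:
            ia, ib = self._index[a], self._index[b]
            W0[ib * N_POP + SS, ia * N_POP + SP] += (
                self.forward_strength * BASE_RATE_PER_MS
            )
        for a, b in self.architecture.backward_edges:
            ia, ib = self._index[a], self._index[b]
            W0[ib * N_POP + SP, ia * N_POP + DP] -= (
                self.backward_strength * BASE_RATE_PER_MS
            )

        for i, a in enumerate(self.areas):
            for gname, gidx in FREE_GAMMA.items():
                names.append(f"{gname}:{a.label}")
                families.append("intrinsic")
                tgt, src, _ = _gamma_entry(gidx)
                entries.append((i * N_POP + tgt, i * N_POP + src))
        for a, b in self.architecture.forward_edges:
            names.append(f"F:{a.label}->{b.label}")
            families.append("extrinsic")
            entries.append(
                (self._index[b] * N_POP + SS, self._index[a] * N_POP + SP)
            )
        for a, b in self.architecture.backward_edges:
            names.append(f"B:{a.label}->{b.label}")
            families.append("extrinsic")
            entries.append(
                (self._index[b] * N_POP + SP, self._index[a] * N_POP + DP)
            )

        b0 = np.zeros(n)
        input_rows: List[int] = []
        for a in self.architecture.input_areas:
            names.append(f"input:{a.label}")
            families.append("input")
            row = self._index[a] * N_POP + SS
            input_rows.append(row)
            b0[row] = 1.0
            entries.append((-1, -1))  # placeholder; handled via input map

        beta_rows: List[int] = []
        if self.effect.target != "none":
            pop = _TARGET_POP[self.effect.target]
            for a in self.effect.affected_areas:
                names.append(f"beta:{a.label}")
                families.append("beta")
                row = self._index[a] * N_POP + pop
                beta_rows.append(row)
                entries.append((-1, -1))

        self.param_names: List[str] = names
        self.param_families: List[str] = families
        self._W0 = W0
        self._b0 = b0
        ent = np.array(entries, dtype=int)
        scaled = np.array(
            [f in ("intrinsic", "extrinsic") for f in families], dtype=bool
        )
        self._scaled_idx = np.flatnonzero(scaled)
        self._scaled_rows = ent[scaled, 0]
        self._scaled_cols = ent[scaled, 1]
        self._input_idx = np.flatnonzero(np.array(families) == "input")
        self._input_rows = np.array(input_rows, dtype=int)
        self._beta_idx = np.flatnonzero(np.array(families) == "beta")
        self._beta_rows = np.array(beta_rows, dtype=int)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_conditions(self) -> int:
        return self.effect.n_conditions

    def prior(self) -> Tuple[np.ndarray, np.ndarray]:
        """Prior mean (zeros) and diagonal variances of the free parameters."""
        mean = np.zeros(self.n_params)
        var = np.array([PRIOR_VARIANCES[f] for f in self.param_families])
        return mean, var

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    def beta_values(self, theta: np.ndarray) -> np.ndarray:
        """Extract the per-area modulation parameters from a theta vector."""
        return np.asarray(theta, dtype=float)[self._beta_idx]

    def beta_names(self) -> List[str]:
        return [self.param_names[i] for i in self._beta_idx]

    # -- assembly -----------------------------------------------------------

    def coupling_batch(
        self, thetas: np.ndarray, condition: int, dtype=np.float64
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Batched coupling matrices and input weights for one condition."""
        thetas = np.atleast_2d(np.asarray(thetas, dtype=dtype))
        B = thetas.shape[0]
        n = self._W0.shape[0]
        W = np.broadcast_to(self._W0.astype(dtype), (B, n, n)).copy()
        if self._scaled_idx.size:
            W[:, self._scaled_rows, self._scaled_cols] = self._W0[
                self._scaled_rows, self._scaled_cols
            ] * np.exp(thetas[:, self._scaled_idx])
        if self._beta_idx.size:
            cov = self.effect.covariate[condition]
            factor = np.exp(thetas[:, self._beta_idx] * cov)
            W[:, self._beta_rows, self._beta_rows] = (
                W[:, self._beta_rows, self._beta_rows] * factor
            )
        b = np.broadcast_to(self._b0.astype(dtype), (B, n)).copy()
        if self._input_idx.size:
            b[:, self._input_rows] = np.exp(thetas[:, self._input_idx])
        return W, b

    def assemble(
        self, condition: int = 0, theta: Optional[np.ndarray] = None
    ) -> AssembledSystem:
        """Single wired system at ``theta`` (defaults to prior mean)."""
        if theta is None:
            theta = np.zeros(self.n_params)
        W, b = self.coupling_batch(np.atleast_2d(theta), condition)
        kappa = self.kappa_vector()
        return AssembledSystem(
            coupling=W[0],
            input_weights=b[0],
            kappa=kappa,
            sigmoid_slope=self.cmc.sigmoid_slope,
            stimulus=self.stimulus,
        )

    def kappa_vector(self) -> np.ndarray:
        return np.tile(1.0 / self.cmc.tau_ms, len(self.areas))

    def simulate_sources(
        self,
        thetas: np.ndarray,
        time_grid_ms: Optional[np.ndarray] = None,
        step_ms: float = 0.5,
        conditions: Optional[Sequence[int]] = None,
        dtype=np.float64,
    ) -> np.ndarray:
        """Source (sp depolarisation) responses for a batch of parameters.

        Returns (B, n_areas, T, C).
        """
        if time_grid_ms is None:
            time_grid_ms = default_time_grid()
        if conditions is None:
            conditions = range(self.n_conditions)
        conditions = list(conditions)
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        B = thetas.shape[0]
        Ws, bs = [], []
        for c in conditions:
            W, b = self.coupling_batch(thetas, c, dtype=dtype)
            Ws.append(W)
            bs.append(b)
        Wall = np.concatenate(Ws, axis=0)
        ball = np.concatenate(bs, axis=0)
        resp = simulate_batch(
            Wall,
            ball,
            self.kappa_vector().astype(dtype),
            self.stimulus,
            time_grid_ms,
            sigmoid_slope=self.cmc.sigmoid_slope,
            step_ms=step_ms,
            dtype=dtype,
        )
        # (C*B, n_areas, T) -> (B, n_areas, T, C)
        n_areas, T = resp.shape[1], resp.shape[2]
        resp = resp.reshape(len(conditions), B, n_areas, T)
        return np.moveaxis(resp, 0, -1)


def _gamma_entry(gidx: int) -> Tuple[int, int, float]:
    from .dynamics import GAMMA_EDGES

    return GAMMA_EDGES[gidx]


def make_model(
    architecture: Architecture,
    effect_target: str = "none",
    n_conditions: int = 1,
    covariate: Optional[Tuple[float, ...]] = None,
    **kwargs,
) -> NetworkModel:
    """Convenience constructor pairing an architecture with an effect model."""
    effect = build_effect_model(effect_target, n_conditions, covariate)
    if effect.target == "none" and len(effect.covariate) != n_conditions:
        effect = ConditionEffectSpec(
            target="none", covariate=tuple(np.zeros(n_conditions))
        )
    return NetworkModel(architecture=architecture, effect=effect, **kwargs)


class ERPForward:
    """Forward map from free parameters to mode-space predicted responses.

    Composes the network dynamics, the lead field and (optionally) the
    spatial-mode projection: ``theta -> modes @ leadfield @ sp(t, c)``.
    The flattened output is what variational Laplace fits.
    """

    def __init__(
        self,
        model: NetworkModel,
        leadfield: np.ndarray,
        modes: Optional[np.ndarray] = None,
        time_grid_ms: Optional[np.ndarray] = None,
        step_ms: float = 0.5,
        sim_dtype=np.float64,
    ):
        self.model = model
        self.leadfield = np.asarray(leadfield, dtype=float)
        self.modes = None if modes is None else np.asarray(modes, dtype=float)
        self.time_grid_ms = (
            default_time_grid() if time_grid_ms is None else np.asarray(time_grid_ms)
        )
        self.step_ms = step_ms
        self.sim_dtype = sim_dtype
        self._proj = (
            self.leadfield if self.modes is None else self.modes @ self.leadfield
        )

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def output_shape(self) -> Tuple[int, int, int]:
        return (
            self._proj.shape[0],
            self.time_grid_ms.size,
            self.model.n_conditions,
        )

    def predict(self, thetas: np.ndarray) -> np.ndarray:
        """Predicted mode responses, shape (B, n_out, T, C)."""
        src = self.model.simulate_sources(
            thetas,
            time_grid_ms=self.time_grid_ms,
            step_ms=self.step_ms,
            dtype=self.sim_dtype,
        )
        return np.einsum("os,bstc->botc", self._proj, src)

    def predict_flat(self, thetas: np.ndarray) -> np.ndarray:
        """Predicted responses flattened to (B, n_out*T*C)."""
        out = self.predict(thetas)
        return out.reshape(out.shape[0], -1)
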