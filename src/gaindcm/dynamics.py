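"""Canonical microcircuit (CMC) neural mass dynamics.

Each cortical source contains four populations — spiny stellate (ss),
superficial pyramidal (sp), inhibitory interneuron (ii) and deep
pyramidal (dp) — with second-order synaptic kinetics per population:

    dv/dt = u
    du/dt = kappa * drive - 2*kappa*u - kappa**2 * v,   kappa = 1/tau

where ``drive`` sums gamma-weighted presynaptic firing (a centred
sigmoid of depolarisation) over the intrinsic wiring table, extrinsic
input from other sources, and the exogenous stimulus.  The ten intrinsic
connections are::

    gamma1  ss -> ss  (-)      gamma6  dp -> ii  (+)
    gamma2  sp -> ss  (-)      gamma7  sp -> sp  (-)   "negative gain"
    gamma3  ii -> ss  (-)      gamma8  ss -> sp  (+)
    gamma4  ii -> ii  (-)      gamma9  ii -> dp  (-)
    gamma5  ss -> ii  (+)      gamma10 dp -> dp  (-)

gamma7 is the self-inhibition of superficial pyramidal cells; its
inverse plays the role of synaptic gain (precision) and is the quantity
modulated by stimulus contrast in this package.  Extrinsic forward
connections are excitatory (sp of the lower area onto ss of the higher);
backward connections are inhibitory (dp of the higher area onto sp of
the lower).

All connection strengths are expressed as dimensionless multiples of a
base rate ``BASE_RATE_PER_MS``; population membrane units are mV and
time is in ms throughout.  The integrator is a fixed-step classical
Runge-Kutta scheme over batches of parameter sets, which is what makes
finite-difference sensitivity computation affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

POPULATIONS = ("ss", "sp", "ii", "dp")
N_POP = 4
SS, SP, II, DP = 0, 1, 2, 3

#: base coupling rate: 200 s^-1 expressed per ms
BASE_RATE_PER_MS = 0.2

#: intrinsic wiring table: gamma index (0-based) -> (target pop, source pop, sign)
GAMMA_EDGES = (
    (SS, SS, -1.0),  # gamma1
    (SS, SP, -1.0),  # gamma2
    (SS, II, -1.0),  # gamma3
    (II, II, -1.0),  # gamma4
    (II, SS, +1.0),  # gamma5
    (II, DP, +1.0),  # gamma6
    (SP, SP, -1.0),  # gamma7
    (SP, SS, +1.0),  # gamma8
    (DP, II, -1.0),  # gamma9
    (DP, DP, -1.0),  # gamma10
)

DEFAULT_GAMMA = np.array([8.0, 4.0, 4.0, 4.0, 4.0, 2.0, 4.0, 4.0, 2.0, 1.0])
DEFAULT_TAU_MS = np.array([2.0, 2.0, 16.0, 28.0])  # ss, sp, ii, dp
DEFAULT_SIGMOID_SLOPE = 2.0

#: default extrinsic strengths (multiples of the base rate); chosen so
#: evoked responses propagate visibly to the top of a four-level
#: hierarchy while the resting state stays stable under coherent
#: +-2 prior-SD scaling of all extrinsic connections
DEFAULT_FORWARD_STRENGTH = 6.0
DEFAULT_BACKWARD_STRENGTH = 3.0

#: divergence guard on membrane depolarisation (mV)
DIVERGENCE_BOUND_MV = 1e3


class DivergenceError(RuntimeError):
    """Raised when an integrated trajectory exceeds the amplitude bound."""


@dataclass
class CMCParameters:
    """Intrinsic parameters of one source.

    gamma magnitudes are positive; signs are fixed by the wiring table.
    """

    gamma: np.ndarray = field(default_factory=lambda: DEFAULT_GAMMA.copy())
    tau_ms: np.ndarray = field(default_factory=lambda: DEFAULT_TAU_MS.copy())
    sigmoid_slope: float = DEFAULT_SIGMOID_SLOPE

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.tau_ms = np.asarray(self.tau_ms, dtype=float)
        if self.gamma.shape != (10,):
            raise ValueError("gamma must have 10 entries")
        if self.tau_ms.shape != (4,):
            raise ValueError("tau_ms must have 4 entries")
        if np.any(self.gamma <= 0) or np.any(self.tau_ms <= 0):
            raise ValueError("gamma and tau magnitudes must be positive")
        if self.sigmoid_slope <= 0:
            raise ValueError("sigmoid slope must be positive")

    def intrinsic_matrix(self, modulation: Optional[np.ndarray] = None) -> np.ndarray:
        """Signed 4x4 intrinsic coupling block (rows: target population).

        ``modulation``, if given, multiplies the corresponding gamma
        entries (e.g. ``exp(beta * covariate)`` on gamma7).
        """
        g = self.gamma if modulation is None else self.gamma * modulation
        block = np.zeros((N_POP, N_POP))
        for k, (tgt, src, sign) in enumerate(GAMMA_EDGES):
            block[tgt, src] += sign * g[k]
        return block * BASE_RATE_PER_MS


@dataclass
class StimulusInput:
    """Smooth exogenous driving input: a Gaussian bump in time (ms)."""

    onset_ms: float = 64.0
    dispersion_ms: float = 16.0
    amplitude: float = 1.0

    def __call__(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        z = (t - self.onset_ms) / self.dispersion_ms
        return self.amplitude * np.exp(-0.5 * z * z)


def sigmoid(v, slope: float = DEFAULT_SIGMOID_SLOPE):
    """Centred firing-rate nonlinearity, odd and bounded in (-1/2, 1/2).

    ``sigmoid(v) = 1/(1+exp(-slope*v)) - 1/2``; slope at zero is
    ``slope/4``.
    """
    return 0.5 * np.tanh(0.5 * slope * np.asarray(v, dtype=float))


def sigmoid_derivative(v, slope: float = DEFAULT_SIGMOID_SLOPE):
    t = np.tanh(0.5 * slope * np.asarray(v, dtype=float))
    return 0.25 * slope * (1.0 - t * t)


@dataclass
class AssembledSystem:
    """A fully wired network ready to integrate.

    ``coupling`` is the (n_pop_total x n_pop_total) signed matrix taking
    population firing to drive (1/ms per unit firing); it contains both
    the intrinsic blocks and the extrinsic edges.  ``input_weights``
    routes the scalar stimulus into spiny stellate populations of the
    input areas.
    """

    coupling: np.ndarray
    input_weights: np.ndarray
    kappa: np.ndarray  # (n_pop_total,) inverse time constants, 1/ms
    sigmoid_slope: float
    stimulus: StimulusInput

    @property
    def n_states(self) -> int:
        return 2 * self.coupling.shape[-1]

    @property
    def n_areas(self) -> int:
        return self.coupling.shape[-1] // N_POP


def state_derivative(system: AssembledSystem, state: np.ndarray, t_ms: float) -> np.ndarray:
    """Time derivative of the flattened state ``[v, u]`` at time ``t_ms``."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        bad = int(np.flatnonzero(~np.isfinite(state))[0])
        raise ValueError(f"non-finite state entry at index {bad}")
    n = system.coupling.shape[-1]
    v, u = state[:n], state[n:]
    drive = system.coupling @ sigmoid(v, system.sigmoid_slope)
    drive = drive + system.input_weights * system.stimulus(t_ms)
    k = system.kappa
    du = k * drive - 2.0 * k * u - k * k * v
    return np.concatenate([v * 0 + u, du])


def linearize(system: AssembledSystem, state: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of :func:`state_derivative` at ``state``.

    Block form ``[[0, I], [K (W s'(v)) - K^2, -2K]]`` with K the
    diagonal of inverse time constants.  Sparsity between areas follows
    the extrinsic wiring.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        bad = int(np.flatnonzero(~np.isfinite(state))[0])
        raise ValueError(f"non-finite state entry at index {bad}")
    n = system.coupling.shape[-1]
    v = state[:n]
    k = system.kappa
    J = np.zeros((2 * n, 2 * n))
    J[:n, n:] = np.eye(n)
    J[n:, :n] = (k[:, None] * system.coupling) * sigmoid_derivative(
        v, system.sigmoid_slope
    )[None, :]
    J[n:, :n] -= np.diag(k * k)
    J[n:, n:] = -2.0 * np.diag(k)
    return J


def resting_jacobian_stable(system: AssembledSystem) -> bool:
    """True when all eigenvalues at the resting state have Re < 0."""
    J = linearize(system, np.zeros(system.n_states))
    return bool(np.all(np.linalg.eigvals(J).real < 0))


# ---------------------------------------------------------------------------
# batched fixed-step integration


def simulate_batch(
    coupling: np.ndarray,
    input_weights: np.ndarray,
    kappa: np.ndarray,
    stimulus: StimulusInput,
    time_grid_ms: np.ndarray,
    sigmoid_slope: float = DEFAULT_SIGMOID_SLOPE,
    step_ms: float = 0.5,
    dtype=np.float64,
    amplitude_bound: float = DIVERGENCE_BOUND_MV,
) -> np.ndarray:
    """Integrate a batch of wired networks from rest; return sp depolarisation.

    Parameters
    ----------
    coupling : (B, n, n) or (n, n)
        Signed firing-to-drive coupling per batch element.
    input_weights : (B, n) or (n,)
        Stimulus routing (non-zero only on ss of input areas).
    kappa : (n,)
        Inverse time constants, shared across the batch.
    time_grid_ms : (T,)
        Equally spaced output grid; the internal step must divide the
        output step exactly.

    Returns
    -------
    (B, n_areas, T) array of superficial-pyramidal depolarisation, the
    EEG-generating signal.
    """
    coupling = np.asarray(coupling, dtype=dtype)
    squeeze = coupling.ndim == 2
    if squeeze:
        coupling = coupling[None]
    input_weights = np.asarray(input_weights, dtype=dtype)
    if input_weights.ndim == 1:
        input_weights = np.broadcast_to(input_weights, coupling.shape[:1] + input_weights.shape)
    input_weights = np.ascontiguousarray(input_weights)

    B, n, _ = coupling.shape
    t = np.asarray(time_grid_ms, dtype=float)
    if t.size < 2:
        raise ValueError("time grid needs at least two points")
    out_step = t[1] - t[0]
    if not np.allclose(np.diff(t), out_step):
        raise ValueError("time grid must be equally spaced")
    n_sub = out_step / step_ms
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise ValueError("internal step must divide the output step")
    n_sub = int(round(n_sub))

    kappa = np.asarray(kappa, dtype=dtype)
    h = np.asarray(step_ms, dtype=dtype)[()]

    sp_idx = np.arange(n // N_POP) * N_POP + SP

    # fold the rate constant and the sigmoid's 1/2 into the coupling so the
    # inner loop is one matmul plus elementwise terms:
    #   du = (kappa/2 * W) tanh(rho*v/2) + kappa*b*stim - 2*kappa*u - kappa^2*v
    KW = 0.5 * kappa[None, :, None] * coupling
    kb = kappa[None, :] * input_weights
    twok = (2.0 * kappa).astype(dtype)
    k2 = (kappa * kappa).astype(dtype)
    half_slope = dtype(0.5 * sigmoid_slope) if dtype is not np.float64 else 0.5 * sigmoid_slope

    x = np.zeros((B, 2 * n), dtype=dtype)
    out = np.empty((B, n // N_POP, t.size), dtype=np.float64)
    out[:, :, 0] = x[:, sp_idx]
    vmax = np.zeros(B)

    # preallocated work buffers
    dx = [np.empty_like(x) for _ in range(4)]
    xt = np.empty_like(x)
    s_buf = np.empty((B, n, 1), dtype=dtype)
    dm = np.empty((B, n, 1), dtype=dtype)
    tmp = np.empty((B, n), dtype=dtype)

    def f(xx, stim_val, k_out):
        vv = xx[:, :n]
        uu = xx[:, n:]
        np.multiply(vv[..., None], half_slope, out=s_buf)
        np.tanh(s_buf, out=s_buf)
        np.matmul(KW, s_buf, out=dm)
        du = k_out[:, n:]
        np.multiply(kb, stim_val, out=du)
        du += dm[..., 0]
        np.multiply(twok, uu, out=tmp)
        du -= tmp
        np.multiply(k2, vv, out=tmp)
        du -= tmp
        k_out[:, :n] = uu

    t0 = t[0]
    for i_out in range(1, t.size):
        for i_sub in range(n_sub):
            tc = t0 + ((i_out - 1) * n_sub + i_sub) * step_ms
            s0 = float(stimulus(tc))
            s_half = float(stimulus(tc + 0.5 * step_ms))
            s1 = float(stimulus(tc + step_ms))
            f(x, s0, dx[0])
            np.multiply(dx[0], 0.5 * h, out=xt)
            xt += x
            f(xt, s_half, dx[1])
            np.multiply(dx[1], 0.5 * h, out=xt)
            xt += x
            f(xt, s_half, dx[2])
            np.multiply(dx[2], h, out=xt)
            xt += x
            f(xt, s1, dx[3])
            # x += h/6 * (k1 + 2 k2 + 2 k3 + k4)
            dx[1] += dx[2]
            dx[1] *= 2.0
            dx[1] += dx[0]
            dx[1] += dx[3]
            dx[1] *= h / 6.0
            x += dx[1]
        out[:, :, i_out] = x[:, sp_idx]
        with np.errstate(invalid="ignore"):
            vmax = np.maximum(vmax, np.abs(x[:, :n]).max(axis=1))

    bad_mask = ~np.isfinite(vmax) | (vmax > amplitude_bound)
    if np.any(bad_mask):
        bad = np.flatnonzero(bad_mask)
        raise DivergenceError(
            f"trajectory exceeded {amplitude_bound} mV for batch elements {bad.tolist()}"
        )
    return out[0] if squeeze else out


def default_time_grid() -> np.ndarray:
    """Peristimulus output grid: -100..400 ms at 200 Hz (5 ms steps)."""
    return np.arange(-100.0, 400.0 + 2.5, 5.0)


def integrate_erp(
    model,
    condition: int,
    time_grid_ms: Optional[np.ndarray] = None,
    step_ms: float = 0.5,
) -> np.ndarray:
    """Source-level evoked response of a NetworkModel in one condition.

    Returns the (n_areas, T) superficial-pyramidal depolarisation time
    courses from a resting initial state.  Deterministic given inputs.
    """
    if time_grid_ms is None:
        time_grid_ms = default_time_grid()
    system = model.assemble(condition=condition)
    return simulate_batch(
        system.coupling,
        system.input_weights,
        system.kappa,
        system.stimulus,
        time_grid_ms,
        sigmoid_slope=system.sigmoid_slope,
        step_ms=step_ms,
    )
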