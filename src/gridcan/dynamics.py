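"""Network integration: velocity drive, recurrence, and neuron-model updates.

Every neuron receives a feed-forward drive

    B_i = 1 + alpha_i * (e_theta_i . v)

where v is the animal's displacement per integration step (meters/step; with
alpha = 45 and steps <= 4 mm this keeps B near its operating point of 1), and
a recurrent drive sum_j W_ij S_j.  Three single-neuron models share this
input structure:

integrator (forward Euler, rectification f(x) = max(x, 0)):
    S <- S + (dt/tau_i) * (-S + f(W S + B))

phenomenological resonator: the integrator state u evolves as above, but the
activity that the rest of the network (and all analyses) see is re-defined as
    S = R * u * |du/dt|^eps
i.e. the low-pass integrator is composed with a fractional-order high-pass
stage; eps = 0, R = 1 reduces exactly to the integrator.

mechanistic resonator: a slow activity-dependent negative feedback variable m
with sigmoidal steady state is subtracted from the drive,
    S <- S + (dt/tau_i) * (-S - g*m + f(W S + B))
    m <- m + (dt/tau_m) * (m_inf(S) - m),   m_inf = 1/(1 + exp((S_half - S)/k))
g = 0 reduces exactly to the integrator; resonance requires tau_m > tau.

For homogeneous (unjittered) weight matrices the recurrent sum is evaluated
as four circular convolutions on the n x n sheet via FFT, which is exact up
to floating point and much faster than the dense matvec; jittered matrices
use the dense product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gridcan.network import (
    NetworkSpec,
    PreferenceMap,
    WeightMatrix,
    HeterogeneityAssignment,
    build_preference_map,
    _direction_kernels,
    _THETAS,
)
from gridcan.trajectory import Trajectory, velocity_series

__all__ = [
    "NeuronModel", "SimulationConfig", "ActivityTrace", "feedforward_drive",
    "step_integrator", "step_phenomenological", "step_mechanistic",
    "simulate", "StructuredRecurrence", "DenseRecurrence",
]


@dataclass(frozen=True)
class NeuronModel:
    """Single-neuron model family and parameters.

    kind: 'integrator', 'phenomenological' or 'mechanistic'.
    epsilon: high-pass exponent of the phenomenological stage.
    R: output scaling of the phenomenological stage.  The default 0.7 keeps
       the homogeneous resonator network's grid patterns intact with mean
       rates within ~10% of the integrator network's; 'auto' instead matches
       mean rates exactly via a short calibration run (which lands at a
       weaker recurrence scale and noticeably degrades pattern quality --
       exposed for sensitivity analyses).  Isolated chirp runs treat 'auto'
       as 1 (the raw high-pass product); R only scales the output there.
    g, k, S_half, tau_m: slow-negative-feedback parameters (mechanistic).
       The default feedback strength g = 0.1 is the strongest feedback for
       which the homogeneous network still forms stable grid patterns;
       beyond it the activity-dependent feedback sets bumps traveling on
       their own and path integration decoheres.
    derivative_mode: 'magnitude' uses |du/dt|^eps (fractional powers of
       negative numbers are undefined); 'rectified' uses max(du/dt, 0)^eps.
    recurrence_on: 'output' feeds the re-defined activity back into the
       recurrent sum (default); 'state' feeds the raw integrator state.
    """

    kind: str = "integrator"
    tau: float = 0.010        # s
    epsilon: float = 0.3
    R: float | str = 0.7
    g: float = 0.1
    k: float = 0.1
    S_half: float = 0.3
    tau_m: float = 0.075      # s
    derivative_mode: str = "magnitude"
    deriv_tau: float = 0.0    # s; low-pass time constant for du/dt (0 = raw)
    recurrence_on: str = "output"

    def __post_init__(self) -> None:
        if self.kind not in ("integrator", "phenomenological", "mechanistic"):
            raise ValueError(f"unknown neuron model kind {self.kind!r}")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not self.tau_m > 0:
            raise ValueError("tau_m must be positive")
        if self.derivative_mode not in ("magnitude", "rectified"):
            raise ValueError(f"unknown derivative_mode {self.derivative_mode!r}")
        if self.recurrence_on not in ("output", "state"):
            raise ValueError(f"unknown recurrence_on {self.recurrence_on!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration step, settling period, initialization seed, recording."""

    dt: float = 1e-3        # s (1 ms for virtual trajectories)
    settle: float = 0.100   # s of zero-velocity drive before the run
    init_seed: int = 0
    record_stride: int = 1  # keep every k-th sample
    record_m: bool = False

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.settle < 0:
            raise ValueError("settle must be >= 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass
class ActivityTrace:
    """Per-neuron activity over the trajectory-aligned part of the run.

    S[t, i] is the activity of neuron i at trajectory sample t (settling
    excluded).  ``m`` optionally holds the feedback state (mechanistic).
    """

    S: np.ndarray          # (T_rec, N)
    dt: float
    stride: int = 1
    m: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.S.shape[1]

    @property
    def n_samples(self) -> int:
        return self.S.shape[0]


def feedforward_drive(prefs: PreferenceMap, alpha_i, v) -> np.ndarray:
    """B_i = 1 + alpha_i * (e_theta_i . v), v in meters per step."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    return 1.0 + np.asarray(alpha_i) * (prefs.e_hat @ v)


def _rectify(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def step_integrator(S, W, B, tau_i, dt) -> np.ndarray:
    """One forward-Euler step of the rectified integrator."""
    S = np.asarray(S, dtype=float)
    drive = _recur(W, S) + B
    _check_finite(drive)
    return S + (dt / np.asarray(tau_i)) * (-S + _rectify(drive))


def step_phenomenological(state, W, B, tau_i, epsilon, R, dt):
    """One step of the phenomenological resonator.

    ``state`` is (u, S_out) from the previous step: u is the integrator
    variable, S_out the re-defined activity seen by the recurrent sum.
    Returns ((u', S_out'), S_out').
    """
    u, S_prev = state
    u = np.asarray(u, dtype=float)
    drive = _recur(W, np.asarray(S_prev, dtype=float)) + B
    _check_finite(drive)
    u_new = u + (dt / np.asarray(tau_i)) * (-u + _rectify(drive))
    du = (u_new - u) / dt
    if epsilon == 0:
        S_out = R * u_new
    else:
        S_out = R * u_new * np.abs(du) ** epsilon
    return (u_new, S_out), S_out


def step_mechanistic(S, m, W, B, tau_i, g, k, S_half, tau_m, dt):
    """One step of the slow-negative-feedback resonator; returns (S', m')."""
    S = np.asarray(S, dtype=float)
    m = np.asarray(m, dtype=float)
    drive = _recur(W, S) + B
    _check_finite(drive)
    S_new = S + (dt / np.asarray(tau_i)) * (-S - g * m + _rectify(drive))
    m_new = m + (dt / tau_m) * (_m_inf(S, S_half, k) - m)
    return S_new, m_new


def _m_inf(S, S_half, k):
    z = np.clip((S_half - S) / k, -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(z))


def _check_finite(x) -> None:
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite values in network drive")


def _flush_subnormals(x: np.ndarray, eps: float = 1e-12) -> None:
    """Zero out vanishing activities in place.

    Exponentially decaying activities of suppressed neurons otherwise drift
    into the subnormal floating-point range, where the recurrent matvec pays
    a large microcode penalty; below ``eps`` they are dynamically zero.
    """
    x[np.abs(x) < eps] = 0.0


class DenseRecurrence:
    """Recurrent drive through an explicit dense weight matrix."""

    def __init__(self, W: np.ndarray):
        self.W = W

    def __call__(self, S: np.ndarray) -> np.ndarray:
        return self.W @ S.astype(self.W.dtype)


class StructuredRecurrence:
    """Recurrent drive via FFT convolution, for unjittered weights.

    The homogeneous W is translation-invariant given the source neuron's
    preferred direction, so W S decomposes into four circular convolutions of
    direction-masked activity sheets with the corresponding shifted DoG
    kernels.  Agrees with the dense product to float32 precision.
    """

    def __init__(self, spec: NetworkSpec, prefs: PreferenceMap | None = None):
        if prefs is None:
            prefs = build_preference_map(spec.n)
        self.n = spec.n
        kernels = _direction_kernels(spec)
        self.k_hat = np.stack([np.fft.rfft2(k) for k in kernels])
        dir_idx = np.argmin(
            np.abs(prefs.theta[:, None] - _THETAS[None, :]), axis=1
        ).reshape(spec.n, spec.n)
        self.masks = np.stack([(dir_idx == d) for d in range(4)]).astype(float)

    def __call__(self, S: np.ndarray) -> np.ndarray:
        sheet = S.reshape(self.n, self.n)
        acc = np.zeros((self.n, self.n // 2 + 1), dtype=complex)
        for d in range(4):
            acc += self.k_hat[d] * np.fft.rfft2(sheet * self.masks[d])
        return np.fft.irfft2(acc, s=(self.n, self.n)).ravel()


def _recur(W, S: np.ndarray) -> np.ndarray:
    if callable(W):
        return W(S)
    Wm = W.W if isinstance(W, WeightMatrix) else np.asarray(W)
    return Wm @ S.astype(Wm.dtype)


def _make_recurrence(assignment: HeterogeneityAssignment, spec: NetworkSpec):
    """Pick the FFT path when the weights carry no per-synapse jitter."""
    wm = assignment.weights
    if wm.jitter_seed is None and wm.spec is not None:
        return StructuredRecurrence(wm.spec)
    return DenseRecurrence(wm.W)


def simulate(
    spec: NetworkSpec,
    assignment: HeterogeneityAssignment,
    traj: Trajectory,
    model: NeuronModel | None = None,
    cfg: SimulationConfig | None = None,
    prefs: PreferenceMap | None = None,
    recurrence=None,
) -> ActivityTrace:
    """Run the CAN over a trajectory and return trajectory-aligned activity.

    Activity starts uniform-random in [0, 1] (from ``cfg.init_seed``); the
    mechanistic feedback state starts at its steady value m_inf(S0).  The
    network settles under zero velocity for ``cfg.settle`` seconds, then each
    trajectory step t >= 1 applies the velocity drive of that step.  The
    recorded trace has one row per trajectory sample (row 0 is the settled
    state at the starting position).
    """
    model = model or NeuronModel()
    cfg = cfg or SimulationConfig()
    if prefs is None:
        prefs = build_preference_map(spec.n)
    if abs(traj.dt_sample - cfg.dt) > 1e-12:
        raise ValueError(
            f"trajectory dt ({traj.dt_sample}) must equal simulation dt ({cfg.dt})"
        )
    if np.any(cfg.dt / np.asarray(assignment.tau_i) > 1.0):
        raise ValueError("Euler stability requires dt/tau <= 1 for every neuron")

    N = spec.n_neurons
    tau_i = assignment.tau_i
    alpha_i = assignment.alpha_i
    recur = recurrence if recurrence is not None else _make_recurrence(assignment, spec)

    rng = np.random.default_rng(cfg.init_seed)
    S = rng.uniform(0.0, 1.0, N)

    v = velocity_series(traj, units="per_step")
    T = traj.n_samples - 1
    n_settle = int(round(cfg.settle / cfg.dt))
    n_rec = T // cfg.record_stride + 1
    out = np.empty((n_rec, N), dtype=np.float32)
    out_m = np.empty((n_rec, N), dtype=np.float32) if cfg.record_m else None

    dt = cfg.dt
    inv_tau = dt / tau_i
    B0 = np.ones(N)

    if model.kind == "integrator":
        for _ in range(n_settle):
            S = S + inv_tau * (-S + _rectify(recur(S) + B0))
            _flush_subnormals(S)
        out[0] = S
        r = 1
        for t in range(1, T + 1):
            B = 1.0 + alpha_i * (prefs.e_hat @ v[t])
            S = S + inv_tau * (-S + _rectify(recur(S) + B))
            _flush_subnormals(S)
            if t % cfg.record_stride == 0:
                out[r] = S
                r += 1
            if t % 5000 == 0:
                _check_divergence(S)
        m_trace = None

    elif model.kind == "phenomenological":
        R = model.R
        if R == "auto":
            R = calibrate_R_network(spec, model, dt=dt)
        u = S
        # the derivative is zero before the first step, so for eps > 0 the
        # re-defined activity starts at zero
        S_out = R * u if model.epsilon == 0 else np.zeros_like(u)
        fb = S_out if model.recurrence_on == "output" else u
        du_state = np.zeros_like(u)
        a_d = dt / model.deriv_tau if model.deriv_tau > 0 else 1.0
        for _ in range(n_settle):
            u_new = u + inv_tau * (-u + _rectify(recur(fb) + B0))
            du_state = du_state + a_d * ((u_new - u) / dt - du_state)
            du = du_state
            if model.epsilon == 0:
                S_out = R * u_new
            elif model.derivative_mode == "magnitude":
                S_out = R * u_new * np.abs(du) ** model.epsilon
            else:
                S_out = R * u_new * _rectify(du) ** model.epsilon
            u = u_new
            _flush_subnormals(u)
            _flush_subnormals(S_out)
            fb = S_out if model.recurrence_on == "output" else u
        out[0] = S_out
        r = 1
        for t in range(1, T + 1):
            B = 1.0 + alpha_i * (prefs.e_hat @ v[t])
            u_new = u + inv_tau * (-u + _rectify(recur(fb) + B))
            du_state = du_state + a_d * ((u_new - u) / dt - du_state)
            du = du_state
            if model.epsilon == 0:
                S_out = R * u_new
            elif model.derivative_mode == "magnitude":
                S_out = R * u_new * np.abs(du) ** model.epsilon
            else:
                S_out = R * u_new * _rectify(du) ** model.epsilon
            u = u_new
            _flush_subnormals(u)
            _flush_subnormals(S_out)
            fb = S_out if model.recurrence_on == "output" else u
            if t % cfg.record_stride == 0:
                out[r] = S_out
                r += 1
            if t % 5000 == 0:
                _check_divergence(u)
        m_trace = None

    else:  # mechanistic
        g, k, S_half = model.g, model.k, model.S_half
        inv_tau_m = dt / model.tau_m
        m = _m_inf(S, S_half, k)
        for _ in range(n_settle):
            S_new = S + inv_tau * (-S - g * m + _rectify(recur(S) + B0))
            m = m + inv_tau_m * (_m_inf(S, S_half, k) - m)
            S = S_new
            _flush_subnormals(S)
        out[0] = S
        if out_m is not None:
            out_m[0] = m
        r = 1
        for t in range(1, T + 1):
            B = 1.0 + alpha_i * (prefs.e_hat @ v[t])
            S_new = S + inv_tau * (-S - g * m + _rectify(recur(S) + B))
            m = m + inv_tau_m * (_m_inf(S, S_half, k) - m)
            S = S_new
            _flush_subnormals(S)
            if t % cfg.record_stride == 0:
                out[r] = S
                if out_m is not None:
                    out_m[r] = m
                r += 1
            if t % 5000 == 0:
                _check_divergence(S)
        m_trace = out_m

    return ActivityTrace(S=out[:r], dt=dt * cfg.record_stride,
                         stride=cfg.record_stride,
                         m=m_trace[:r] if m_trace is not None else None)


_R_NETWORK_CACHE: dict = {}


def calibrate_R_network(
    spec: NetworkSpec,
    model: NeuronModel,
    dt: float = 1e-3,
    duration: float = 2.0,
    calib_seed: int = 99991,
) -> float:
    """Output scale R matching the homogeneous resonator network's mean
    activity to the integrator network's.

    Runs short homogeneous simulations on a fixed calibration trajectory:
    one integrator run fixes the target rate, two resonator probe runs give
    the (log-log) response of mean rate to R, and the match is interpolated.
    Cached per (n, tau, epsilon).
    """
    key = (spec.n, round(model.tau, 9), round(model.epsilon, 9),
           model.derivative_mode, round(model.deriv_tau, 9))
    if key in _R_NETWORK_CACHE:
        return _R_NETWORK_CACHE[key]
    from gridcan.trajectory import Arena, generate_virtual_trajectory
    from gridcan.network import HeterogeneitySpec
    from gridcan.network import apply_heterogeneities, WeightMatrix

    arena = Arena()
    traj = generate_virtual_trajectory(arena, duration, dt_sample=dt,
                                       seed=calib_seed)
    assign = apply_heterogeneities(
        spec, WeightMatrix(W=None, spec=spec), HeterogeneitySpec(degree=0))
    cfg = SimulationConfig(dt=dt, init_seed=calib_seed)

    def mean_rate(m: NeuronModel) -> float:
        tr = simulate(spec, assign, traj, m, cfg)
        return float(tr.S.mean())

    from dataclasses import replace as _replace

    target = mean_rate(_replace(model, kind="integrator"))
    r1, r2 = 0.5, 1.0
    a1 = mean_rate(_replace(model, R=r1))
    a2 = mean_rate(_replace(model, R=r2))
    if a1 <= 0 or a2 <= 0 or a1 == a2:
        R_star = 1.0
    else:
        slope = (np.log(a2) - np.log(a1)) / (np.log(r2) - np.log(r1))
        R_star = float(np.exp(np.log(r2) + (np.log(target) - np.log(a2))
                              / slope))
        R_star = float(np.clip(R_star, 0.05, 20.0))
    _R_NETWORK_CACHE[key] = R_star
    return R_star


def _check_divergence(S: np.ndarray) -> None:
    mx = float(np.max(np.abs(S)))
    if not np.isfinite(mx) or mx > 1e6:
        raise FloatingPointError(
            f"network activity diverged (max |S| = {mx:.3g})"
        )
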