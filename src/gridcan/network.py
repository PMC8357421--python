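"""Toroidal CAN lattice: direction tiling, Mexican-hat weights, heterogeneities.

The network is an n x n sheet of rate neurons with periodic boundaries.  Each
neuron carries a preferred direction theta in {0, pi/2, pi, 3pi/2} (east,
north, west, south), laid out in 2x2 blocks so each direction claims exactly a
quarter of the sheet.  The recurrent weight from neuron j to neuron i is a
difference of Gaussians (DoG) evaluated at the toroidal displacement shifted
by l lattice units along j's preferred direction:

    W_ij = W0(x_i - x_j - l * e_theta_j),
    W0(x) = a * exp(-gamma |x|^2) - exp(-beta |x|^2),

with beta = 3 / lambda^2, gamma = 1.1 * beta, and lambda the lattice
periodicity.  With a = 1 every weight is <= 0 (an all-inhibitory network) and
the center shift makes velocity input translate the bump pattern.

Biological heterogeneities are injected at integer degrees 1..5 by sampling,
per neuron, the integration time constant tau and the velocity gain alpha from
uniform ranges that widen with degree, and, per synapse, a zero-mean additive
jitter to W whose span widens with degree.  The raw jitter bounds are scaled
by a dimensionless factor kappa (default 1e-5): applied raw they would dwarf
every weight, and any net-positive jitter mean accumulates over the N^2
synapses into runaway excitation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "NetworkSpec", "PreferenceMap", "WeightMatrix", "HeterogeneitySpec",
    "HeterogeneityAssignment", "build_preference_map", "toroidal_displacement",
    "build_weight_matrix", "apply_heterogeneities", "weight_rmse",
    "HETEROGENEITY_TABLE", "dog_kernel",
]

# Per-degree uniform sampling bounds: tau (ms), alpha (gain), raw weight jitter.
HETEROGENEITY_TABLE = {
    1: {"tau_ms": (8.0, 12.0), "alpha": (35.0, 55.0), "jitter": (0.0, 300.0)},
    2: {"tau_ms": (6.0, 14.0), "alpha": (25.0, 65.0), "jitter": (0.0, 600.0)},
    3: {"tau_ms": (4.0, 16.0), "alpha": (15.0, 75.0), "jitter": (0.0, 900.0)},
    4: {"tau_ms": (2.0, 18.0), "alpha": (5.0, 85.0), "jitter": (0.0, 1200.0)},
    5: {"tau_ms": (1.0, 20.0), "alpha": (0.0, 100.0), "jitter": (0.0, 1500.0)},
}

HETEROGENEITY_KINDS = ("intrinsic", "afferent", "synaptic")

# Fixed 2x2 block layout (row, col) -> direction index into _THETAS.
# [[E, N], [W, S]]: any fixed tiling satisfies the uniform-block arrangement.
_BLOCK = np.array([[0, 1], [3, 2]])
_THETAS = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])  # E, N, W, S


@dataclass(frozen=True)
class NetworkSpec:
    """Structural and default-parameter description of the CAN sheet."""

    n: int = 60                  # lattice side; n^2 neurons
    lambda_grid: float = 13.0    # periodicity of the weight kernel, lattice units
    shift: float = 2.0           # center shift l along preferred direction
    a: float = 1.0               # DoG sign parameter (1 -> all-inhibitory)
    tau_default: float = 0.010   # s
    alpha_default: float = 45.0  # velocity gain

    def __post_init__(self) -> None:
        if self.n % 2 != 0:
            raise ValueError("lattice side n must be even (2x2 direction blocks)")
        if not self.lambda_grid > 0:
            raise ValueError("lambda_grid must be positive")

    @property
    def beta(self) -> float:
        return 3.0 / self.lambda_grid**2

    @property
    def gamma(self) -> float:
        return 1.1 * self.beta

    @property
    def n_neurons(self) -> int:
        return self.n * self.n


@dataclass
class PreferenceMap:
    """Per-neuron preferred directions and unit vectors (flattened row-major)."""

    theta: np.ndarray  # (N,) values in {0, pi/2, pi, 3pi/2}
    e_hat: np.ndarray  # (N, 2) unit vectors (cos, sin)
    n: int


@dataclass
class WeightMatrix:
    """Dense recurrent weights, W[i, j] = weight from j onto i."""

    W: np.ndarray
    spec: NetworkSpec | None = None
    jitter_seed: int | None = None

    @property
    def shape(self):
        return self.W.shape


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Which heterogeneity kinds to inject, at what degree, with which seed.

    ``jitter_scale`` (kappa) converts the raw per-synapse jitter bound into
    weight units.  By default the jitter is zero-mean: each synapse receives
    U[-bound/2, +bound/2] * kappa, mirroring how the tau and alpha ranges
    straddle their homogeneous defaults.  ``jitter_centered=False`` switches
    to strictly positive U[0, bound] * kappa; note that a positive mean adds
    up over the N^2 synapses and flips the net recurrence excitatory (and
    hence unstable) once kappa * bound/2 * N^2 exceeds the total inhibition
    a neuron receives.  The default kappa = 1e-5 puts the degree-1 jitter
    span at a few percent of the largest weight magnitude, a perturbation as
    mild as the degree-1 tau and alpha spans.
    """

    kinds: tuple = HETEROGENEITY_KINDS
    degree: int = 0
    seed: int = 0
    jitter_scale: float = 1e-5
    jitter_centered: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.degree <= 5:
            raise ValueError("degree must be in 0..5")
        for k in self.kinds:
            if k not in HETEROGENEITY_KINDS:
                raise ValueError(f"unknown heterogeneity kind {k!r}")
        if self.degree > 0 and not self.kinds:
            raise ValueError("kinds must be non-empty for degree > 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["kinds"] = list(self.kinds)
        return json.dumps(d)


@dataclass
class HeterogeneityAssignment:
    """Concrete per-neuron tau/alpha values and the (possibly jittered) W."""

    tau_i: np.ndarray      # (N,) seconds
    alpha_i: np.ndarray    # (N,)
    weights: WeightMatrix
    spec: HeterogeneitySpec | None = None


def build_preference_map(n: int) -> PreferenceMap:
    """Tile the n x n sheet with 2x2 direction blocks [[E, N], [W, S]]."""
    if n % 2 != 0:
        raise ValueError("n must be even")
    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    idx = _BLOCK[rows % 2, cols % 2]
    theta = _THETAS[idx].ravel()
    e_hat = np.column_stack([np.cos(theta), np.sin(theta)])
    # snap exact zeros (cos(pi/2) etc. are ~1e-16)
    e_hat = np.round(e_hat, 12)
    return PreferenceMap(theta=theta, e_hat=e_hat, n=n)


def toroidal_displacement(xi, xj, n: int) -> np.ndarray:
    """Minimum-image displacement xi - xj on the n-torus.

    Each component is mapped into (-n/2, n/2].
    """
    d = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    d = np.mod(d, n)
    d = np.where(d > n / 2, d - n, d)
    return d


def dog_kernel(spec: NetworkSpec, dx, dy) -> np.ndarray:
    """Difference-of-Gaussians W0 at displacement (dx, dy)."""
    r2 = np.asarray(dx, dtype=float) ** 2 + np.asarray(dy, dtype=float) ** 2
    return spec.a * np.exp(-spec.gamma * r2) - np.exp(-spec.beta * r2)


def _direction_kernels(spec: NetworkSpec) -> np.ndarray:
    """Shifted DoG kernels K[dir, dr, dc] = W0(minimg(dr, dc) - l*e_dir).

    K is indexed by raw displacement (dr, dc) = ((row_i - row_j) mod n,
    (col_i - col_j) mod n); the minimum image is taken per component before
    evaluating the DoG.  Lattice x maps to columns and y to rows so that
    e_hat = (cos, sin) lands on the (col, row) axes.
    """
    n = spec.n
    raw = np.arange(n, dtype=float)
    mi = np.where(raw > n / 2, raw - n, raw)  # minimum image per component
    dr, dc = np.meshgrid(mi, mi, indexing="ij")
    kernels = np.empty((4, n, n))
    for d, th in enumerate(_THETAS):
        ex, ey = np.cos(th), np.sin(th)
        kernels[d] = dog_kernel(spec, dc - spec.shift * ex, dr - spec.shift * ey)
    return kernels


def build_weight_matrix(
    spec: NetworkSpec, prefs: PreferenceMap | None = None, dtype=np.float32
) -> WeightMatrix:
    """Assemble the dense N x N center-shifted Mexican-hat weight matrix."""
    if prefs is None:
        prefs = build_preference_map(spec.n)
    n = spec.n
    N = n * n
    kernels = _direction_kernels(spec).astype(dtype)
    dir_idx = np.argmin(
        np.abs(prefs.theta[:, None] - _THETAS[None, :]), axis=1
    )
    rows = np.arange(N) // n
    cols = np.arange(N) % n
    W = np.empty((N, N), dtype=dtype)
    # column j: kernel of j's direction evaluated at (r_i - r_j, c_i - c_j)
    for j in range(N):
        dr = (rows - rows[j]) % n
        dc = (cols - cols[j]) % n
        W[:, j] = kernels[dir_idx[j], dr, dc]
    return WeightMatrix(W=W, spec=spec)


def apply_heterogeneities(
    spec: NetworkSpec,
    weights: WeightMatrix,
    het: HeterogeneitySpec,
) -> HeterogeneityAssignment:
    """Sample per-neuron tau/alpha and per-synapse jitter at the given degree.

    Kinds not requested stay at the homogeneous defaults; degree 0 returns the
    defaults exactly (W is shared, not copied).  All draws come from a single
    generator seeded by ``het.seed``, so an assignment is reproducible.
    """
    N = spec.n_neurons
    tau_i = np.full(N, spec.tau_default)
    alpha_i = np.full(N, spec.alpha_default)
    if het.degree == 0:
        return HeterogeneityAssignment(tau_i, alpha_i, weights, het)

    rng = np.random.default_rng(het.seed)
    bounds = HETEROGENEITY_TABLE[het.degree]
    W_out = weights
    if "intrinsic" in het.kinds:
        lo, hi = bounds["tau_ms"]
        tau_i = rng.uniform(lo, hi, N) * 1e-3
    if "afferent" in het.kinds:
        lo, hi = bounds["alpha"]
        alpha_i = rng.uniform(lo, hi, N)
    if "synaptic" in het.kinds:
        lo, hi = bounds["jitter"]
        shape = weights.W.shape
        if het.jitter_centered:
            jit = rng.uniform(-hi / 2, hi / 2, shape)
        else:
            jit = rng.uniform(lo, hi, shape)
        W_j = weights.W + (het.jitter_scale * jit).astype(weights.W.dtype)
        W_out = WeightMatrix(
            W=W_j.astype(weights.W.dtype), spec=spec, jitter_seed=het.seed
        )
    return HeterogeneityAssignment(tau_i, alpha_i, W_out, het)


def weight_rmse(wa: WeightMatrix | np.ndarray, wb: WeightMatrix | np.ndarray) -> float:
    """Root-mean-square difference between two weight matrices."""
    A = wa.W if isinstance(wa, WeightMatrix) else np.asarray(wa)
    B = wb.W if isinstance(wb, WeightMatrix) else np.asarray(wb)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    diff = A.astype(np.float64) - B.astype(np.float64)
    return float(np.sqrt(np.mean(diff**2)))
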