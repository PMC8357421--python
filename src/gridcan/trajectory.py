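"""Virtual rodent trajectories in open arenas.

A virtual animal starts at the arena center and, at every millisecond step,
draws a step length d ~ U[0, step_max] and a small heading deviation
A ~ U[-turn_halfwidth, +turn_halfwidth] added to a persistent heading, so that
movement is smooth.  Candidate positions that would leave the arena are
redrawn; within a thin zone along the wall the absolute heading is redrawn
from U[0, 2*pi] to allow the sharp turns that real animals make at boundaries.
The heading is measured from the +y axis: x advances with sin(heading), y
with cos(heading).

These fast trajectories cover an arena far quicker than a recorded animal
path, which is what makes the network simulations affordable; recorded paths
can still be loaded from a plain (t, x, y) table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Arena", "Trajectory", "generate_virtual_trajectory", "velocity_series",
    "coverage_fraction", "load_trajectory_table", "save_trajectory_table",
    "random_walk_trajectory",
]


@dataclass(frozen=True)
class Arena:
    """Open arena: a circle (inscribed) or square within [0, extent]^2.

    ``extent`` is the circle diameter or the square side, in meters
    (default 2 m).
    """

    shape: str = "circle"
    extent: float = 2.0

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "square"):
            raise ValueError(f"unknown arena shape {self.shape!r}")
        if not self.extent > 0:
            raise ValueError("arena extent must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.extent / 2.0, self.extent / 2.0)

    def contains(self, x, y):
        """Vectorized membership test."""
        x = np.asarray(x)
        y = np.asarray(y)
        if self.shape == "square":
            return (x >= 0) & (x <= self.extent) & (y >= 0) & (y <= self.extent)
        r = self.extent / 2.0
        return (x - r) ** 2 + (y - r) ** 2 <= r**2

    def wall_distance(self, x: float, y: float) -> float:
        """Distance from (x, y) to the nearest wall (negative if outside)."""
        if self.shape == "square":
            return min(x, y, self.extent - x, self.extent - y)
        r = self.extent / 2.0
        return r - math.hypot(x - r, y - r)


@dataclass
class Trajectory:
    """Time-stamped 2D path sampled at uniform dt_sample."""

    positions: np.ndarray  # (T+1, 2) meters
    dt_sample: float  # seconds per step
    arena: Arena | None = None
    seed: int | None = None

    @property
    def duration(self) -> float:
        return (len(self.positions) - 1) * self.dt_sample

    @property
    def n_samples(self) -> int:
        return len(self.positions)

    def __len__(self) -> int:
        return len(self.positions)


def generate_virtual_trajectory(
    arena: Arena,
    duration: float,
    dt_sample: float = 1e-3,
    seed: int = 0,
    step_max: float = 0.004,
    turn_halfwidth: float = math.pi / 36,
    boundary_zone: float = 0.02,
    resample_cap: int = 1000,
) -> Trajectory:
    """Generate a fast virtual trajectory starting at the arena center.

    Each step draws d ~ U[0, step_max] and a heading deviation
    A ~ U[-turn_halfwidth, +turn_halfwidth]; the position update is
    x += d*sin(heading), y += d*cos(heading) with the persistent absolute
    heading.  Within ``boundary_zone`` of the wall the absolute heading is
    redrawn from U[0, 2*pi].  Draws taking the animal out of the arena are
    rejected and repicked, up to ``resample_cap`` attempts per step.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if not dt_sample > 0:
        raise ValueError("dt_sample must be positive")
    if not step_max > 0:
        raise ValueError("step_max must be positive")

    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt_sample))
    pos = np.empty((n_steps + 1, 2), dtype=np.float64)
    x, y = arena.center
    pos[0] = (x, y)
    heading = rng.uniform(0.0, 2 * math.pi)

    for t in range(1, n_steps + 1):
        near_wall = arena.wall_distance(x, y) < boundary_zone
        for attempt in range(resample_cap):
            d = rng.uniform(0.0, step_max)
            if near_wall:
                cand_heading = rng.uniform(0.0, 2 * math.pi)
            else:
                cand_heading = heading + rng.uniform(-turn_halfwidth, turn_halfwidth)
            xn = x + d * math.sin(cand_heading)
            yn = y + d * math.cos(cand_heading)
            if arena.contains(xn, yn):
                break
        else:
            raise RuntimeError(
                f"trajectory stuck at ({x:.4f}, {y:.4f}) after "
                f"{resample_cap} resampling attempts (step {t})"
            )
        x, y, heading = xn, yn, cand_heading
        pos[t] = (x, y)

    return Trajectory(positions=pos, dt_sample=dt_sample, arena=arena, seed=seed)


def random_walk_trajectory(
    arena: Arena,
    duration: float,
    dt_sample: float = 1e-3,
    seed: int = 0,
    step_max: float = 0.004,
) -> Trajectory:
    """Pure isotropic random walk (heading fully redrawn every step).

    A coverage baseline: lacking a persistent heading it diffuses instead of
    running, so it covers the arena more slowly than the virtual trajectory.
    """
    return generate_virtual_trajectory(
        arena,
        duration,
        dt_sample=dt_sample,
        seed=seed,
        step_max=step_max,
        turn_halfwidth=math.pi,
        boundary_zone=0.0,
    )


def velocity_series(traj: Trajectory, units: str = "per_step") -> np.ndarray:
    """Velocity vectors from consecutive displacements; v[0] = (0, 0).

    ``units='per_step'`` returns meters per sample step (the scale the
    feed-forward drive expects); ``'per_second'`` divides by dt_sample.
    """
    if traj.n_samples < 2:
        raise ValueError("need at least two samples to derive velocities")
    if units not in ("per_step", "per_second"):
        raise ValueError(f"unknown units {units!r}")
    v = np.zeros_like(traj.positions)
    v[1:] = np.diff(traj.positions, axis=0)
    if units == "per_second":
        v /= traj.dt_sample
    return v


def coverage_fraction(traj: Trajectory, arena: Arena, n_pixels: int = 100) -> float:
    """Fraction of in-arena pixels visited at least once."""
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    px = arena.extent / n_pixels
    ix = np.clip((traj.positions[:, 0] / px).astype(int), 0, n_pixels - 1)
    iy = np.clip((traj.positions[:, 1] / px).astype(int), 0, n_pixels - 1)
    visited = np.zeros((n_pixels, n_pixels), dtype=bool)
    visited[ix, iy] = True

    centers = (np.arange(n_pixels) + 0.5) * px
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    in_arena = arena.contains(cx, cy)
    n_in = int(in_arena.sum())
    if n_in == 0:
        return 0.0
    return float((visited & in_arena).sum() / n_in)


def load_trajectory_table(
    path,
    dt_sample: float = 1e-3,
    arena: Arena | None = None,
) -> Trajectory:
    """Load a (t, x, y) CSV table and resample to uniform dt_sample.

    Time must be monotone increasing; positions are linearly interpolated
    onto a uniform grid.  If ``arena`` is given, out-of-arena samples are
    reported by row index.
    """
    df = pd.read_csv(path)
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"trajectory table missing column {col!r}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("trajectory table needs at least two rows")
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"non-monotone time at row {bad}")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    if arena is not None:
        inside = arena.contains(x, y)
        if not np.all(inside):
            rows = np.flatnonzero(~inside)[:10]
            raise ValueError(f"out-of-arena samples at rows {rows.tolist()}")
    tu = np.arange(t[0], t[-1] + dt_sample / 2, dt_sample)
    xu = np.interp(tu, t, x)
    yu = np.interp(tu, t, y)
    return Trajectory(
        positions=np.column_stack([xu, yu]), dt_sample=dt_sample, arena=arena
    )


def save_trajectory_table(traj: Trajectory, path) -> None:
    """Write a trajectory as a `t,x,y` CSV table (seconds, meters)."""
    t = np.arange(traj.n_samples) * traj.dt_sample
    pd.DataFrame(
        {"t": t, "x": traj.positions[:, 0], "y": traj.positions[:, 1]}
    ).to_csv(path, index=False)
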