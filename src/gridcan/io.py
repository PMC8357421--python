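"""HDF5 persistence for trajectories, weights, and activity traces."""

from __future__ import annotations

import numpy as np
import h5py

from gridcan.trajectory import Arena, Trajectory
from gridcan.network import NetworkSpec, WeightMatrix
from gridcan.dynamics import ActivityTrace

__all__ = [
    "save_trajectory_h5", "load_trajectory_h5",
    "save_weights_h5", "load_weights_h5",
    "save_trace_h5", "load_trace_h5",
]


def save_trajectory_h5(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("/trajectory/positions", data=traj.positions)
        d.attrs["dt_sample"] = traj.dt_sample
        if traj.seed is not None:
            d.attrs["seed"] = traj.seed
        if traj.arena is not None:
            d.attrs["arena_shape"] = traj.arena.shape
            d.attrs["extent"] = traj.arena.extent


def load_trajectory_h5(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        d = f["/trajectory/positions"]
        arena = None
        if "arena_shape" in d.attrs:
            arena = Arena(shape=str(d.attrs["arena_shape"]),
                          extent=float(d.attrs["extent"]))
        return Trajectory(
            positions=d[...],
            dt_sample=float(d.attrs["dt_sample"]),
            arena=arena,
            seed=int(d.attrs["seed"]) if "seed" in d.attrs else None,
        )


def save_weights_h5(wm: WeightMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("/network/W", data=wm.W, chunks=True)
        if wm.spec is not None:
            for k in ("n", "lambda_grid", "shift", "a", "tau_default",
                      "alpha_default"):
                d.attrs[k] = getattr(wm.spec, k)
        if wm.jitter_seed is not None:
            d.attrs["jitter_seed"] = wm.jitter_seed


def load_weights_h5(path) -> WeightMatrix:
    with h5py.File(path, "r") as f:
        d = f["/network/W"]
        spec = None
        if "n" in d.attrs:
            spec = NetworkSpec(
                n=int(d.attrs["n"]), lambda_grid=float(d.attrs["lambda_grid"]),
                shift=float(d.attrs["shift"]), a=float(d.attrs["a"]),
                tau_default=float(d.attrs["tau_default"]),
                alpha_default=float(d.attrs["alpha_default"]),
            )
        js = int(d.attrs["jitter_seed"]) if "jitter_seed" in d.attrs else None
        return WeightMatrix(W=d[...], spec=spec, jitter_seed=js)


def save_trace_h5(trace: ActivityTrace, path, **attrs) -> None:
    with h5py.File(path, "w") as f:
        n = trace.S.shape[1]
        d = f.create_dataset("/sim/S", data=trace.S.astype(np.float32),
                             chunks=(min(1000, trace.S.shape[0]), n))
        d.attrs["dt"] = trace.dt
        d.attrs["stride"] = trace.stride
        for k, v in attrs.items():
            d.attrs[k] = v
        if trace.m is not None:
            f.create_dataset("/sim/m", data=trace.m.astype(np.float32))


def load_trace_h5(path) -> ActivityTrace:
    with h5py.File(path, "r") as f:
        d = f["/sim/S"]
        m = f["/sim/m"][...] if "/sim/m" in f else None
        return ActivityTrace(S=d[...], dt=float(d.attrs["dt"]),
                             stride=int(d.attrs["stride"]), m=m)
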