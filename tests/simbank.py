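"""Shared simulation bank for the network-level acceptance tests.

All network-level claims (heterogeneity disruption, resonator rescue,
spectral suppression) are measured on a common set of 60x60 simulations
driven by one virtual trajectory.  Simulations are expensive, so each run
is executed once per test session and only small summaries (sampled grid
scores, percent changes, variance profiles) are kept.

Scale choices (full-scale protocols use 100 s runs; these are scaled down to fit
a test session): metric-bearing runs use a 20 s trajectory, spectral-only
twin runs 6 s, homogeneous pattern-quality runs 30 s.  Grid metrics are
computed for an evenly spaced subsample of 24 of the 3600 neurons.
"""

from __future__ import annotations

import numpy as np

from gridcan import (
    Arena,
    NetworkSpec,
    NeuronModel,
    SimulationConfig,
    HeterogeneitySpec,
    build_preference_map,
    build_weight_matrix,
    apply_heterogeneities,
    generate_virtual_trajectory,
    simulate,
)
from gridcan.gridmetrics import metrics_for_neurons, percent_change
from gridcan.spectral import (
    activity_spectrum,
    normalized_spectral_difference,
    octave_auc,
    total_auc,
)

N = 60
TRAJ_SEED = 11
INIT_SEED = 7
HET_SEEDS = (101, 102, 103)
T_METRIC = 20.0   # s; metric-bearing heterogeneous/homogeneous twins
T_SPECTRAL = 6.0  # s; spectral-only twins across all degrees
T_QUALITY = 30.0  # s; homogeneous pattern-quality runs
N_METRIC_NEURONS = 24
F_CUT = 25.0      # Hz stored spectral band


def _model(kind: str, tau_m: float = 0.075) -> NeuronModel:
    return NeuronModel(kind=kind, tau_m=tau_m)


class SimBank:
    """Lazily computed summaries of the shared 60x60 simulation set."""

    def __init__(self):
        self.arena = Arena()
        self.spec = NetworkSpec(n=N)
        self.prefs = build_preference_map(N)
        self.weights = build_weight_matrix(self.spec, self.prefs)
        self.idx = np.linspace(0, N * N - 1, N_METRIC_NEURONS).astype(int)
        self._traj = {}
        self._homo_assign = apply_heterogeneities(
            self.spec, self.weights, HeterogeneitySpec(degree=0))
        self._cache = {}

    def traj(self, T: float):
        if T not in self._traj:
            self._traj[T] = generate_virtual_trajectory(
                self.arena, T, seed=TRAJ_SEED)
        return self._traj[T]

    def _assignment(self, degree: int, seed: int, kinds=None):
        if degree == 0:
            return self._homo_assign
        spec_h = HeterogeneitySpec(
            kinds=kinds or ("intrinsic", "afferent", "synaptic"),
            degree=degree, seed=seed)
        return apply_heterogeneities(self.spec, self.weights, spec_h)

    def run(self, kind: str, degree: int, seed: int = HET_SEEDS[0],
            T: float = T_METRIC, kinds=None, tau_m: float = 0.075):
        """Summaries for one simulation (cached by configuration).

        Grid metrics are computed for runs long enough to build rate maps
        (T >= T_METRIC); short spectral-only runs keep just the spectra.
        """
        key = (kind, degree, seed if degree else 0, T,
               tuple(kinds) if kinds else None, tau_m)
        if key in self._cache:
            return self._cache[key]
        traj = self.traj(T)
        assignment = self._assignment(degree, seed, kinds)
        trace = simulate(
            self.spec, assignment, traj, _model(kind, tau_m),
            SimulationConfig(init_seed=INIT_SEED), prefs=self.prefs)
        out = {}
        if T >= T_METRIC:
            m = metrics_for_neurons(trace, traj, self.idx, arena=self.arena)
            out["metrics"] = m
            out["grid_scores"] = m["grid_score"]
        sp = activity_spectrum(trace, f_cut=F_CUT)
        out["spectrum"] = sp
        self._cache[key] = out
        return out

    # -- paired summaries ---------------------------------------------------

    def percent_change_grid(self, kind: str, degree: int, seed: int,
                            T: float = T_METRIC, kinds=None,
                            tau_m: float = 0.075) -> np.ndarray:
        het = self.run(kind, degree, seed, T, kinds, tau_m)
        homo = self.run(kind, 0, 0, T, None, tau_m)
        return percent_change(het["grid_scores"], homo["grid_scores"])

    def spectral_comparison(self, kind: str, degree: int, seed: int,
                            T: float = T_METRIC, kinds=None,
                            tau_m: float = 0.075):
        het = self.run(kind, degree, seed, T, kinds, tau_m)
        homo = self.run(kind, 0, 0, T, None, tau_m)
        comp = normalized_spectral_difference(het["spectrum"], homo["spectrum"])
        return {
            "variance": comp.variance,
            "freqs": comp.freqs,
            "total_auc": total_auc(comp.freqs, comp.variance),
            "octave_shares": octave_auc(comp.freqs, comp.variance,
                                        denominator="bands_total"),
        }

    def cross_model_difference(self, kind: str, degree: int, seed: int,
                               T: float = T_SPECTRAL):
        """Mean normalized difference between a resonator network's activity
        spectra and the matched integrator network's (same heterogeneity
        instance, trajectory, and initialization)."""
        res = self.run(kind, degree, seed, T)["spectrum"]
        ref = self.run("integrator", degree, seed, T)["spectrum"]
        comp = normalized_spectral_difference(res, ref)
        return comp.freqs, comp.delta.mean(axis=0)


_BANK = None


def get_bank() -> SimBank:
    global _BANK
    if _BANK is None:
        _BANK = SimBank()
    return _BANK
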