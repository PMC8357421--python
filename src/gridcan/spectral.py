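"""Spectral analysis of temporal activity.

Heterogeneities perturb network activity predominantly at low frequencies.
To quantify that, each neuron's activity S_i(t) over the whole run is Fourier
transformed (no taper, DC retained: windowing would redistribute exactly the
low-frequency content under study), a heterogeneous run is compared with its
homogeneous twin through the normalized difference

    dS(f) = (S_het(f) - S_homo(f)) / (max S_het + max S_homo),

the across-neuron variance of dS(f) summarizes the perturbation per
frequency, and areas under the curve in the octaves 0-2, 2-4, 4-8 and
8-16 Hz summarize its distribution over bands.  The twin runs must share the
trajectory and initial conditions for the per-neuron difference to be
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gridcan.dynamics import ActivityTrace

__all__ = [
    "SpectrumSet", "SpectralComparison", "activity_spectrum",
    "normalized_spectral_difference", "variance_profile", "octave_auc",
    "OCTAVES",
]

OCTAVES = ((0.0, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 16.0))


@dataclass
class SpectrumSet:
    """Single-sided FFT magnitudes, one row per neuron."""

    freqs: np.ndarray       # (F,)
    magnitude: np.ndarray   # (neurons, F)
    provenance: str = ""


@dataclass
class SpectralComparison:
    """Per-neuron normalized spectral differences and their variance."""

    freqs: np.ndarray
    delta: np.ndarray             # (neurons, F), |delta| <= 1 by construction
    variance: np.ndarray          # (F,) across-neuron variance of delta


def activity_spectrum(
    trace: ActivityTrace, f_cut: float = 50.0, demean: bool = False
) -> SpectrumSet:
    """Per-neuron magnitude spectrum of S_i(t), truncated at ``f_cut`` Hz."""
    T = trace.n_samples * trace.dt
    if T < 2.0:
        raise ValueError("trace shorter than 2 s")
    S = np.asarray(trace.S, dtype=float)
    if demean:
        S = S - S.mean(axis=0, keepdims=True)
    mag = np.abs(np.fft.rfft(S, axis=0)).T  # (neurons, F)
    freqs = np.fft.rfftfreq(trace.n_samples, trace.dt)
    keep = freqs <= f_cut
    return SpectrumSet(freqs=freqs[keep], magnitude=mag[:, keep])


def normalized_spectral_difference(
    spec_het: SpectrumSet, spec_homo: SpectrumSet
) -> SpectralComparison:
    """Per-neuron normalized difference between twin runs' spectra."""
    if spec_het.magnitude.shape != spec_homo.magnitude.shape:
        raise ValueError("spectrum sets have mismatched shapes")
    if not np.allclose(spec_het.freqs, spec_homo.freqs):
        raise ValueError("frequency axes differ")
    max_h = spec_het.magnitude.max(axis=1, keepdims=True)
    max_o = spec_homo.magnitude.max(axis=1, keepdims=True)
    denom = max_h + max_o
    denom[denom == 0] = 1.0
    delta = (spec_het.magnitude - spec_homo.magnitude) / denom
    var = delta.var(axis=0)
    return SpectralComparison(freqs=spec_het.freqs, delta=delta, variance=var)


def variance_profile(
    comparison: SpectralComparison, normalized: bool = False
) -> np.ndarray:
    """Across-neuron variance of the normalized difference per frequency bin."""
    if comparison.delta.shape[0] < 2:
        raise ValueError("variance profile needs at least two neurons")
    v = comparison.delta.var(axis=0)
    if normalized:
        mx = v.max()
        if mx > 0:
            v = v / mx
    return v


def octave_auc(
    freqs: np.ndarray,
    profile: np.ndarray,
    bands=OCTAVES,
    denominator: str = "full_spectrum",
) -> np.ndarray:
    """Percent area under ``profile`` per octave band.

    ``denominator='full_spectrum'`` divides by the AUC over the whole
    frequency axis (relative power); ``'bands_total'`` divides by the summed
    band AUCs so the shares total 100%.
    """
    freqs = np.asarray(freqs, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if freqs[-1] < max(hi for _, hi in bands):
        raise ValueError("frequency axis does not cover the octave bands")
    aucs = np.array([_band_auc(freqs, profile, lo, hi) for lo, hi in bands])
    if denominator == "full_spectrum":
        total = np.trapezoid(profile, freqs)
    elif denominator == "bands_total":
        total = aucs.sum()
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if total == 0:
        return np.zeros(len(bands))
    return 100.0 * aucs / total


def total_auc(freqs: np.ndarray, profile: np.ndarray) -> float:
    """Trapezoidal AUC of a profile over its full frequency axis."""
    return float(np.trapezoid(np.asarray(profile, float), np.asarray(freqs, float)))


def _band_auc(freqs, profile, lo, hi) -> float:
    # interpolate the band edges so shares are exact for flat profiles
    grid = freqs[(freqs > lo) & (freqs < hi)]
    edges = np.concatenate([[lo], grid, [hi]])
    vals = np.interp(edges, freqs, profile)
    return float(np.trapezoid(vals, edges))
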