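"""Rate maps and grid-cell measurements.

The arena is divided into n_pixels x n_pixels bins (default 100 x 100).  A
neuron's rate map is its mean activity per visit to each pixel (the activity
map normalized by the occupancy map); maps are smoothed with a 2D Gaussian
(sigma = 2 px, truncated at 3 sigma, weights renormalized over valid pixels
so arena edges are not dragged toward zero).  Unvisited or out-of-arena
pixels are invalid and excluded from every statistic.

Eight measurements summarize each map: grid score, average and peak rate,
number / mean size / average spacing of firing fields, spatial information
rate (bits/s) and sparsity.  The grid score contrasts rotational symmetries
of the map's spatial autocorrelogram:

    grid score = min(SAC60, SAC120) - max(SAC30, SAC90, SAC150)

where SAC_phi is the Pearson correlation between the autocorrelogram and its
rotation by phi degrees, over mutually valid lags.  Hexagonal
(triangular-lattice) firing scores positive; square lattices and
unstructured maps score <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from gridcan.trajectory import Arena, Trajectory
from gridcan.dynamics import ActivityTrace

__all__ = [
    "RateMap", "GridFieldSet", "GridCellMetrics", "compute_rate_map",
    "detect_fields", "grid_score", "autocorrelogram", "information_rate",
    "sparsity", "summarize_metrics", "percent_change",
    "diagonal_phase_profile", "metrics_for_neurons",
]


@dataclass
class RateMap:
    """Occupancy-normalized spatial activity map of one neuron.

    ``values``: raw rate per pixel (nan on invalid pixels);
    ``occupancy``: visit probability per pixel (sums to 1 over valid pixels);
    ``valid``: in-arena and visited;
    ``in_arena``: the geometric support of the map;
    ``smoothed``: mask-renormalized Gaussian smoothing of the visited pixels,
    defined over the whole in-arena support -- unvisited holes left by short
    runs are interpolated from their smoothed neighborhood, so that rotation
    comparisons and field detection see contiguous support.
    """

    values: np.ndarray
    occupancy: np.ndarray
    valid: np.ndarray
    smoothed: np.ndarray
    in_arena: np.ndarray | None = None
    arena: Arena | None = None
    sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if self.in_arena is None:
            self.in_arena = self.valid

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        occupancy: np.ndarray | None = None,
        valid: np.ndarray | None = None,
        sigma_px: float = 2.0,
        arena: Arena | None = None,
    ) -> "RateMap":
        """Wrap a synthetic rate array (uniform occupancy unless given)."""
        values = np.asarray(values, dtype=float)
        if valid is None:
            valid = np.isfinite(values)
        if occupancy is None:
            occupancy = valid / valid.sum()
        smoothed = _masked_smooth(values, valid, sigma_px, support=valid)
        vals = np.where(valid, values, np.nan)
        return cls(values=vals, occupancy=occupancy, valid=valid,
                   smoothed=smoothed, in_arena=valid, arena=arena,
                   sigma_px=sigma_px)


def _masked_smooth(
    values: np.ndarray,
    valid: np.ndarray,
    sigma_px: float,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian smoothing with mask-renormalized weights (truncate 3 sigma).

    Defined on ``support`` (default: the valid mask); pixels whose smoothing
    window contains no valid data stay nan.
    """
    if support is None:
        support = valid
    if sigma_px <= 0:
        out = np.where(valid, values, np.nan)
        out[~support] = np.nan
        return out
    v = np.where(valid, values, 0.0)
    num = ndimage.gaussian_filter(v, sigma_px, truncate=3.0)
    den = ndimage.gaussian_filter(valid.astype(float), sigma_px, truncate=3.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 1e-9, num / den, np.nan)
    sm[~support] = np.nan
    return sm


def compute_rate_map(
    trace: ActivityTrace,
    neuron_index: int,
    traj: Trajectory,
    arena: Arena | None = None,
    n_pixels: int = 100,
    sigma_px: float = 2.0,
) -> RateMap:
    """Bin one neuron's activity over the trajectory into a rate map."""
    if arena is None:
        arena = traj.arena
    if arena is None:
        raise ValueError("arena required (not attached to trajectory)")
    pos = traj.positions[:: trace.stride]
    if len(pos) != trace.n_samples:
        pos = pos[: trace.n_samples]
    if len(pos) == 0:
        raise ValueError("empty trajectory")
    act = np.asarray(trace.S[:, neuron_index], dtype=float)

    px = arena.extent / n_pixels
    ix = np.clip((pos[:, 0] / px).astype(int), 0, n_pixels - 1)
    iy = np.clip((pos[:, 1] / px).astype(int), 0, n_pixels - 1)
    flat = ix * n_pixels + iy
    counts = np.bincount(flat, minlength=n_pixels * n_pixels).astype(float)
    sums = np.bincount(flat, weights=act, minlength=n_pixels * n_pixels)
    counts = counts.reshape(n_pixels, n_pixels)
    sums = sums.reshape(n_pixels, n_pixels)

    centers = (np.arange(n_pixels) + 0.5) * px
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    in_arena = np.asarray(arena.contains(cx, cy))
    valid = (counts > 0) & in_arena

    occupancy = np.where(valid, counts, 0.0)
    occupancy /= occupancy.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = sums / counts
    rate[~valid] = np.nan
    smoothed = _masked_smooth(rate, valid, sigma_px, support=in_arena)
    return RateMap(values=rate, occupancy=occupancy, valid=valid,
                   smoothed=smoothed, in_arena=in_arena, arena=arena,
                   sigma_px=sigma_px)


@dataclass
class GridFieldSet:
    """Detected firing fields: peak locations/heights and member pixels."""

    peaks: np.ndarray       # (F, 2) pixel coordinates (row, col)
    heights: np.ndarray     # (F,)
    labels: np.ndarray      # map-shaped; -1 outside fields, else field index
    areas: np.ndarray       # (F,) pixel counts

    @property
    def n_fields(self) -> int:
        return len(self.heights)


def detect_fields(
    rmap: RateMap, rel_threshold: float = 0.2, abs_peak_min: float = 0.1
) -> GridFieldSet:
    """Local maxima of the smoothed map and their 20%-of-peak firing fields.

    Maxima are 8-neighborhood dominant (plateaus merge to their centroid) and
    must reach ``abs_peak_min``.  Each field is the connected region around
    its peak holding at least ``rel_threshold`` of the peak height; pixels
    reachable from several peaks go to the nearest one.
    """
    support = np.isfinite(rmap.smoothed)
    sm = np.where(support, rmap.smoothed, -np.inf)
    footprint = np.ones((3, 3), dtype=bool)
    mx = ndimage.maximum_filter(sm, footprint=footprint, mode="constant",
                                cval=-np.inf)
    is_max = (sm == mx) & support & (sm >= abs_peak_min)
    # merge plateau maxima into centroids
    lab, n_pk = ndimage.label(is_max, structure=footprint)
    peaks, heights = [], []
    for p in range(1, n_pk + 1):
        rows, cols = np.nonzero(lab == p)
        r, c = int(round(rows.mean())), int(round(cols.mean()))
        peaks.append((r, c))
        heights.append(float(sm[rows[0], cols[0]]))
    labels = np.full(sm.shape, -1, dtype=int)
    if not peaks:
        return GridFieldSet(peaks=np.empty((0, 2), int), heights=np.empty(0),
                            labels=labels, areas=np.empty(0, int))

    order = np.argsort(heights)[::-1]
    peaks = [peaks[i] for i in order]
    heights = [heights[i] for i in order]

    claim_dist = np.full(sm.shape, np.inf)
    rr, cc = np.meshgrid(np.arange(sm.shape[0]), np.arange(sm.shape[1]),
                         indexing="ij")
    for f, ((pr, pc), h) in enumerate(zip(peaks, heights)):
        mask = support & (sm >= rel_threshold * h)
        comp_lab, _ = ndimage.label(mask, structure=footprint)
        comp = comp_lab == comp_lab[pr, pc]
        d = (rr - pr) ** 2 + (cc - pc) ** 2
        take = comp & (d < claim_dist)
        labels[take] = f
        claim_dist[take] = d[take]

    areas = np.array([(labels == f).sum() for f in range(len(peaks))])
    return GridFieldSet(peaks=np.array(peaks), heights=np.array(heights),
                        labels=labels, areas=areas)


def _rotate(map2d: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the array center, inverse-mapped bilinear resampling.

    Output samples whose source coordinate leaves the array extent are nan;
    nan inputs contaminate any interpolation cell that touches them.
    """
    n0, n1 = map2d.shape
    cy, cx = (n0 - 1) / 2.0, (n1 - 1) / 2.0
    th = np.deg2rad(angle)
    ii, jj = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    y = np.cos(th) * (ii - cy) + np.sin(th) * (jj - cx) + cy
    x = -np.sin(th) * (ii - cy) + np.cos(th) * (jj - cx) + cx
    inside = (y >= 0) & (y <= n0 - 1) & (x >= 0) & (x <= n1 - 1)
    y0 = np.clip(np.floor(y).astype(int), 0, n0 - 2)
    x0 = np.clip(np.floor(x).astype(int), 0, n1 - 2)
    fy = y - y0
    fx = x - x0
    with np.errstate(invalid="ignore"):
        out = (map2d[y0, x0] * (1 - fy) * (1 - fx)
               + map2d[y0 + 1, x0] * fy * (1 - fx)
               + map2d[y0, x0 + 1] * (1 - fy) * fx
               + map2d[y0 + 1, x0 + 1] * fy * fx)
    out[~inside] = np.nan
    return out


def autocorrelogram(
    values: np.ndarray, valid: np.ndarray, min_overlap: int = 20
) -> np.ndarray:
    """Masked spatial autocorrelogram (Pearson correlation at every lag).

    Only mutually valid pixel pairs contribute at each lag; lags with fewer
    than ``min_overlap`` overlapping pixels are nan.
    """
    from scipy.signal import fftconvolve

    M = np.where(valid, values, 0.0)
    V = valid.astype(float)

    def xcorr(a, b):
        return fftconvolve(a, b[::-1, ::-1], mode="full")

    n_ov = xcorr(V, V)
    sx = xcorr(M, V)
    sy = xcorr(V, M)
    sxx = xcorr(M * M, V)
    syy = xcorr(V, M * M)
    sxy = xcorr(M, M)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n_ov * sxy - sx * sy
        den = np.sqrt(np.maximum(n_ov * sxx - sx**2, 0.0)) * \
            np.sqrt(np.maximum(n_ov * syy - sy**2, 0.0))
        ac = num / den
    ac[np.round(n_ov) < min_overlap] = np.nan
    return ac


def grid_score(
    rmap: RateMap,
    rotations=(30, 60, 90, 120, 150),
    min_valid_fraction: float = 0.10,
) -> float:
    """Rotational-symmetry grid score of the smoothed map.

    SAC_phi is the Pearson correlation between the map's spatial
    autocorrelogram and the autocorrelogram rotated by phi degrees about its
    (centered) origin, over lags valid in both.  Working on the
    autocorrelogram rather than the raw map makes the score independent of
    where the firing lattice happens to sit relative to the arena center.
    Zero-variance (flat) maps score 0 by convention.
    """
    support = np.isfinite(rmap.smoothed)
    sm = np.where(support, rmap.smoothed, 0.0)
    if support.mean() < min_valid_fraction:
        raise ValueError("too few valid pixels for grid score")
    if np.ptp(sm[support]) == 0:
        return 0.0

    ac = autocorrelogram(sm, support)
    sacs = {}
    for phi in rotations:
        rot = _rotate(ac, phi)
        both = np.isfinite(ac) & np.isfinite(rot)
        if both.sum() < min_valid_fraction * support.size:
            raise ValueError(f"insufficient overlap after {phi} deg rotation")
        a = ac[both]
        b = rot[both]
        if a.std() == 0 or b.std() == 0:
            sacs[phi] = 0.0
        else:
            sacs[phi] = float(np.corrcoef(a, b)[0, 1])
    return min(sacs[60], sacs[120]) - max(sacs[30], sacs[90], sacs[150])


def information_rate(rmap: RateMap) -> float:
    """Skaggs spatial information rate, bits/s: sum_m p_m mu_m log2(mu_m/mu)."""
    p = rmap.occupancy[rmap.valid]
    mu_m = rmap.values[rmap.valid]
    mu = float(np.sum(p * mu_m))
    if mu <= 0:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = p * mu_m * np.log2(mu_m / mu)
    return float(np.nansum(np.where(mu_m > 0, terms, 0.0)))


def sparsity(rmap: RateMap) -> float:
    """Square mean rate over mean square rate; 1 = uniform, ->0 selective."""
    p = rmap.occupancy[rmap.valid]
    mu_m = rmap.values[rmap.valid]
    mu = float(np.sum(p * mu_m))
    denom = float(np.sum(p * mu_m**2))
    if denom == 0:
        return float("nan")
    return mu**2 / denom


@dataclass
class GridCellMetrics:
    """The eight per-neuron grid measurements."""

    grid_score: float
    avg_rate: float
    peak_rate: float
    n_fields: int
    mean_field_size: float       # pixels
    avg_spacing: float           # pixels (nan when < 2 fields)
    info_rate: float             # bits/s
    sparsity: float


def summarize_metrics(
    rmap: RateMap,
    fields: GridFieldSet | None = None,
    spacing_mode: str = "all_pairs",
) -> GridCellMetrics:
    """Assemble the eight grid measurements for one rate map.

    ``spacing_mode='all_pairs'`` averages every pairwise peak distance (the
    literal definition); ``'nearest_neighbor'`` averages each peak's distance
    to its nearest neighbor, which does not inflate with many fields.
    """
    if fields is None:
        fields = detect_fields(rmap)
    sm = rmap.smoothed[np.isfinite(rmap.smoothed)]
    avg_rate = float(np.mean(sm))
    peak_rate = float(np.max(sm))
    nf = fields.n_fields
    mean_size = float(fields.areas.sum() / nf) if nf else 0.0
    if nf >= 2:
        pk = fields.peaks.astype(float)
        d = np.sqrt(((pk[:, None, :] - pk[None, :, :]) ** 2).sum(-1))
        iu = np.triu_indices(nf, 1)
        if spacing_mode == "all_pairs":
            spacing = float(d[iu].mean())
        elif spacing_mode == "nearest_neighbor":
            np.fill_diagonal(d, np.inf)
            spacing = float(d.min(axis=1).mean())
        else:
            raise ValueError(f"unknown spacing_mode {spacing_mode!r}")
    else:
        spacing = float("nan")
    try:
        gs = grid_score(rmap)
    except ValueError:
        gs = float("nan")
    return GridCellMetrics(
        grid_score=gs, avg_rate=avg_rate, peak_rate=peak_rate, n_fields=nf,
        mean_field_size=mean_size, avg_spacing=spacing,
        info_rate=information_rate(rmap), sparsity=sparsity(rmap),
    )


def percent_change(metric_het, metric_homo):
    """100 * (het - homo) / |homo|; nan where the reference is zero."""
    het = np.asarray(metric_het, dtype=float)
    homo = np.asarray(metric_homo, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = 100.0 * (het - homo) / np.abs(homo)
    pc = np.where(homo == 0, np.nan, pc)
    if pc.ndim == 0:
        return float(pc)
    return pc


def diagonal_phase_profile(rmap: RateMap) -> np.ndarray:
    """(activity, spatial derivative) along the main diagonal of the map.

    The orbit closes for spatially periodic activity and opens up when
    periodicity is lost, making it a quick visual stability check.
    """
    n = rmap.n_pixels
    if rmap.smoothed.shape[0] != rmap.smoothed.shape[1]:
        raise ValueError("diagonal profile requires a square pixel grid")
    diag = np.array([rmap.smoothed[i, i] for i in range(n)])
    diag = np.nan_to_num(diag, nan=0.0)
    deriv = np.gradient(diag)
    return np.column_stack([diag, deriv])


def metrics_for_neurons(
    trace: ActivityTrace,
    traj: Trajectory,
    neuron_indices,
    arena: Arena | None = None,
    n_pixels: int = 100,
    sigma_px: float = 2.0,
) -> dict:
    """Grid metrics for a set of neurons; returns arrays keyed by metric."""
    rows = {k: [] for k in ("grid_score", "avg_rate", "peak_rate", "n_fields",
                            "mean_field_size", "avg_spacing", "info_rate",
                            "sparsity")}
    for i in neuron_indices:
        rm = compute_rate_map(trace, i, traj, arena=arena,
                              n_pixels=n_pixels, sigma_px=sigma_px)
        m = summarize_metrics(rm)
        for k in rows:
            rows[k].append(getattr(m, k))
    return {k: np.array(v, dtype=float) for k, v in rows.items()}
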