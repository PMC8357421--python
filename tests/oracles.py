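"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the library code paths they check: the
autocorrelogram is accumulated lag by lag with explicit slicing, and the
rotation resamples with hand-written inverse-mapped bilinear interpolation.
"""

from __future__ import annotations

import numpy as np


def brute_autocorrelogram(values: np.ndarray, valid: np.ndarray,
                          min_overlap: int = 20) -> np.ndarray:
    """Pearson correlation at every integer lag, by explicit shifting."""
    n0, n1 = values.shape
    M = np.where(valid, values, 0.0)
    V = valid.astype(float)
    out = np.full((2 * n0 - 1, 2 * n1 - 1), np.nan)
    for dr in range(-(n0 - 1), n0):
        for dc in range(-(n1 - 1), n1):
            r0a, r1a = max(0, dr), min(n0, n0 + dr)
            r0b, r1b = max(0, -dr), min(n0, n0 - dr)
            c0a, c1a = max(0, dc), min(n1, n1 + dc)
            c0b, c1b = max(0, -dc), min(n1, n1 - dc)
            a = M[r0a:r1a, c0a:c1a]
            b = M[r0b:r1b, c0b:c1b]
            va = V[r0a:r1a, c0a:c1a]
            vb = V[r0b:r1b, c0b:c1b]
            w = va * vb
            n = w.sum()
            if n < min_overlap:
                continue
            sx = (a * w).sum()
            sy = (b * w).sum()
            sxx = (a * a * w).sum()
            syy = (b * b * w).sum()
            sxy = (a * b * w).sum()
            den = np.sqrt(max(n * sxx - sx**2, 0.0)) * \
                np.sqrt(max(n * syy - sy**2, 0.0))
            if den > 0:
                out[dr + n0 - 1, dc + n1 - 1] = (n * sxy - sx * sy) / den
    return out


def brute_rotate_bilinear(a: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the array center with inverse-mapped bilinear sampling;
    samples touching the outside or a nan are nan."""
    n0, n1 = a.shape
    cy, cx = (n0 - 1) / 2.0, (n1 - 1) / 2.0
    th = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(th), np.sin(th)
    out = np.full_like(a, np.nan, dtype=float)
    for i in range(n0):
        for j in range(n1):
            # inverse rotation of the output coordinate
            y = cos_t * (i - cy) + sin_t * (j - cx) + cy
            x = -sin_t * (i - cy) + cos_t * (j - cx) + cx
            if not (0 <= y <= n0 - 1 and 0 <= x <= n1 - 1):
                continue
            y0 = min(max(int(np.floor(y)), 0), n0 - 2)
            x0 = min(max(int(np.floor(x)), 0), n1 - 2)
            fy, fx = y - y0, x - x0
            out[i, j] = (a[y0, x0] * (1 - fy) * (1 - fx)
                         + a[y0 + 1, x0] * fy * (1 - fx)
                         + a[y0, x0 + 1] * (1 - fy) * fx
                         + a[y0 + 1, x0 + 1] * fy * fx)
    return out


def brute_grid_score(values: np.ndarray, valid: np.ndarray) -> float:
    """Grid score by brute-force autocorrelogram rotation correlation."""
    ac = brute_autocorrelogram(values, valid)
    sacs = {}
    for phi in (30, 60, 90, 120, 150):
        rot = brute_rotate_bilinear(ac, phi)
        both = np.isfinite(ac) & np.isfinite(rot)
        a, b = ac[both], rot[both]
        sacs[phi] = float(np.corrcoef(a, b)[0, 1])
    return min(sacs[60], sacs[120]) - max(sacs[30], sacs[90], sacs[150])


def hexagonal_map(spacing: float, n_px: int = 60, sigma: float | None = None,
                  phase=(0.0, 0.0), angle: float = 0.0):
    """Synthetic triangular-lattice bump map on a circular support."""
    if sigma is None:
        sigma = spacing / 5.0
    a1 = spacing * np.array([np.cos(angle), np.sin(angle)])
    a2 = spacing * np.array([np.cos(angle + np.pi / 3),
                             np.sin(angle + np.pi / 3)])
    yy, xx = np.meshgrid(np.arange(n_px), np.arange(n_px), indexing="ij")
    m = np.zeros((n_px, n_px))
    reach = int(np.ceil(2 * n_px / spacing)) + 1
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            p = np.asarray(phase) + i * a1 + j * a2 + n_px / 2.0
            if -3 * sigma - spacing < p[0] < n_px + 3 * sigma + spacing and \
               -3 * sigma - spacing < p[1] < n_px + 3 * sigma + spacing:
                m += np.exp(-((xx - p[0]) ** 2 + (yy - p[1]) ** 2)
                            / (2 * sigma**2))
    circ = (xx - n_px / 2) ** 2 + (yy - n_px / 2) ** 2 <= (n_px / 2) ** 2
    return m, circ


def square_map(spacing: float, n_px: int = 60, sigma: float | None = None,
               phase=(0.0, 0.0)):
    """Synthetic square-lattice bump map on a circular support."""
    if sigma is None:
        sigma = spacing / 5.0
    yy, xx = np.meshgrid(np.arange(n_px), np.arange(n_px), indexing="ij")
    m = np.zeros((n_px, n_px))
    reach = int(np.ceil(n_px / spacing)) + 1
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            p = (phase[0] + i * spacing, phase[1] + j * spacing)
            m += np.exp(-((xx - p[0] - n_px / 2) ** 2
                          + (yy - p[1] - n_px / 2) ** 2) / (2 * sigma**2))
    circ = (xx - n_px / 2) ** 2 + (yy - n_px / 2) ** 2 <= (n_px / 2) ** 2
    return m, circ
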