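"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately use different algorithms from the package:

* median outlier test by explicit per-pixel loops;
* h-minima by iterated reconstruction-by-erosion to a fixpoint plus a
  plateau-flood regional-minima search;
* prominence by exhaustive level-set scanning with connected components;
* polynomial least squares via the normal equations.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_STRUCT8 = np.ones((3, 3), dtype=bool)


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                offs.append((dy, dx))
    return offs


def median_outlier_reference(img: np.ndarray, radius: int, threshold: float) -> np.ndarray:
    """Bright-outlier removal with explicit loops and edge replication."""
    ny, nx = img.shape
    offs = disk_offsets(radius)
    out = img.astype(np.float64).copy()
    for y in range(ny):
        for x in range(nx):
            vals = []
            for dy, dx in offs:
                yy = min(max(y + dy, 0), ny - 1)
                xx = min(max(x + dx, 0), nx - 1)
                vals.append(float(img[yy, xx]))
            med = float(np.median(vals))
            if float(img[y, x]) - med > threshold:
                out[y, x] = med
    return out


def reconstruction_by_erosion(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Iterate geodesic erosion of marker above mask until the fixpoint."""
    rec = marker.astype(np.float64).copy()
    while True:
        eroded = ndimage.grey_erosion(rec, footprint=_STRUCT8, mode="nearest")
        nxt = np.maximum(eroded, mask)
        if np.array_equal(nxt, rec):
            return rec
        rec = nxt


def hminima_peaks_reference(img: np.ndarray, h: float) -> list[tuple[int, int, float]]:
    """Surviving minima after h-minima suppression, one per plateau.

    A minimum survives when its dynamic (climb needed to reach strictly
    deeper terrain) is at least h: pixels where the erosion-reconstruction
    of (image + h) exceeds the image by >= h. Returns (y, x, value) of the
    representative pixel (deepest value, ties smallest (y, x)) per
    8-connected surviving region, mirroring the package's representative
    rule.
    """
    rec = reconstruction_by_erosion(img + h, img)
    mask = rec - img >= h
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    peaks = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        vals = img[ys, xs]
        order = np.lexsort((xs, ys, vals))
        peaks.append((int(ys[order[0]]), int(xs[order[0]]), float(vals[order[0]])))
    return sorted(peaks)


def prominence_reference(
    values: np.ndarray, valid: np.ndarray, peaks: list[tuple[int, int]]
) -> list[float]:
    """Exhaustive level-set prominence for negative peaks.

    For peak p with value v, scan every distinct level L >= v; at the
    first L where the 8-connected component of {value <= L} containing p
    holds a pixel lexicographically deeper than p — value < v, or equal
    value at smaller (y, x) — the prominence is min(L, 0) - v. A peak
    whose component never meets deeper terrain gets the zero reference:
    prominence = -v.
    """
    v = np.asarray(values, dtype=np.float64)
    levels = np.unique(v[valid])
    out = []
    for (py, px) in peaks:
        pv = v[py, px]
        key = (pv, py, px)
        prom = -pv
        for L in levels[levels >= pv]:
            mask = valid & (v <= L)
            lab, _ = ndimage.label(mask, structure=_STRUCT8)
            comp = lab == lab[py, px]
            ys, xs = np.nonzero(comp)
            found = False
            for yy, xx, vv in zip(ys, xs, v[ys, xs]):
                if (vv, yy, xx) < key:
                    found = True
                    break
            if found:
                prom = min(float(L), 0.0) - pv
                break
        out.append(float(prom))
    return out


def lstsq_normal_equations(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least squares via the normal equations (independent of lstsq)."""
    return np.linalg.solve(A.T @ A, A.T @ b)
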