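"""Cavity detection and 2-D topographic prominence on the penetration map.

Cavities dug by migrating cells are negative peaks of the mode-zeroed
penetration map. Detection uses the h-minima transform (suppressing local
minima whose dynamic relative to their surroundings is below a floor h,
5 µm by default) followed by an absolute-depth filter at the same floor,
so every reported cavity is at least h µm deep in both senses.

The prominence of a negative peak is the vertical distance between its
minimum and its key level: the lowest flooding level at which its basin
connects (8-connectivity) to a basin holding a strictly deeper minimum.
The key level is capped at the zero plane — after mode zeroing the
undisturbed surface sits at 0, and an isolated pit in a flat surface has
prominence equal to its depth. Consequently 0 < prominence <= depth for
every reported peak. Ties in depth are broken deterministically: the peak
earlier in (descending depth, then (y, x)) order counts as the deeper one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import h_minima as _h_minima

from .errors import EmptyMaskError, StalePeaksError
from .surface import PenetrationMap

_CONNECTIVITY = 8  # in-plane neighbourhood, fixed by design
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Peak:
    """One detected cavity (negative peak)."""

    x_px: int
    y_px: int
    depth_um: float
    prominence_um: float  # NaN until compute_prominences has run
    basin_area_px: int

    def sort_key(self) -> tuple:
        return (-self.depth_um, self.y_px, self.x_px)


@dataclass
class PeakSet:
    """Detected cavities with provenance.

    ``dx``/``dy`` carry the pixel spacing so tables can report µm
    coordinates. Ordering is deterministic: descending depth, then (y, x).
    """

    peaks: list[Peak]
    h_floor_um: float
    dx: float = 1.0
    dy: float = 1.0
    source: dict = field(default_factory=dict)

    def ordered(self) -> list[Peak]:
        return sorted(self.peaks, key=Peak.sort_key)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def depths_um(self) -> np.ndarray:
        return np.array([p.depth_um for p in self.ordered()], dtype=float)

    @property
    def prominences_um(self) -> np.ndarray:
        return np.array([p.prominence_um for p in self.ordered()], dtype=float)


@dataclass(frozen=True)
class Histogram:
    """Fixed-width histogram: ``counts[i]`` covers ``[edges[i], edges[i+1])``
    (last bin closed)."""

    bin_edges_um: np.ndarray
    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


def detect_negative_peaks(pen: PenetrationMap, h_floor_um: float = 5.0) -> PeakSet:
    """Find cavities at least ``h_floor_um`` deep.

    The h-minima transform with ``h = h_floor_um`` is applied to the valid
    region (invalid pixels filled with a value above every valid one, so
    they are never minima and never connect basins). Surviving minima
    plateaus are labelled with 8-connectivity; each label yields one peak
    at its deepest pixel (ties: smallest (y, x)). Peaks shallower than the
    floor in absolute value (relative to the zero plane) are discarded.
    """
    if h_floor_um <= 0:
        raise ValueError("h_floor_um must be > 0")
    v = np.asarray(pen.value_um, dtype=np.float64)
    valid = pen.valid.mask & np.isfinite(v)
    if not valid.any():
        raise EmptyMaskError("penetration map has no valid pixel")
    fill = float(v[valid].max()) + 2.0 * h_floor_um + 1.0
    img = np.where(valid, v, fill)
    minima = _h_minima(img, h_floor_um) > 0
    minima &= valid
    labels, n_labels = ndimage.label(minima, structure=_STRUCT8)
    peaks: list[Peak] = []
    for lab in range(1, n_labels + 1):
        ys, xs = np.nonzero(labels == lab)
        vals = v[ys, xs]
        order = np.lexsort((xs, ys, vals))
        iy, ix, vmin = int(ys[order[0]]), int(xs[order[0]]), float(vals[order[0]])
        if vmin <= -h_floor_um:
            peaks.append(
                Peak(x_px=ix, y_px=iy, depth_um=-vmin, prominence_um=float("nan"), basin_area_px=len(ys))
            )
    peaks.sort(key=Peak.sort_key)
    return PeakSet(
        peaks=peaks,
        h_floor_um=float(h_floor_um),
        dx=pen.geometry.dx,
        dy=pen.geometry.dy,
        source=dict(pen.source),
    )


class _UnionFind:
    __slots__ = ("parent", "min_key", "peak_idx")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.min_key: list[tuple] = [()] * n
        self.peak_idx: list[int] = [-1] * n

    def find(self, a: int) -> int:
        p = self.parent
        root = a
        while p[root] != root:
            root = p[root]
        while p[a] != root:
            p[a], a = root, p[a]
        return root


def compute_prominences(pen: PenetrationMap, peaks: PeakSet) -> PeakSet:
    """Fill in topographic prominences by flooding from the minima upward.

    Valid pixels are processed in increasing (value, y, x) order with a
    union-find over 8-connected components (level-set flooding). When two
    basins meet at level L, the one whose minimum is shallower — larger
    (value, y, x) — dies; if it held a detected peak with minimum value v,
    that peak's prominence is ``min(L, 0) - v``. A basin that never meets a
    deeper one keeps the zero reference plane: prominence ``= -v = depth``.
    """
    v = np.asarray(pen.value_um, dtype=np.float64)
    valid = pen.valid.mask & np.isfinite(v)
    ny, nx = v.shape

    ordered_peaks = peaks.ordered()
    peak_at: dict[tuple[int, int], int] = {}
    for i, p in enumerate(ordered_peaks):
        if not (0 <= p.y_px < ny and 0 <= p.x_px < nx) or not valid[p.y_px, p.x_px]:
            raise StalePeaksError(f"peak at ({p.y_px}, {p.x_px}) not inside the valid map")
        if not np.isclose(v[p.y_px, p.x_px], -p.depth_um, atol=1e-9):
            raise StalePeaksError(
                f"peak at ({p.y_px}, {p.x_px}) value {v[p.y_px, p.x_px]} != -depth {-p.depth_um}"
            )
        peak_at[(p.y_px, p.x_px)] = i

    ys, xs = np.nonzero(valid)
    vals = v[ys, xs]
    order = np.lexsort((xs, ys, vals))
    ys, xs, vals = ys[order], xs[order], vals[order]

    idx_of = np.full((ny, nx), -1, dtype=np.int64)
    idx_of[ys, xs] = np.arange(ys.size)

    uf = _UnionFind(ys.size)
    active = np.zeros(ys.size, dtype=bool)
    prominence = [float("nan")] * len(ordered_peaks)

    neighbours = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for k in range(ys.size):
        y, x, val = int(ys[k]), int(xs[k]), float(vals[k])
        active[k] = True
        uf.min_key[k] = (val, y, x)
        uf.peak_idx[k] = peak_at.get((y, x), -1)
        for dy_, dx_ in neighbours:
            yn, xn = y + dy_, x + dx_
            if 0 <= yn < ny and 0 <= xn < nx:
                j = idx_of[yn, xn]
                if j >= 0 and active[j]:
                    ra, rb = uf.find(k), uf.find(j)
                    if ra == rb:
                        continue
                    # deeper basin = lexicographically smaller (value, y, x)
                    if uf.min_key[ra] <= uf.min_key[rb]:
                        deep, shallow = ra, rb
                    else:
                        deep, shallow = rb, ra
                    dead_peak = uf.peak_idx[shallow]
                    if dead_peak >= 0:
                        vmin = uf.min_key[shallow][0]
                        prominence[dead_peak] = min(val, 0.0) - vmin
                    uf.parent[shallow] = deep
    # basins that survived the flood: reference level is the zero plane
    seen_roots = set()
    for k in range(ys.size):
        r = uf.find(k)
        if r in seen_roots:
            continue
        seen_roots.add(r)
        if uf.peak_idx[r] >= 0:
            prominence[uf.peak_idx[r]] = -uf.min_key[r][0]

    new_peaks = [replace(p, prominence_um=float(prominence[i])) for i, p in enumerate(ordered_peaks)]
    return PeakSet(
        peaks=new_peaks,
        h_floor_um=peaks.h_floor_um,
        dx=peaks.dx,
        dy=peaks.dy,
        source=dict(peaks.source),
    )


def histogram_values(
    values, bin_um: float, value_range: tuple[float, float] | None = None
) -> Histogram:
    """Fixed-width histogram of µm values.

    Bins are left-closed right-open with the last bin closed; counts sum to
    the number of finite inputs within the range. An empty input yields an
    empty histogram (zero bins).
    """
    if bin_um <= 0:
        raise ValueError("bin_um must be > 0")
    vals = np.asarray(values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return Histogram(bin_edges_um=np.array([]), counts=np.array([], dtype=np.int64))
    if value_range is None:
        lo = np.floor(vals.min() / bin_um) * bin_um
        hi = np.ceil(vals.max() / bin_um) * bin_um
        if hi <= lo:
            hi = lo + bin_um
    else:
        lo, hi = float(value_range[0]), float(value_range[1])
    n_bins = max(int(np.ceil((hi - lo) / bin_um - 1e-9)), 1)
    edges = lo + bin_um * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return Histogram(bin_edges_um=edges, counts=counts.astype(np.int64))
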