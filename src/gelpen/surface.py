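"""Gel-surface extraction, reference-surface fitting, and the penetration map.

The gel channel of a two-photon stack is dark above the hydrogel and bright
inside it. The observed surface is located per pixel column as the z
position where the axial intensity profile first crosses the midpoint
between its minimum and maximum (half-maximum crossing, scanning from the
top, with linear interpolation between slices). A bivariate polynomial of
total degree 3 fitted to that depth map estimates the undisturbed surface;
the signed difference between fit and observation, Gaussian-smoothed and
shifted so its histogram mode sits at zero, is the penetration map whose
negative peaks are the cell-made cavities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateFitError, EmptyMaskError, SurfaceError
from .preprocess import ValidityMask
from .stack_io import VoxelGeometry

logger = logging.getLogger(__name__)

#: Monomial exponents (i on x, j on y) of the total-degree-<=3 basis,
#: ordered by total degree then descending x power. 10 terms.
POLY_EXPONENTS: tuple[tuple[int, int], ...] = (
    (0, 0),
    (1, 0),
    (0, 1),
    (2, 0),
    (1, 1),
    (0, 2),
    (3, 0),
    (2, 1),
    (1, 2),
    (0, 3),
)


def normalized_coords(ny: int, nx: int) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float, float]]:
    """Pixel-index grids affinely mapped to [-1, 1] for fit conditioning.

    Returns ``(xn, yn, norm)`` where ``norm = (cx, sx, cy, sy)`` and
    ``xn = (x - cx) / sx``. A degenerate axis (single pixel) maps to 0.
    """
    cx, sx = (nx - 1) / 2.0, max((nx - 1) / 2.0, 1.0)
    cy, sy = (ny - 1) / 2.0, max((ny - 1) / 2.0, 1.0)
    yy, xx = np.mgrid[0:ny, 0:nx]
    return (xx - cx) / sx, (yy - cy) / sy, (cx, sx, cy, sy)


def polynomial_design(xn: np.ndarray, yn: np.ndarray) -> np.ndarray:
    """Design matrix of the 10 monomials x^i y^j (i + j <= 3)."""
    xn = np.asarray(xn, dtype=np.float64).ravel()
    yn = np.asarray(yn, dtype=np.float64).ravel()
    return np.stack([xn**i * yn**j for i, j in POLY_EXPONENTS], axis=1)


@dataclass
class DepthMap:
    """Per-(x, y) gel-surface z position in µm from the top of the stack.

    Invalid pixels carry NaN and are excluded from every statistic.
    """

    z_um: np.ndarray
    valid: ValidityMask
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=np.float64)
        if self.z_um.shape != self.valid.mask.shape:
            raise SurfaceError("depth map and validity mask shapes differ")
        ok = self.valid.mask
        vals = self.z_um[ok]
        if vals.size and (np.any(~np.isfinite(vals)) or vals.min() < 0 or vals.max() > self.geometry.depth_extent_um + 1e-9):
            raise SurfaceError("valid depth values must lie within [0, (nz-1)*dz]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_um.shape


@dataclass
class SurfaceModel:
    """Fitted total-degree-3 bivariate polynomial reference surface.

    ``coeffs[k]`` multiplies ``x^i * y^j`` with ``(i, j) = POLY_EXPONENTS[k]``
    in normalized coordinates ``xn = (x - cx)/sx``, ``yn = (y - cy)/sy``
    where ``norm = (cx, sx, cy, sy)``.
    """

    coeffs: np.ndarray
    norm: tuple[float, float, float, float]
    rmse_um: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64).ravel()
        if self.coeffs.size != len(POLY_EXPONENTS):
            raise SurfaceError(f"expected {len(POLY_EXPONENTS)} coefficients, got {self.coeffs.size}")

    def evaluate(self, ny: int, nx: int) -> np.ndarray:
        """Evaluate P(x, y) on the full (ny, nx) pixel grid, in µm."""
        cx, sx, cy, sy = self.norm
        yy, xx = np.mgrid[0:ny, 0:nx]
        A = polynomial_design((xx - cx) / sx, (yy - cy) / sy)
        return (A @ self.coeffs).reshape(ny, nx)

    def to_dict(self) -> dict:
        return {
            "exponents": [list(e) for e in POLY_EXPONENTS],
            "coeffs_um": self.coeffs.tolist(),
            "norm_cx_sx_cy_sy": list(self.norm),
            "rmse_um": self.rmse_um,
        }


@dataclass
class PenetrationMap:
    """Signed deviation of the observed surface from the reference, in µm.

    Negative values are deeper than the reference (cavities). The map has
    been Gaussian-smoothed with ``sigma_um`` and shifted by its histogram
    mode (bin width ``bin_um``, zero-centred bins) so the undisturbed
    surface sits at 0.
    """

    value_um: np.ndarray
    valid: ValidityMask
    geometry: VoxelGeometry
    sigma_um: float
    mode_shift_um: float
    bin_um: float
    source: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.value_um.shape


def extract_surface(
    gel_volume: np.ndarray,
    geometry: VoxelGeometry,
    valid: ValidityMask,
    presmooth_sigma_px: float = 0.0,
) -> DepthMap:
    """Locate the gel surface per pixel column by half-maximum crossing.

    For each valid column the 1-D z profile is optionally Gaussian-smoothed
    (``presmooth_sigma_px`` in slices), then the surface is the smallest z
    at which the intensity first reaches ``(I_min + I_max) / 2`` scanning
    from the top, linearly interpolated between the bracketing slices and
    converted to µm with ``dz``. Flat columns (I_max == I_min) are marked
    invalid with a warning. The result is invariant to affine intensity
    rescaling a*I + b with a > 0.
    """
    vol = np.asarray(gel_volume, dtype=np.float64)
    if vol.shape != geometry.shape:
        raise SurfaceError(f"volume shape {vol.shape} does not match geometry {geometry.shape}")
    if presmooth_sigma_px < 0:
        raise ValueError("presmooth_sigma_px must be >= 0")
    if presmooth_sigma_px > 0:
        vol = ndimage.gaussian_filter1d(vol, presmooth_sigma_px, axis=0, mode="nearest")

    imax = vol.max(axis=0)
    imin = vol.min(axis=0)
    half = 0.5 * (imin + imax)
    flat = imax == imin

    # first slice whose intensity reaches the half level
    ge = vol >= half[np.newaxis]
    first = ge.argmax(axis=0)

    below_idx = np.maximum(first - 1, 0)
    take = np.take_along_axis
    i_lo = take(vol, below_idx[np.newaxis], axis=0)[0]
    i_hi = take(vol, first[np.newaxis], axis=0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (half - i_lo) / (i_hi - i_lo)
    z_idx = np.where(first == 0, 0.0, below_idx + frac)
    z_um = z_idx * geometry.dz

    mask = valid.mask & ~flat
    n_flat = int((valid.mask & flat).sum())
    if n_flat:
        logger.warning("extract_surface: %d valid columns are flat; marked invalid", n_flat)
    if not mask.any():
        raise EmptyMaskError("no valid, non-flat columns; cannot extract a surface")
    z_um = np.where(mask, z_um, np.nan)
    return DepthMap(z_um=z_um, valid=ValidityMask(mask), geometry=geometry)


def fit_reference_surface(depth: DepthMap) -> SurfaceModel:
    """Least-squares fit of the undisturbed-surface polynomial.

    Fits the total-degree-3 bivariate polynomial over valid pixels only,
    with (x, y) normalized to [-1, 1]. Reproduces exactly (to float
    tolerance) any depth map that is itself such a polynomial.
    """
    ny, nx = depth.shape
    mask = depth.valid.mask & np.isfinite(depth.z_um)
    n = int(mask.sum())
    if n < len(POLY_EXPONENTS):
        raise DegenerateFitError(f"need >= {len(POLY_EXPONENTS)} valid pixels, got {n}")
    xn, yn, norm = normalized_coords(ny, nx)
    A = polynomial_design(xn[mask], yn[mask])
    b = depth.z_um[mask]
    coeffs, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < len(POLY_EXPONENTS):
        raise DegenerateFitError(
            f"rank-deficient design (rank {rank} < {len(POLY_EXPONENTS)}): degenerate mask geometry"
        )
    resid = A @ coeffs - b
    rmse = float(np.sqrt(np.mean(resid**2)))
    return SurfaceModel(coeffs=coeffs, norm=norm, rmse_um=rmse)


def histogram_mode(values: np.ndarray, bin_um: float) -> float:
    """Mode of *values* by fixed-width histogram with zero-centred bins.

    Bin k covers ``[(k - 0.5) * bin_um, (k + 0.5) * bin_um)``; the mode is
    the centre of the most populated bin, ties resolved toward the centre
    nearest 0 (then the smaller centre). Anchoring the bins at zero makes
    the estimator exact on data already centred at zero.
    """
    if bin_um <= 0:
        raise ValueError("bin_um must be > 0")
    vals = np.asarray(values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyMaskError("cannot take the mode of an empty value set")
    k = np.floor(vals / bin_um + 0.5).astype(np.int64)
    uniq, counts = np.unique(k, return_counts=True)
    best = counts.max()
    cand = uniq[counts == best]
    centers = cand.astype(np.float64) * bin_um
    order = np.lexsort((centers, np.abs(centers)))
    return float(centers[order[0]])


def _normalized_gaussian(values: np.ndarray, mask: np.ndarray, sigma_yx_px: tuple[float, float]) -> np.ndarray:
    """Gaussian smoothing where invalid pixels neither contribute nor spread."""
    w = mask.astype(np.float64)
    num = ndimage.gaussian_filter(np.where(mask, values, 0.0), sigma=sigma_yx_px, mode="constant")
    den = ndimage.gaussian_filter(w, sigma=sigma_yx_px, mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(mask, out, np.nan)


def compute_penetration(
    depth: DepthMap,
    model: SurfaceModel,
    sigma_um: float = 2.0,
    bin_um: float = 1.0,
) -> PenetrationMap:
    """Penetration map: fitted reference minus observed depth, mode-zeroed.

    ``raw = P(x, y) - z_um(x, y)`` so cavities (larger observed z) are
    negative. The raw map is smoothed with a normalized Gaussian of scale
    ``sigma_um`` (converted to pixels via dy, dx; ``sigma_um = 0`` skips
    smoothing), then shifted by its histogram mode (bin ``bin_um``) which
    estimates the zero-depth level. Adding a constant to every depth value
    leaves the result unchanged (absorbed by the constant term of the fit).
    """
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    ny, nx = depth.shape
    mask = depth.valid.mask & np.isfinite(depth.z_um)
    if not mask.any():
        raise EmptyMaskError("empty valid mask in compute_penetration")
    ref = model.evaluate(ny, nx)
    raw = np.where(mask, ref - depth.z_um, np.nan)
    if sigma_um > 0:
        sigma_yx = (sigma_um / depth.geometry.dy, sigma_um / depth.geometry.dx)
        smoothed = _normalized_gaussian(raw, mask, sigma_yx)
    else:
        smoothed = raw
    mode = histogram_mode(smoothed[mask], bin_um)
    value = np.where(mask, smoothed - mode, np.nan)
    return PenetrationMap(
        value_um=value,
        valid=ValidityMask(mask),
        geometry=depth.geometry,
        sigma_um=float(sigma_um),
        mode_shift_um=float(mode),
        bin_um=float(bin_um),
    )
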