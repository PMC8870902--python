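"""Synthetic two-channel two-photon phantoms with exact ground truth.

The phantom emulates the imaging situation of a hydrogel scaffold colonised
by cells: a smooth undisturbed surface described by a total-degree-<=3
polynomial in µm; Gaussian-profile cavities ("pits") that add depth where
cells have digested the gel; a gel channel that is dark above the surface
and bright below it, with a logistic axial transition; a cell channel of
ellipsoidal blobs sitting inside the cavities; linear channel crosstalk;
additive Gaussian noise; optional radial vignetting; and sparse saturated
single-voxel speckle artifacts. Everything is deterministic given the seed,
and the analytic truth (cavity-free surface, true depth map, expected
peaks) is returned alongside the stack.

Presets draw pit depths from the depth distributions characteristic of the
dopamine-modified gel that supports migration — mean ± SD of (39, 18) and
(75, 30) µm for periodontal ligament cells at days 7 and 14, and (24, 9)
and (18, 8) µm for SH-SY5Y neuroblastoma cells — truncated below at the
5 µm detection floor (and above at 180 µm so pits stay inside the stack).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import GelpenError
from .preprocess import MixingMatrix, forward_mix
from .stack_io import CELL, GEL, MultiChannelStack, VoxelGeometry
from .surface import SurfaceModel, normalized_coords
from .topography import Peak, PeakSet

#: Default imaging geometry: ~0.3 x 0.3 mm field, 240 µm axial range.
DEFAULT_GEOMETRY = VoxelGeometry(nz=120, ny=256, nx=256, dz=2.0, dy=1.24, dx=1.24)

#: Gentle tilt + curvature of the undisturbed surface, µm, in normalized
#: coordinates (constant term = nominal surface depth below the stack top).
DEFAULT_SURFACE_COEFFS = (40.0, 3.0, -2.0, 1.5, 1.0, -1.2, 0.5, 0.3, -0.4, 0.2)

#: (mean, SD) of the cavity-depth distribution per preset, µm, plus the
#: pit and cell radii appropriate to the cell size (~30 µm PDLC, ~12 µm
#: SH-SY5Y).
PRESET_TABLE = {
    "pdlc_day7": {"depth_mu": 39.0, "depth_sd": 18.0, "pit_radius_um": 18.0, "cell_radius_um": 14.0},
    "pdlc_day14": {"depth_mu": 75.0, "depth_sd": 30.0, "pit_radius_um": 18.0, "cell_radius_um": 14.0},
    "shsy5y_day7": {"depth_mu": 24.0, "depth_sd": 9.0, "pit_radius_um": 12.0, "cell_radius_um": 6.0},
    "shsy5y_day14": {"depth_mu": 18.0, "depth_sd": 8.0, "pit_radius_um": 12.0, "cell_radius_um": 6.0},
}

DEPTH_FLOOR_UM = 5.0
DEPTH_CAP_UM = 180.0


@dataclass(frozen=True)
class Pit:
    """Gaussian depression added to the surface height field.

    Contributes ``depth_um * exp(-r^2 / (2 radius_um^2))`` of extra depth
    at in-plane distance r from the centre.
    """

    x_um: float
    y_um: float
    depth_um: float
    radius_um: float


@dataclass(frozen=True)
class CellBlob:
    """Spherical (in µm; ellipsoidal in voxels) bright blob in the cell channel."""

    x_um: float
    y_um: float
    z_um: float
    radius_um: float


@dataclass
class PhantomConfig:
    geometry: VoxelGeometry = DEFAULT_GEOMETRY
    surface_coeffs: tuple = DEFAULT_SURFACE_COEFFS
    pits: tuple[Pit, ...] = ()
    cells: tuple[CellBlob, ...] = ()
    axial_width_um: float = 2.0  # logistic transition width of the gel edge
    gel_level: float = 200.0
    cell_level: float = 180.0
    crosstalk: MixingMatrix = field(default_factory=MixingMatrix)
    noise_sd: float = 0.0
    n_speckles: int = 0
    speckle_level: float | None = None  # default: 4 x gel_level ("saturated")
    vignette_strength: float = 0.0  # 0 = off; intensity x (1 - s*(r/r_max)^2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axial_width_um <= 0:
            raise GelpenError("axial_width_um must be > 0")
        g = self.geometry
        for p in self.pits:
            if p.radius_um <= 0 or p.depth_um <= 0:
                raise GelpenError(f"pit radius and depth must be > 0: {p}")
            if not (0 <= p.x_um <= (g.nx - 1) * g.dx and 0 <= p.y_um <= (g.ny - 1) * g.dy):
                raise GelpenError(f"pit outside image bounds: {p}")

    @property
    def field_um(self) -> tuple[float, float]:
        g = self.geometry
        return ((g.ny - 1) * g.dy, (g.nx - 1) * g.dx)


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a generated phantom."""

    true_surface: "np.ndarray"  # cavity-free surface height, µm, (ny, nx)
    true_depth_map: "np.ndarray"  # surface with cavities, µm, (ny, nx)
    expected_peaks: PeakSet  # analytic depths; prominences only when separated
    separated: bool  # all pit pairs farther apart than 4 x (r_i + r_j)


def _surface_model(config: PhantomConfig) -> SurfaceModel:
    g = config.geometry
    _, _, norm = normalized_coords(g.ny, g.nx)
    return SurfaceModel(coeffs=np.asarray(config.surface_coeffs, dtype=float), norm=norm, rmse_um=0.0)


def surface_heights(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (cavity-free base, base + pit depressions) in µm, shape (ny, nx)."""
    g = config.geometry
    base = _surface_model(config).evaluate(g.ny, g.nx)
    yy, xx = np.mgrid[0 : g.ny, 0 : g.nx]
    x_um = xx * g.dx
    y_um = yy * g.dy
    total = base.copy()
    for p in config.pits:
        r2 = (x_um - p.x_um) ** 2 + (y_um - p.y_um) ** 2
        total += p.depth_um * np.exp(-r2 / (2.0 * p.radius_um**2))
    return base, total


def _pits_separated(pits: tuple[Pit, ...]) -> bool:
    for i, a in enumerate(pits):
        for b in pits[i + 1 :]:
            d = float(np.hypot(a.x_um - b.x_um, a.y_um - b.y_um))
            if d <= 4.0 * (a.radius_um + b.radius_um):
                return False
    return True


def _expected_peaks(config: PhantomConfig, base: np.ndarray, total: np.ndarray) -> tuple[PeakSet, bool]:
    g = config.geometry
    separated = _pits_separated(config.pits)
    peaks = []
    for p in config.pits:
        ix = int(round(p.x_um / g.dx))
        iy = int(round(p.y_um / g.dy))
        depth = float(total[iy, ix] - base[iy, ix])  # includes overlap of neighbours
        peaks.append(
            Peak(
                x_px=ix,
                y_px=iy,
                depth_um=depth,
                prominence_um=depth if separated else float("nan"),
                basin_area_px=0,
            )
        )
    peaks.sort(key=Peak.sort_key)
    ps = PeakSet(peaks=peaks, h_floor_um=0.0, dx=g.dx, dy=g.dy, source={"phantom_seed": config.seed})
    return ps, separated


def generate_phantom(config: PhantomConfig) -> tuple[MultiChannelStack, PhantomTruth]:
    """Render the phantom stack and its analytic truth.

    Gel channel: ``gel_level * logistic((z - s(x, y)) / width) * vignette``
    plus noise; cell channel: blobs plus noise; then the crosstalk matrix
    mixes the two channels, and speckles are written last as saturated
    single voxels in the observed gel channel.
    """
    g = config.geometry
    rng = np.random.default_rng(config.seed)
    base, total = surface_heights(config)

    z_um = (np.arange(g.nz, dtype=np.float32) * g.dz)[:, np.newaxis, np.newaxis]
    gel = config.gel_level * expit(
        (z_um - total.astype(np.float32)[np.newaxis]) / config.axial_width_um
    )

    if config.vignette_strength > 0:
        yy, xx = np.mgrid[0 : g.ny, 0 : g.nx]
        cy, cx = (g.ny - 1) / 2.0, (g.nx - 1) / 2.0
        r2 = ((yy - cy) * g.dy) ** 2 + ((xx - cx) * g.dx) ** 2
        falloff = 1.0 - config.vignette_strength * r2 / r2.max()
        gel *= np.clip(falloff, 0.0, None).astype(np.float32)[np.newaxis]

    cell = np.zeros_like(gel)
    for b in config.cells:
        # render each blob only inside its 4-sigma bounding box
        x0, x1 = _clip_range(b.x_um - 4 * b.radius_um, b.x_um + 4 * b.radius_um, g.dx, g.nx)
        y0, y1 = _clip_range(b.y_um - 4 * b.radius_um, b.y_um + 4 * b.radius_um, g.dy, g.ny)
        z0, z1 = _clip_range(b.z_um - 4 * b.radius_um, b.z_um + 4 * b.radius_um, g.dz, g.nz)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        xs = (np.arange(x0, x1, dtype=np.float32) * g.dx - b.x_um) ** 2
        ys = (np.arange(y0, y1, dtype=np.float32) * g.dy - b.y_um) ** 2
        zs = (np.arange(z0, z1, dtype=np.float32) * g.dz - b.z_um) ** 2
        d2 = zs[:, None, None] + ys[None, :, None] + xs[None, None, :]
        cell[z0:z1, y0:y1, x0:x1] += config.cell_level * np.exp(-d2 / (2.0 * b.radius_um**2))

    if config.noise_sd > 0:
        gel = gel + config.noise_sd * rng.standard_normal(gel.shape, dtype=np.float32)
        cell = cell + config.noise_sd * rng.standard_normal(cell.shape, dtype=np.float32)
    gel = np.clip(gel, 0.0, None)
    cell = np.clip(cell, 0.0, None)

    stack = MultiChannelStack(
        geometry=g,
        channels={"gel": gel, "cell": cell},
        channel_roles={GEL: "gel", CELL: "cell"},
    )
    observed = forward_mix(stack, config.crosstalk)

    if config.n_speckles > 0:
        level = config.speckle_level if config.speckle_level is not None else 4.0 * config.gel_level
        zs = rng.integers(0, g.nz, size=config.n_speckles)
        ys = rng.integers(0, g.ny, size=config.n_speckles)
        xs = rng.integers(0, g.nx, size=config.n_speckles)
        observed.channels["gel"][zs, ys, xs] = level

    expected, separated = _expected_peaks(config, base, total)
    truth = PhantomTruth(
        true_surface=base,
        true_depth_map=total,
        expected_peaks=expected,
        separated=separated,
    )
    return observed, truth


def _clip_range(lo_um: float, hi_um: float, spacing: float, n: int) -> tuple[int, int]:
    return max(int(np.floor(lo_um / spacing)), 0), min(int(np.ceil(hi_um / spacing)) + 1, n)


def _grid_pits(
    g: VoxelGeometry,
    depths: np.ndarray,
    radius_um: float,
    rng: np.random.Generator,
    jitter_um: float = 8.0,
) -> tuple[Pit, ...]:
    """Place len(depths) pits on a jittered square grid covering the field."""
    n = len(depths)
    side = int(np.ceil(np.sqrt(n)))
    fy, fx = (g.ny - 1) * g.dy, (g.nx - 1) * g.dx
    centers_x = (np.arange(side) + 0.5) / side * fx
    centers_y = (np.arange(side) + 0.5) / side * fy
    pits = []
    k = 0
    for cy in centers_y:
        for cx in centers_x:
            if k >= n:
                break
            jx, jy = rng.uniform(-jitter_um, jitter_um, size=2)
            pits.append(
                Pit(
                    x_um=float(np.clip(cx + jx, radius_um, fx - radius_um)),
                    y_um=float(np.clip(cy + jy, radius_um, fy - radius_um)),
                    depth_um=float(depths[k]),
                    radius_um=radius_um,
                )
            )
            k += 1
    return tuple(pits)


def truncated_normal_mean(
    mu: float, sd: float, lo: float = DEPTH_FLOOR_UM, hi: float = DEPTH_CAP_UM
) -> float:
    """Mean of N(mu, sd) truncated to [lo, hi] — the presets' true mean depth."""
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.mean(a, b, loc=mu, scale=sd))


def preset_configs(name: str, seed: int = 0, n_pits: int = 4) -> PhantomConfig:
    """Fully populated phantom config for a named study condition.

    ``flat_control`` has no pits or cells, emulating the gel compositions
    on which no cavity formation was observed. The other presets draw
    ``n_pits`` cavity depths from the condition's truncated normal depth
    distribution and place one cell blob inside each cavity. The default
    of 4 cavities per stack keeps the cavity footprint below ~10% of the
    field, consistent with the method's assumption that the relatively few
    cells disturb the surface shape only locally.
    """
    g = DEFAULT_GEOMETRY
    if name == "flat_control":
        return PhantomConfig(
            geometry=g,
            pits=(),
            cells=(),
            noise_sd=0.04 * 200.0,
            n_speckles=40,
            crosstalk=MixingMatrix(((1.0, 0.15), (0.08, 1.0))),
            seed=seed,
        )
    if name not in PRESET_TABLE:
        raise GelpenError(f"unknown preset {name!r}; choose from {sorted(PRESET_TABLE)} or 'flat_control'")
    p = PRESET_TABLE[name]
    rng = np.random.default_rng(seed)
    mu, sd = p["depth_mu"], p["depth_sd"]
    a, b = (DEPTH_FLOOR_UM - mu) / sd, (DEPTH_CAP_UM - mu) / sd
    depths = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n_pits, random_state=rng)
    pits = _grid_pits(g, depths, p["pit_radius_um"], rng)
    base, total = surface_heights(replace(PhantomConfig(geometry=g, seed=seed), pits=pits))
    cells = []
    for pit in pits:
        ix = int(round(pit.x_um / g.dx))
        iy = int(round(pit.y_um / g.dy))
        z_floor = float(total[iy, ix])
        cells.append(
            CellBlob(
                x_um=pit.x_um,
                y_um=pit.y_um,
                z_um=max(z_floor - p["cell_radius_um"], 0.0),
                radius_um=p["cell_radius_um"],
            )
        )
    return PhantomConfig(
        geometry=g,
        pits=pits,
        cells=tuple(cells),
        noise_sd=0.04 * 200.0,
        n_speckles=40,
        crosstalk=MixingMatrix(((1.0, 0.15), (0.08, 1.0))),
        seed=seed,
    )


def deep_pit_series_config(seed: int = 0) -> PhantomConfig:
    """Five well-separated pits spanning the observed depth range.

    Depths {10, 25, 50, 100, 150} µm — the largest matching the maximum
    penetration reported for periodontal ligament cells — on a 512x512
    field so the pits satisfy the separation rule (pairwise distance
    > 4 x (r_i + r_j)) and occupy a small enough area fraction that the
    reference fit is not pulled into the cavities, with 2% intensity noise.
    """
    g = VoxelGeometry(nz=120, ny=512, nx=512, dz=2.0, dy=1.24, dx=1.24)
    fy, fx = (g.ny - 1) * g.dy, (g.nx - 1) * g.dx
    r = 15.0
    margin = 110.0
    centres = [
        (margin, margin),
        (fx - margin, margin),
        (margin, fy - margin),
        (fx - margin, fy - margin),
        (fx / 2, fy / 2),
    ]
    depths = [10.0, 25.0, 50.0, 100.0, 150.0]
    pits = tuple(
        Pit(x_um=cx, y_um=cy, depth_um=d, radius_um=r) for (cx, cy), d in zip(centres, depths)
    )
    return PhantomConfig(
        geometry=g,
        pits=pits,
        noise_sd=0.02 * 200.0,
        n_speckles=40,
        crosstalk=MixingMatrix(((1.0, 0.15), (0.08, 1.0))),
        seed=seed,
    )
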