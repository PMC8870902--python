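"""Read/write multi-channel Z-stacks and tabular outputs.

Conventions used throughout the package:

* axis order ``(z, y, x)`` per channel; ``z = 0`` is the top of the stack
  (objective side) and increasing z goes deeper into the gel;
* all physical quantities in µm, pixel indices 0-based;
* ``x_um = x_px * dx`` exactly (and likewise for y, z).

Stacks are stored as OME-TIFF with physical voxel sizes and channel names
embedded, via :mod:`tifffile`.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import tifffile

from .errors import ChannelError, GeometryError, StackIOError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .topography import PeakSet

GEL = "gel"
CELL = "cell"

#: Column order of the peaks CSV.
PEAKS_COLUMNS = (
    "peak_id",
    "x_px",
    "y_px",
    "x_um",
    "y_um",
    "depth_um",
    "prominence_um",
    "basin_area_px",
)


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel counts and physical spacings of a stack.

    Parameters
    ----------
    nz, ny, nx
        Number of voxels along z (depth), y (rows) and x (columns).
    dz, dy, dx
        Physical voxel spacing in µm along the same axes; strictly positive.
    """

    nz: int
    ny: int
    nx: int
    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        for name in ("nz", "ny", "nx"):
            n = getattr(self, name)
            if not (isinstance(n, (int, np.integer)) and n >= 1):
                raise GeometryError(f"{name} must be a positive integer, got {n!r}")
        for name in ("dz", "dy", "dx"):
            d = getattr(self, name)
            if not (np.isfinite(d) and d > 0):
                raise GeometryError(f"{name} must be strictly positive and finite, got {d!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nz, self.ny, self.nx)

    @property
    def depth_extent_um(self) -> float:
        """z position of the deepest slice, ``(nz - 1) * dz``."""
        return (self.nz - 1) * self.dz


@dataclass
class MultiChannelStack:
    """A multi-channel 3-D image stack with shared voxel geometry.

    ``channels`` maps channel name to a ``(nz, ny, nx)`` array;
    ``channel_roles`` assigns exactly one channel each to the roles
    ``"gel"`` (hydrogel fluorescence) and ``"cell"`` (cell label).
    """

    geometry: VoxelGeometry
    channels: dict[str, np.ndarray]
    channel_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ChannelError("stack must carry at least one channel")
        for name, arr in self.channels.items():
            if arr.shape != self.geometry.shape:
                raise ChannelError(
                    f"channel {name!r} has shape {arr.shape}, geometry says {self.geometry.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ChannelError(f"channel {name!r} contains non-finite intensities")
            if arr.min() < 0:
                raise ChannelError(f"channel {name!r} contains negative intensities")
        for role, name in self.channel_roles.items():
            if name not in self.channels:
                raise ChannelError(f"role {role!r} assigned to absent channel {name!r}")
        if GEL in self.channel_roles and CELL in self.channel_roles:
            if self.channel_roles[GEL] == self.channel_roles[CELL]:
                raise ChannelError("gel and cell roles must be assigned to distinct channels")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def role_volume(self, role: str) -> np.ndarray:
        """Return the 3-D array of the channel assigned to *role*."""
        if role not in self.channel_roles:
            raise ChannelError(f"no channel assigned to role {role!r}")
        return self.channels[self.channel_roles[role]]

    @property
    def gel(self) -> np.ndarray:
        return self.role_volume(GEL)

    @property
    def cell(self) -> np.ndarray:
        return self.role_volume(CELL)


def _resolve_roles(
    names: Sequence[str], role_map: Mapping[str, str | int] | None
) -> dict[str, str]:
    """Turn a role map (names or indices) into a name-valued map.

    Defaults to first channel = gel, second = cell when two or more
    channels are present and no map is given.
    """
    if role_map is None:
        if len(names) < 2:
            return {}
        return {GEL: names[0], CELL: names[1]}
    out: dict[str, str] = {}
    for role, key in role_map.items():
        if isinstance(key, (int, np.integer)):
            if not 0 <= key < len(names):
                raise ChannelError(f"role {role!r}: channel index {key} out of range")
            out[role] = names[key]
        else:
            if key not in names:
                raise ChannelError(f"role {role!r} names absent channel {key!r}")
            out[role] = str(key)
    return out


def _axes_to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Normalize a tifffile series to (C, Z, Y, X) regardless of on-disk layout."""
    axes = axes.upper()
    arr = data
    # squeeze singleton axes we do not model (time, sample, ...)
    keep = "CZYX"
    for i in reversed(range(len(axes))):
        ax = axes[i]
        if ax not in keep:
            if arr.shape[i] != 1:
                raise StackIOError(f"unsupported non-singleton axis {ax!r} in TIFF (axes={axes})")
            arr = np.squeeze(arr, axis=i)
            axes = axes[:i] + axes[i + 1 :]
    for ax in keep:
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in keep]
    return np.transpose(arr, order)


def _parse_ome(xml: str) -> tuple[dict[str, float], list[str]]:
    """Extract physical voxel sizes (µm) and channel names from OME-XML."""
    sizes: dict[str, float] = {}
    names: list[str] = []
    root = ET.fromstring(xml)
    for elem in root.iter():
        tag = elem.tag.rsplit("}", 1)[-1]
        if tag == "Pixels":
            for ax in ("X", "Y", "Z"):
                val = elem.get(f"PhysicalSize{ax}")
                if val is not None:
                    sizes[ax.lower()] = float(val)
        elif tag == "Channel":
            name = elem.get("Name")
            if name is not None:
                names.append(name)
    return sizes, names


def read_stack(
    path: str | Path,
    geometry_override: VoxelGeometry | None = None,
    role_map: Mapping[str, str | int] | None = None,
) -> MultiChannelStack:
    """Read a TIFF / OME-TIFF Z-stack into a :class:`MultiChannelStack`.

    Axis order is normalized to ``(z, y, x)`` per channel regardless of the
    on-disk layout. Physical voxel sizes are taken from OME metadata; for a
    plain TIFF without them, ``geometry_override`` must supply the spacings
    (its voxel counts, if inconsistent with the file, are ignored in favour
    of the data shape).
    """
    path = Path(path)
    if not path.exists():
        raise StackIOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = _axes_to_czyx(series.asarray(), series.axes)
            ome = tif.ome_metadata
    except StackIOError:
        raise
    except Exception as exc:  # malformed file
        raise StackIOError(f"cannot read TIFF {path}: {exc}") from exc

    nc, nz, ny, nx = data.shape
    if nc < 2:
        raise ChannelError(f"{path}: need at least 2 channels, found {nc}")

    sizes: dict[str, float] = {}
    names: list[str] = []
    if ome:
        sizes, names = _parse_ome(ome)
    if len(names) != nc:
        names = [f"ch{i}" for i in range(nc)]

    if geometry_override is not None:
        geom = VoxelGeometry(nz, ny, nx, geometry_override.dz, geometry_override.dy, geometry_override.dx)
    elif {"x", "y", "z"} <= sizes.keys():
        geom = VoxelGeometry(nz, ny, nx, sizes["z"], sizes["y"], sizes["x"])
    else:
        raise GeometryError(
            f"{path}: no physical voxel sizes in metadata and no geometry_override given"
        )

    channels = {name: data[i] for i, name in enumerate(names)}
    roles = _resolve_roles(names, role_map)
    return MultiChannelStack(geometry=geom, channels=channels, channel_roles=roles)


def write_stack(stack: MultiChannelStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with voxel sizes and channel names embedded.

    ``read_stack(write_stack(s))`` is the identity on arrays (bit-exact for
    integer dtypes), geometry and channel names.
    """
    path = Path(path)
    g = stack.geometry
    data = np.stack([stack.channels[name] for name in stack.channel_names])
    metadata = {
        "axes": "CZYX",
        "PhysicalSizeX": g.dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": g.dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": g.dz,
        "PhysicalSizeZUnit": "µm",
        "Channel": {"Name": stack.channel_names},
    }
    try:
        tifffile.imwrite(path, data, ome=True, metadata=metadata)
    except OSError as exc:
        raise StackIOError(f"cannot write {path}: {exc}") from exc
    return path


def write_plane_tiff(plane: np.ndarray, path: str | Path) -> Path:
    """Write a single 2-D map (e.g. depth or penetration, µm) as float32 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(plane, dtype=np.float32))
    return path


def write_peaks_table(peaks: "PeakSet", path: str | Path) -> Path:
    """Serialize a :class:`~gelpen.topography.PeakSet` as CSV.

    Rows are ordered by descending depth, ties broken by (y, x); µm
    coordinates are pixel index times spacing. An empty set yields a
    header-only file.
    """
    import pandas as pd

    path = Path(path)
    rows = [
        {
            "peak_id": i,
            "x_px": p.x_px,
            "y_px": p.y_px,
            "x_um": p.x_px * peaks.dx,
            "y_um": p.y_px * peaks.dy,
            "depth_um": p.depth_um,
            "prominence_um": p.prominence_um,
            "basin_area_px": p.basin_area_px,
        }
        for i, p in enumerate(peaks.ordered())
    ]
    df = pd.DataFrame(rows, columns=list(PEAKS_COLUMNS))
    try:
        df.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise StackIOError(f"cannot write {path}: {exc}") from exc
    return path
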