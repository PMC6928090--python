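"""Rasterizing leaflet head heavy atoms into a rectangular height grid.

The membrane rectangle (default 320 × 360 Å²) is meshed into square
cells (default 5 × 5 Å²; 64 × 72 = 4608 cells) and each cell's height
is the mean z of the leaflet's head heavy atoms falling in it.  Cells
containing no atoms are invalid and carry an explicit mask, not a
sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ROLE_LOWER, ROLE_UPPER, Frame, Topology, wrap_xy

_LEAFLET_ROLE = {"upper": ROLE_UPPER, "lower": ROLE_LOWER}


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectangular mesh: origin, square-cell spacing, cell counts."""

    origin: tuple = (0.0, 0.0)
    spacing: float = 5.0
    nx: int = 64
    ny: int = 72

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def extent(self) -> tuple:
        return (self.nx * self.spacing, self.ny * self.spacing)

    @classmethod
    def from_box(cls, box: tuple, spacing: float = 5.0,
                 origin: tuple = (0.0, 0.0)) -> "GridSpec":
        nx, ny = box[0] / spacing, box[1] / spacing
        if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
            raise ValueError(f"spacing {spacing} does not tile box {box} exactly")
        return cls(origin=origin, spacing=spacing, nx=int(round(nx)), ny=int(round(ny)))

    def cell_index(self, xy: np.ndarray) -> tuple:
        """Half-open cell indices [x0+iΔ, x0+(i+1)Δ) of wrapped coordinates."""
        rel = np.asarray(xy, dtype=float) - np.asarray(self.origin)
        i = np.floor(rel[..., 0] / self.spacing).astype(int)
        j = np.floor(rel[..., 1] / self.spacing).astype(int)
        return i, j


@dataclass
class HeightMap:
    """Per-cell mean heights with a validity mask for one leaflet frame."""

    grid: GridSpec
    heights: np.ndarray  # (nx, ny), NaN where invalid
    valid: np.ndarray  # (nx, ny) bool
    time: float
    leaflet: str

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    def valid_heights(self) -> np.ndarray:
        """Flat array of the defined cell heights {h_i}."""
        return self.heights[self.valid]


def build_height_map(frame: Frame, topology: Topology, leaflet: str,
                     grid: GridSpec | None = None) -> HeightMap:
    """Grid the leaflet's head heavy atoms into per-cell mean z heights.

    Atom (x, y) are wrapped into the periodic box first; an atom exactly
    on the far edge wraps to the origin side.  The grid must tile the
    box (a grid smaller than the box raises if an atom lands outside).
    """
    role = _LEAFLET_ROLE.get(leaflet)
    if role is None:
        raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")
    idx = topology.role_indices(role)
    if idx.size == 0:
        raise ValueError(f"frame contains no atoms with role {role!r}")
    if grid is None:
        grid = GridSpec.from_box(frame.box)

    pos = frame.positions[idx]
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite atom coordinates")
    xy = wrap_xy(pos[:, :2], frame.box)
    i, j = grid.cell_index(xy)
    if np.any((i < 0) | (i >= grid.nx) | (j < 0) | (j >= grid.ny)):
        bad = np.flatnonzero((i < 0) | (i >= grid.nx) | (j < 0) | (j >= grid.ny))[0]
        raise ValueError(
            f"atom at wrapped ({xy[bad, 0]:.3f}, {xy[bad, 1]:.3f}) falls outside "
            f"the {grid.extent[0]:.0f}x{grid.extent[1]:.0f} grid"
        )

    flat = i * grid.ny + j
    counts = np.bincount(flat, minlength=grid.nx * grid.ny).astype(float)
    sums = np.bincount(flat, weights=pos[:, 2], minlength=grid.nx * grid.ny)
    valid = counts > 0
    heights = np.full(grid.nx * grid.ny, np.nan)
    heights[valid] = sums[valid] / counts[valid]
    return HeightMap(
        grid=grid,
        heights=heights.reshape(grid.nx, grid.ny),
        valid=valid.reshape(grid.nx, grid.ny),
        time=frame.time,
        leaflet=leaflet,
    )


def global_mean_height(hm: HeightMap) -> float:
    """Global mean h̄ = Σh_i / n over the n valid cells."""
    if hm.n_valid == 0:
        raise ValueError("height map has no valid cells")
    return float(np.mean(hm.valid_heights()))


def local_thickness_map(upper: HeightMap, lower: HeightMap) -> tuple:
    """Cellwise thickness (upper − lower) where both leaflets are defined.

    Returns (thickness array NaN-masked, joint validity mask, frame-average
    thickness over the jointly valid cells).
    """
    if upper.grid != lower.grid:
        raise ValueError("height maps use different grids")
    joint = upper.valid & lower.valid
    if not joint.any():
        raise ValueError("no jointly valid cells")
    thickness = np.full_like(upper.heights, np.nan)
    thickness[joint] = upper.heights[joint] - lower.heights[joint]
    return thickness, joint, float(np.mean(thickness[joint]))


def height_maps_series(traj, leaflet: str, grid: GridSpec | None = None) -> list:
    """Height map for every frame of a trajectory."""
    return [build_height_map(fr, traj.topology, leaflet, grid) for fr in traj.frames]
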