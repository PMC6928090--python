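"""Protein–membrane coupling metrics.

The embedded core protein is enclosed by a rectangle (a tight per-frame
bounding box, or a fixed 30 × 40 Å² rectangle); the membrane height in
the ring of grid cells extending five cells beyond that rectangle
measures the local lift the protein imparts, compared against the
global mean height of the whole surface and against the protein's own
centre-of-mass elevation.

Two contribution decompositions are provided: the protein-lift
contribution (local minus global height) and the per-surface flow
contribution (half the deformation difference between a flow case and
its stationary counterpart).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heightmap import GridSpec, build_height_map, global_mean_height
from .model import ROLE_PROTEIN, ROLE_UPPER, Frame, Topology, Trajectory, wrap_xy

DEFAULT_BBOX_DIMS = (30.0, 40.0)  # Å
DEFAULT_MARGIN_CELLS = 5


@dataclass(frozen=True)
class ProximityRecord:
    time: float  # ns
    local_height: float  # Å, mean z of head atoms in the ring
    global_height: float  # Å, mean over all valid cells
    com_z: float  # Å
    bbox: tuple  # (x_min, x_max, y_min, y_max)
    ring_cells: int


def protein_bbox(frame: Frame, topology: Topology, mode: str = "auto",
                 rect: tuple = DEFAULT_BBOX_DIMS) -> tuple:
    """Rectangle enclosing the protein, as (x_min, x_max, y_min, y_max).

    ``auto``: tight x,y bounding box of the protein atoms.
    ``fixed``: ``rect`` given as 4 numbers is used verbatim (atom
    positions are ignored); given as (width, height) dims it is centred
    on the protein's mean x,y.
    """
    if mode == "fixed" and len(rect) == 4:
        x0, x1, y0, y1 = map(float, rect)
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"degenerate rectangle {rect}")
        return (x0, x1, y0, y1)
    idx = topology.role_indices(ROLE_PROTEIN)
    if idx.size == 0:
        raise ValueError("no protein atoms in topology")
    xy = frame.positions[idx, :2]
    if mode == "auto":
        return (float(xy[:, 0].min()), float(xy[:, 0].max()),
                float(xy[:, 1].min()), float(xy[:, 1].max()))
    if mode == "fixed":
        w, h = rect
        cx, cy = float(xy[:, 0].mean()), float(xy[:, 1].mean())
        return (cx - w / 2, cx + w / 2, cy - h / 2, cy + h / 2)
    raise ValueError(f"mode must be 'auto' or 'fixed', got {mode!r}")


def _ring_cell_mask(grid: GridSpec, bbox: tuple, margin_cells: int) -> np.ndarray:
    """Boolean (nx, ny) mask of ring cells: the bbox snapped outward to
    whole cells, expanded by margin_cells per side, minus the snapped
    bbox cells.  Indices wrap periodically."""
    x0, x1, y0, y1 = bbox
    ox, oy = grid.origin
    i0 = int(np.floor((x0 - ox) / grid.spacing))
    i1 = int(np.ceil((x1 - ox) / grid.spacing))  # exclusive
    j0 = int(np.floor((y0 - oy) / grid.spacing))
    j1 = int(np.ceil((y1 - oy) / grid.spacing))

    def _fill(mask, a0, a1, b0, b1):
        ii = np.arange(a0, a1) % grid.nx
        jj = np.arange(b0, b1) % grid.ny
        mask[np.ix_(ii, jj)] = True

    inner = np.zeros((grid.nx, grid.ny), dtype=bool)
    _fill(inner, i0, i1, j0, j1)
    outer = np.zeros_like(inner)
    _fill(outer, i0 - margin_cells, i1 + margin_cells,
          j0 - margin_cells, j1 + margin_cells)
    return outer & ~inner


def local_ring_height(frame: Frame, topology: Topology, grid: GridSpec,
                      bbox: tuple, margin_cells: int = DEFAULT_MARGIN_CELLS,
                      leaflet: str = "upper", weighting: str = "atom") -> tuple:
    """Mean membrane height in the ring of cells around the protein bbox.

    Returns (height, ring_cell_count).  ``weighting`` "atom" averages
    the raw z of head heavy atoms whose wrapped (x, y) falls in a ring
    cell; "cell" averages the occupied ring cells' mean heights instead.
    """
    if margin_cells < 1:
        raise ValueError(f"margin_cells must be >= 1, got {margin_cells}")
    ring = _ring_cell_mask(grid, bbox, margin_cells)
    n_ring = int(ring.sum())
    if n_ring == 0:
        raise ValueError("ring contains no cells")

    if weighting == "cell":
        hm = build_height_map(frame, topology, leaflet, grid)
        sel = ring & hm.valid
        if not sel.any():
            raise ValueError("no occupied cells in the ring")
        return float(np.mean(hm.heights[sel])), n_ring
    if weighting != "atom":
        raise ValueError(f"weighting must be 'atom' or 'cell', got {weighting!r}")

    role = ROLE_UPPER if leaflet == "upper" else "lower_head_heavy"
    idx = topology.role_indices(role)
    pos = frame.positions[idx]
    xy = wrap_xy(pos[:, :2], frame.box)
    i, j = grid.cell_index(xy)
    ok = (i >= 0) & (i < grid.nx) & (j >= 0) & (j < grid.ny)
    in_ring = np.zeros(len(idx), dtype=bool)
    in_ring[ok] = ring[i[ok], j[ok]]
    if not in_ring.any():
        raise ValueError("no head heavy atoms in the ring region")
    return float(np.mean(pos[in_ring, 2])), n_ring


def protein_com_z(frame: Frame, topology: Topology) -> float:
    """Mass-weighted mean z of the protein atoms."""
    idx = topology.role_indices(ROLE_PROTEIN)
    if idx.size == 0:
        raise ValueError("no protein atoms in topology")
    m = topology.masses[idx]
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total protein mass")
    return float(np.sum(m * frame.positions[idx, 2]) / total)


def lift_decomposition(local_mean: float, global_mean: float) -> float:
    """Extra height contributed by the protein lift: local − global."""
    return float(local_mean) - float(global_mean)


def flow_decomposition(deformation_flow: float, deformation_stationary: float) -> float:
    """Per-surface flow contribution: (flow − stationary) / 2.

    The raw difference (both surfaces together) is twice the returned
    value.
    """
    return (float(deformation_flow) - float(deformation_stationary)) / 2.0


def proximity_series(traj: Trajectory, grid: GridSpec | None = None,
                     bbox_mode: str = "auto", bbox_rect: tuple = DEFAULT_BBOX_DIMS,
                     margin_cells: int = DEFAULT_MARGIN_CELLS,
                     weighting: str = "atom") -> tuple:
    """Per-frame proximity records plus mean ± SE summaries."""
    records = []
    for fr in traj.frames:
        g = grid or GridSpec.from_box(fr.box)
        bbox = protein_bbox(fr, traj.topology, bbox_mode, bbox_rect)
        local, n_ring = local_ring_height(fr, traj.topology, g, bbox,
                                          margin_cells, "upper", weighting)
        hm = build_height_map(fr, traj.topology, "upper", g)
        records.append(ProximityRecord(
            time=fr.time, local_height=local,
            global_height=global_mean_height(hm),
            com_z=protein_com_z(fr, traj.topology),
            bbox=bbox, ring_cells=n_ring,
        ))

    def _summary(values: np.ndarray) -> dict:
        if values.size < 2:
            return {"mean": float(values.mean()) if values.size else float("nan"),
                    "se": float("nan"), "n": int(values.size)}
        return {"mean": float(values.mean()),
                "se": float(values.std(ddof=1) / np.sqrt(values.size)),
                "n": int(values.size)}

    summaries = {
        name: _summary(np.array([getattr(r, name) for r in records]))
        for name in ("local_height", "global_height", "com_z")
    }
    summaries["lift"] = {
        "mean": summaries["local_height"]["mean"] - summaries["global_height"]["mean"],
    }
    return records, summaries
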