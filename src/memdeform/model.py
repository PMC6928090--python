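"""Internal data model for bilayer trajectory post-processing.

Units follow a single convention throughout the package: coordinates in
Å, times in ns, velocities in Å/ns, forces in pN, masses in amu.  The
simulation box is a rectangle (Lx, Ly) periodic in x and y and open in
z; the physical membrane patch (a hexagon) lives inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: Role labels partitioning the atoms of a system.
ROLE_UPPER = "upper_head_heavy"
ROLE_LOWER = "lower_head_heavy"
ROLE_PROTEIN = "protein"
ROLE_OTHER = "other"
ROLES = (ROLE_UPPER, ROLE_LOWER, ROLE_PROTEIN, ROLE_OTHER)

#: Elements admissible for lipid head heavy atoms (carbon, nitrogen, phosphorus).
HEAD_HEAVY_ELEMENTS = frozenset({"C", "N", "P"})

#: Standard atomic masses (amu) for elements this package encounters.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098,
}

#: Conversion factor from kcal·mol⁻¹·Å⁻¹ to pN.
KCAL_PER_MOL_ANGSTROM_TO_PN = 69.4786


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology: identity, element, mass and role label."""

    atom_id: int
    element: str
    mass: float
    role: str

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_id}: mass must be > 0, got {self.mass}")
        if self.role not in ROLES:
            raise ValueError(f"atom {self.atom_id}: unknown role {self.role!r}")
        if self.role in (ROLE_UPPER, ROLE_LOWER) and self.element not in HEAD_HEAVY_ELEMENTS:
            raise ValueError(
                f"atom {self.atom_id}: head-heavy role requires element C, N or P, "
                f"got {self.element!r}"
            )


class Topology:
    """Columnar container of AtomRecords with fast role selection."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self._atoms = tuple(atoms)
        self.atom_ids = np.array([a.atom_id for a in atoms], dtype=np.int64)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.roles = np.array([a.role for a in atoms], dtype=object)

    def __len__(self) -> int:
        return len(self._atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self._atoms)

    def __getitem__(self, i: int) -> AtomRecord:
        return self._atoms[i]

    def role_indices(self, role: str) -> np.ndarray:
        """Indices (0-based positions) of atoms carrying ``role``."""
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return np.flatnonzero(self.roles == role)

    def role_counts(self) -> dict:
        return {r: int(np.sum(self.roles == r)) for r in ROLES}


@dataclass
class Frame:
    """Time-stamped snapshot: positions of every topology atom plus the box."""

    time: float  # ns
    positions: np.ndarray  # (n_atoms, 3) in Å
    box: tuple  # (Lx, Ly) in Å, periodic in x and y

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3), got {self.positions.shape}")
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"frame time must be finite and non-negative, got {self.time}")
        if len(self.box) != 2 or self.box[0] <= 0 or self.box[1] <= 0:
            raise ValueError(f"box must be a positive (Lx, Ly) pair, got {self.box}")


class Trajectory:
    """Time-ordered frames over a fixed topology, sampled at a uniform dt.

    Optional per-frame per-atom forces and velocities are NaN-masked
    arrays of the same (n_frames, n_atoms, 3) shape as the positions:
    a NaN row means the quantity is absent for that atom, never zero.
    """

    _DT_TOL = 1e-6  # ns

    def __init__(self, topology: Topology, frames: Sequence[Frame], dt: float = 0.1,
                 forces: np.ndarray | None = None,
                 velocities: np.ndarray | None = None):
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        n_atoms = len(topology)
        for k, fr in enumerate(frames):
            if fr.positions.shape[0] != n_atoms:
                raise ValueError(
                    f"frame {k}: expected {n_atoms} atoms, found {fr.positions.shape[0]}"
                )
        times = np.array([fr.time for fr in frames])
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if len(times) > 1 and np.any(np.abs(np.diff(times) - dt) > self._DT_TOL):
            raise ValueError(f"successive frame times must differ by dt={dt} ns")
        self.topology = topology
        self.frames = list(frames)
        self.dt = float(dt)
        self.forces = self._check_aux(forces, n_atoms, "forces")
        self.velocities = self._check_aux(velocities, n_atoms, "velocities")

    def _check_aux(self, arr, n_atoms: int, name: str):
        if arr is None:
            return None
        arr = np.asarray(arr, dtype=float)
        expected = (len(self.frames), n_atoms, 3)
        if arr.shape != expected:
            raise ValueError(f"{name} shape {arr.shape} does not match {expected}")
        return arr

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def positions_array(self) -> np.ndarray:
        """All positions stacked as (n_frames, n_atoms, 3)."""
        return np.stack([fr.positions for fr in self.frames])


def wrap_xy(xy: np.ndarray, box: tuple) -> np.ndarray:
    """Wrap in-plane coordinates into [0, Lx) × [0, Ly)."""
    xy = np.asarray(xy, dtype=float)
    out = xy.copy()
    out[..., 0] %= box[0]
    out[..., 1] %= box[1]
    return out


def minimum_image_displacement(delta: np.ndarray, box: tuple) -> np.ndarray:
    """Minimum-image x,y displacement for a periodic rectangle; z untouched."""
    delta = np.array(delta, dtype=float)
    for axis, L in enumerate(box[:2]):
        delta[..., axis] -= L * np.round(delta[..., axis] / L)
    return delta
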