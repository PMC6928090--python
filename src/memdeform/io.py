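"""Reading topologies, trajectories and force/velocity tables.

The on-disk formats are the field's standard ones — PDB for the
topology, DCD or multi-model PDB for coordinates — parsed through
MDAnalysis.  A plain per-frame coordinate CSV is accepted as a
text-only alternative.  Role labels (which leaflet a head-group heavy
atom belongs to, what is protein) are assigned from user-supplied
pattern rules, never guessed geometrically.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    ELEMENT_MASSES,
    KCAL_PER_MOL_ANGSTROM_TO_PN,
    ROLE_LOWER,
    ROLE_OTHER,
    ROLE_UPPER,
    AtomRecord,
    Frame,
    Topology,
    Trajectory,
)


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


@dataclass(frozen=True)
class RoleRule:
    """Maps atoms to a role by glob patterns on resname / atom name / segid.

    Each pattern field is a comma-separated list of case-insensitive
    globs ("P,N,C*"); ``None`` matches anything.  Rules are applied in
    order; the first match wins and unmatched atoms become "other".
    """

    role: str
    resname: str | None = None
    name: str | None = None
    segid: str | None = None

    def _match_field(self, pattern: str | None, value: str) -> bool:
        if pattern is None:
            return True
        return any(
            fnmatch.fnmatchcase(value.upper(), p.strip().upper())
            for p in pattern.split(",")
        )

    def matches(self, resname: str, name: str, segid: str) -> bool:
        return (
            self._match_field(self.resname, resname)
            and self._match_field(self.name, name)
            and self._match_field(self.segid, segid)
        )


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (e.g. 'C12' -> 'C', 'CL' -> 'CL')."""
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if stripped[:2] in ELEMENT_MASSES and stripped[:2] not in ("CA",):
        return stripped[:2]
    if stripped[:1] in ELEMENT_MASSES:
        return stripped[:1]
    raise FormatError(f"cannot infer element from atom name {name!r}")


def _first_malformed_pdb_line(path) -> int | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    return lineno
    return None


def read_topology(path, role_map: list[RoleRule] | None = None) -> Topology:
    """Read a PDB topology and assign every atom exactly one role.

    Atoms matching no rule get role "other".  Element symbols come from
    the PDB element column when present, otherwise from the atom name;
    masses from a standard element-mass table.
    """
    import MDAnalysis as mda

    role_map = list(role_map or [])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        lineno = None
        try:
            lineno = _first_malformed_pdb_line(path)
        except OSError:
            pass
        where = f" (first malformed record at line {lineno})" if lineno else ""
        raise FormatError(f"cannot parse PDB topology {path}{where}: {exc}") from exc

    atoms = u.atoms
    names = atoms.names
    resnames = atoms.resnames if hasattr(atoms, "resnames") else [""] * len(atoms)
    segids = atoms.segids if hasattr(atoms, "segids") else [""] * len(atoms)
    try:
        elements = [e.upper() if e else "" for e in atoms.elements]
    except Exception:
        elements = [""] * len(atoms)

    matched = [0] * len(role_map)
    records = []
    for i in range(len(atoms)):
        role = ROLE_OTHER
        for k, rule in enumerate(role_map):
            if rule.matches(str(resnames[i]), str(names[i]), str(segids[i])):
                role = rule.role
                matched[k] += 1
                break
        element = elements[i] or _element_from_name(str(names[i]))
        mass = ELEMENT_MASSES.get(element)
        if mass is None:
            raise FormatError(f"no standard mass for element {element!r} (atom {i})")
        records.append(AtomRecord(atom_id=i, element=element, mass=mass, role=role))

    for k, rule in enumerate(role_map):
        if matched[k] == 0:
            warnings.warn(f"role rule {rule} matched zero atoms", stacklevel=2)
    return Topology(records)


def _frames_from_csv(path) -> tuple[np.ndarray, tuple | None]:
    df = pd.read_csv(path)
    required = {"frame", "atom_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"coordinate CSV {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    n_frames = int(df["frame"].max()) + 1
    n_atoms = int(df["atom_id"].max()) + 1
    pos = np.full((n_frames, n_atoms, 3), np.nan)
    pos[df["frame"].to_numpy(), df["atom_id"].to_numpy()] = df[["x", "y", "z"]].to_numpy()
    if np.isnan(pos).any():
        raise FormatError(f"coordinate CSV {path} has missing (frame, atom) entries")
    return pos, None


def _frames_from_mda(path):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.PDB import PDBReader

    suffix = str(path).lower().rsplit(".", 1)[-1]
    reader_cls = {"dcd": DCDReader, "pdb": PDBReader, "ent": PDBReader}.get(suffix)
    if reader_cls is None:
        raise FormatError(f"unsupported trajectory format: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = reader_cls(str(path))
        frames, box = [], None
        for ts in reader:
            frames.append(ts.positions.astype(float).copy())
            if ts.dimensions is not None and ts.dimensions[0] > 0:
                box = (float(ts.dimensions[0]), float(ts.dimensions[1]))
        reader.close()
    return np.stack(frames), box


def read_trajectory(topology: Topology, path, dt: float = 0.1,
                    box: tuple | None = None) -> Trajectory:
    """Read a DCD, multi-model PDB, or coordinate-CSV trajectory.

    Frame times are assigned as i·dt (ns).  ``box`` overrides (or, for
    CSV input, supplies) the periodic rectangle (Lx, Ly) in Å.
    """
    if str(path).lower().endswith(".csv"):
        pos, file_box = _frames_from_csv(path)
    else:
        pos, file_box = _frames_from_mda(path)
    if pos.shape[0] == 0:
        raise FormatError(f"trajectory {path} contains zero frames")
    if pos.shape[1] != len(topology):
        raise ValueError(
            f"atom-count mismatch: topology has {len(topology)} atoms, "
            f"trajectory {path} has {pos.shape[1]}"
        )
    use_box = box or file_box
    if use_box is None:
        raise ValueError(f"trajectory {path} carries no box; pass box=(Lx, Ly)")
    frames = [Frame(time=i * dt, positions=pos[i], box=tuple(use_box))
              for i in range(pos.shape[0])]
    return Trajectory(topology, frames, dt=dt)


def _read_vector_table(traj: Trajectory, path, columns: tuple, scale: float) -> np.ndarray:
    df = pd.read_csv(path)
    required = {"frame_index", "atom_id", *columns}
    if not required.issubset(df.columns):
        raise FormatError(
            f"table {path} must have columns {sorted(required)}, found {list(df.columns)}"
        )
    n_frames, n_atoms = len(traj), traj.n_atoms
    fidx = df["frame_index"].to_numpy(dtype=int)
    aidx = df["atom_id"].to_numpy(dtype=int)
    if fidx.size and (fidx.min() < 0 or fidx.max() >= n_frames):
        bad = fidx[(fidx < 0) | (fidx >= n_frames)][0]
        raise ValueError(
            f"frame index {bad} out of range for a {n_frames}-frame trajectory"
        )
    if aidx.size and (aidx.min() < 0 or aidx.max() >= n_atoms):
        bad = aidx[(aidx < 0) | (aidx >= n_atoms)][0]
        raise ValueError(f"atom id {bad} out of range for {n_atoms} atoms")
    out = np.full((n_frames, n_atoms, 3), np.nan)
    out[fidx, aidx] = df[list(columns)].to_numpy(dtype=float) * scale
    return out


def attach_forces(traj: Trajectory, path, unit: str = "pN") -> Trajectory:
    """Attach per-frame per-atom forces from a CSV table.

    The table has columns frame_index, atom_id, fx, fy, fz.  Atoms
    without a row keep NaN (absent), never zero.  ``unit`` declares the
    table's force unit: "pN" or "kcal/mol/A" (converted to pN).
    """
    scale = {"pN": 1.0, "kcal/mol/A": KCAL_PER_MOL_ANGSTROM_TO_PN}.get(unit)
    if scale is None:
        raise ValueError(f"unknown force unit {unit!r}; use 'pN' or 'kcal/mol/A'")
    traj.forces = _read_vector_table(traj, path, ("fx", "fy", "fz"), scale)
    return traj


def attach_velocities(traj: Trajectory, path) -> Trajectory:
    """Attach per-frame per-atom velocities (Å/ns) from a CSV table."""
    traj.velocities = _read_vector_table(traj, path, ("vx", "vy", "vz"), 1.0)
    return traj


def infer_leaflet_roles(topology: Topology, frame: Frame,
                        candidate_indices: np.ndarray) -> dict:
    """Convenience classifier: split candidate head atoms by the bilayer
    mid-plane z of the given frame.  Returned as a suggestion mapping
    atom index -> role; never applied automatically.
    """
    z = frame.positions[candidate_indices, 2]
    mid = float(np.mean(z))
    return {
        int(i): (ROLE_UPPER if zi > mid else ROLE_LOWER)
        for i, zi in zip(candidate_indices, z)
    }


def write_trajectory_npz(traj: Trajectory, path) -> None:
    """Serialize frames (and any attached forces/velocities) to an NPZ container."""
    payload = {
        "positions": traj.positions_array(),
        "times": traj.times,
        "box": np.array(traj.frames[0].box),
        "dt": np.array(traj.dt),
        "roles": traj.topology.roles.astype(str),
        "elements": traj.topology.elements.astype(str),
        "masses": traj.topology.masses,
    }
    if traj.forces is not None:
        payload["forces"] = traj.forces
    if traj.velocities is not None:
        payload["velocities"] = traj.velocities
    np.savez_compressed(path, **payload)
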