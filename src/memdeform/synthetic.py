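"""Ground-truthed synthetic bilayer trajectories.

Emulates the geometry of a hexagonal POPC membrane patch (circumcircle
diameter 179 Å, flat sides parallel to the flow axis) centred in a
320 × 360 Å² periodic rectangle: two leaflets of head-group heavy
atoms ~42 Å apart, travelling surface undulations, per-leaflet x-drift,
an embedded protein cylinder with a prescribed centre-of-mass height
and a Gaussian membrane-lift bump on the upper leaflet, and i.i.d.
normal x-forces on upper head atoms.

The dynamics are kinematic prescriptions, not physics: every realized
quantity is recorded in a GroundTruth object so downstream statistics
can be checked against independent oracles.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import (
    ROLE_LOWER,
    ROLE_PROTEIN,
    ROLE_UPPER,
    AtomRecord,
    Frame,
    Topology,
    Trajectory,
)


@dataclass(frozen=True)
class Mode:
    """One travelling undulation mode A·sin(kx·x + ky·y + φ + ω·t)."""

    amplitude: float  # Å
    kx: float  # Å⁻¹
    ky: float  # Å⁻¹
    phase: float = 0.0  # rad
    angular_speed: float = 0.0  # rad/ns

    @classmethod
    def from_wavelength(cls, amplitude: float, wavelength: float, axis: str = "x",
                        phase: float = 0.0, angular_speed: float = 0.0) -> "Mode":
        k = 2.0 * np.pi / wavelength
        kx, ky = (k, 0.0) if axis == "x" else (0.0, k)
        return cls(amplitude, kx, ky, phase, angular_speed)


@dataclass
class SyntheticParams:
    """Parameters of the synthetic bilayer patch.

    Defaults emulate the modelled system: hexagon circumcircle diameter
    179 Å in a 320 × 360 Å² rectangle, leaflets 42 Å apart, head-atom
    surface density matching ~8 C/N/P head heavy atoms per POPC lipid
    at ~65 Å² per lipid, frames every 0.1 ns.
    """

    hex_circumdiameter: float = 179.0  # Å
    rect: tuple = (320.0, 360.0)  # Å
    thickness_d0: float = 42.0  # Å
    head_density: float = 0.12  # atoms/Å² per leaflet
    modes: tuple = (Mode.from_wavelength(3.0, 80.0, angular_speed=2.0),)
    noise_sigma: float = 0.5  # Å, z-noise per atom per frame
    drift_upper_x: float = 4.2  # Å/ns
    drift_lower_x: float = 0.0  # Å/ns
    protein_radius: float = 12.0  # Å
    protein_height: float = 60.0  # Å
    protein_n_atoms: int = 400
    com_z_trajectory: Callable[[float], float] | float = 0.0  # Å
    bump_amplitude: float = 2.5  # Å (L)
    bump_width: float = 15.0  # Å (w)
    force_mean_x: float = 0.5  # pN
    force_sigma: float = 0.2  # pN
    dt: float = 0.1  # ns
    n_frames: int = 50
    seed: int = 0
    head_style: str = "P"  # "P" single pseudo-atom, "CNP" 3-atom head
    include_protein: bool = True
    with_forces: bool = True

    def __post_init__(self) -> None:
        if self.hex_circumdiameter > min(self.rect):
            raise ValueError("hexagon circumcircle must fit inside the rectangle")
        for name in ("head_density", "noise_sigma", "bump_width", "force_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(m.amplitude < 0 for m in self.modes):
            raise ValueError("mode amplitudes must be >= 0")
        if self.head_style not in ("P", "CNP"):
            raise ValueError("head_style must be 'P' or 'CNP'")

    @property
    def hex_circumradius(self) -> float:
        return self.hex_circumdiameter / 2.0

    @property
    def center(self) -> tuple:
        return (self.rect[0] / 2.0, self.rect[1] / 2.0)

    def com_z(self, t: float) -> float:
        if callable(self.com_z_trajectory):
            return float(self.com_z_trajectory(t))
        return float(self.com_z_trajectory)


def hexagon_area(circumradius: float) -> float:
    """Area of a regular hexagon with given circumradius: (3√3/2)·R²."""
    return 1.5 * np.sqrt(3.0) * circumradius**2


def in_hexagon(x, y, center: tuple, circumradius: float) -> np.ndarray:
    """Point-in-regular-hexagon test, flat sides parallel to the x axis.

    Vertices sit at angles 0°, 60°, … from the centre, so the top and
    bottom edges are horizontal at y = ±(√3/2)·R.
    """
    lx = np.abs(np.asarray(x, dtype=float) - center[0])
    ly = np.abs(np.asarray(y, dtype=float) - center[1])
    s3 = np.sqrt(3.0)
    return (ly <= s3 / 2.0 * circumradius + 1e-12) & (ly <= s3 * (circumradius - lx) + 1e-12)


def surface_height(params: SyntheticParams, x, y, t: float) -> np.ndarray:
    """Undulation field u(x, y, t): sum of the travelling modes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = np.zeros(np.broadcast(x, y).shape)
    for m in params.modes:
        u = u + m.amplitude * np.sin(m.kx * x + m.ky * y + m.phase + m.angular_speed * t)
    return u


def bump_height(params: SyntheticParams, x, y) -> np.ndarray:
    """Protein membrane-lift bump L·exp(−r²/(2w²)) around the protein axis."""
    cx, cy = params.center
    r2 = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2
    return params.bump_amplitude * np.exp(-r2 / (2.0 * params.bump_width**2))


@dataclass
class GroundTruth:
    """Realized generator state, sufficient for independent oracles."""

    params: SyntheticParams
    head_xy0_upper: np.ndarray  # (n_sites, 2) lattice positions at t=0
    head_xy0_lower: np.ndarray
    com_z_per_frame: np.ndarray
    role_counts: dict
    times: np.ndarray

    def true_x(self, leaflet: str, frame_index: int) -> np.ndarray:
        """Unwrapped x of each head site at the given frame."""
        t = self.times[frame_index]
        if leaflet == "upper":
            return self.head_xy0_upper[:, 0] + self.params.drift_upper_x * t
        if leaflet == "lower":
            return self.head_xy0_lower[:, 0] + self.params.drift_lower_x * t
        raise ValueError(f"unknown leaflet {leaflet!r}")

    def to_jsonable(self) -> dict:
        p = self.params
        return {
            "hex_circumdiameter": p.hex_circumdiameter,
            "rect": list(p.rect),
            "thickness_d0": p.thickness_d0,
            "head_density": p.head_density,
            "modes": [dataclasses.asdict(m) for m in p.modes],
            "noise_sigma": p.noise_sigma,
            "drift_upper_x": p.drift_upper_x,
            "drift_lower_x": p.drift_lower_x,
            "bump_amplitude": p.bump_amplitude,
            "bump_width": p.bump_width,
            "protein_radius": p.protein_radius,
            "protein_height": p.protein_height,
            "force_mean_x": p.force_mean_x,
            "force_sigma": p.force_sigma,
            "dt": p.dt,
            "n_frames": p.n_frames,
            "seed": p.seed,
            "com_z_per_frame": self.com_z_per_frame.tolist(),
            "role_counts": self.role_counts,
        }


# Fixed intra-head offsets (Å) for the 3-atom C/N/P head variant.
_CNP_OFFSETS = np.array([[0.0, 0.0, 0.0], [1.2, 0.8, 0.0], [-1.0, 1.1, 0.0]])
_CNP_ELEMENTS = ("P", "N", "C")
_ELEM_MASS = {"P": 30.974, "N": 14.007, "C": 12.011}


def _head_lattice(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered square lattice clipped to the hexagon; one site per head."""
    a = 1.0 / np.sqrt(params.head_density)
    R = params.hex_circumradius
    cx, cy = params.center
    xs = np.arange(cx - R, cx + R + a, a)
    ys = np.arange(cy - np.sqrt(3) / 2 * R, cy + np.sqrt(3) / 2 * R + a, a)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts += rng.uniform(-a / 2, a / 2, size=pts.shape)
    keep = in_hexagon(pts[:, 0], pts[:, 1], (cx, cy), R)
    return pts[keep]


def _protein_sites(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in the protein cylinder, COM-centred in z."""
    n = params.protein_n_atoms
    r = params.protein_radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    z = rng.uniform(-params.protein_height / 2, params.protein_height / 2, size=n)
    z -= z.mean()  # equal-mass atoms: COM z is exactly the mean
    cx, cy = params.center
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta), z])


def generate(params: SyntheticParams) -> tuple:
    """Generate (Trajectory, Topology, GroundTruth) from the parameters.

    Upper-leaflet heads sit at z = +d0/2 + u(x,y,t) + bump + noise, the
    lower leaflet at z = −d0/2 + u(x,y,t) + noise; both drift in x at
    their leaflet's velocity with periodic wrapping.  The same seed
    always yields bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    upper_xy = _head_lattice(params, rng)
    lower_xy = _head_lattice(params, rng)
    if len(upper_xy) < 10 or len(lower_xy) < 10:
        raise ValueError(
            f"head_density {params.head_density} yields a leaflet with fewer than "
            f"10 atoms ({len(upper_xy)}/{len(lower_xy)}); statistics undefined"
        )
    protein_xyz = _protein_sites(params, rng) if params.include_protein else np.empty((0, 3))

    atoms_per_head = 1 if params.head_style == "P" else 3
    records = []
    aid = 0
    for xy, role in ((upper_xy, ROLE_UPPER), (lower_xy, ROLE_LOWER)):
        for _ in range(len(xy)):
            for j in range(atoms_per_head):
                el = "P" if params.head_style == "P" else _CNP_ELEMENTS[j]
                records.append(AtomRecord(aid, el, _ELEM_MASS[el], role))
                aid += 1
        # per-leaflet contiguous blocks keep index arithmetic trivial
    for _ in range(len(protein_xyz)):
        records.append(AtomRecord(aid, "C", _ELEM_MASS["C"], ROLE_PROTEIN))
        aid += 1
    topology = Topology(records)

    n_frames = params.n_frames
    times = np.arange(n_frames) * params.dt
    Lx = params.rect[0]
    com_z = np.array([params.com_z(t) for t in times])

    frames = []
    forces = np.full((n_frames, len(topology), 3), np.nan) if params.with_forces else None
    n_up_atoms = len(upper_xy) * atoms_per_head
    for i, t in enumerate(times):
        blocks = []
        for xy0, drift, base_z, with_bump in (
            (upper_xy, params.drift_upper_x, params.thickness_d0 / 2, True),
            (lower_xy, params.drift_lower_x, -params.thickness_d0 / 2, False),
        ):
            x = (xy0[:, 0] + drift * t) % Lx
            y = xy0[:, 1]
            z = base_z + surface_height(params, x, y, t)
            if with_bump:
                z = z + bump_height(params, x, y)
            if params.noise_sigma > 0:
                z = z + rng.normal(0.0, params.noise_sigma, size=len(x))
            sites = np.column_stack([x, y, z])
            if atoms_per_head == 1:
                blocks.append(sites)
            else:
                expanded = (sites[:, None, :] + _CNP_OFFSETS[None, :, :]).reshape(-1, 3)
                blocks.append(expanded)
        if params.include_protein:
            prot = protein_xyz.copy()
            prot[:, 2] += com_z[i]
            blocks.append(prot)
        frames.append(Frame(time=t, positions=np.vstack(blocks), box=params.rect))
        if forces is not None:
            forces[i, :n_up_atoms, 0] = rng.normal(
                params.force_mean_x, params.force_sigma, size=n_up_atoms)
            forces[i, :n_up_atoms, 1:] = 0.0

    traj = Trajectory(topology, frames, dt=params.dt, forces=forces)
    truth = GroundTruth(
        params=params,
        head_xy0_upper=upper_xy,
        head_xy0_lower=lower_xy,
        com_z_per_frame=com_z,
        role_counts=topology.role_counts(),
        times=times,
    )
    return traj, topology, truth


def write_fixture(traj: Trajectory, topology: Topology, truth: GroundTruth,
                  outdir, trajectory_format: str = "dcd") -> dict:
    """Write topology.pdb, a trajectory (DCD or multi-model PDB), a force
    CSV table and the ground-truth JSON into an existing directory.

    Returns a dict of the written paths.
    """
    import MDAnalysis as mda
    import pandas as pd

    if not os.path.isdir(outdir):
        raise FileNotFoundError(f"output directory {outdir} does not exist")

    resname = {ROLE_UPPER: "UHD", ROLE_LOWER: "LHD", ROLE_PROTEIN: "PRO"}
    n = len(topology)
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n), trajectory=True)
    u.add_TopologyAttr("names", [str(e) for e in topology.elements])
    u.add_TopologyAttr("resnames",
                       [resname.get(r, "OTH") for r in topology.roles])
    u.add_TopologyAttr("elements", [str(e) for e in topology.elements])
    u.add_TopologyAttr("masses", topology.masses)
    box = traj.frames[0].box
    u.dimensions = [box[0], box[1], 200.0, 90.0, 90.0, 90.0]
    u.atoms.positions = traj.frames[0].positions

    paths = {"topology": os.path.join(outdir, "topology.pdb")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(paths["topology"])

        if trajectory_format == "dcd":
            paths["trajectory"] = os.path.join(outdir, "traj.dcd")
            with mda.Writer(paths["trajectory"], n_atoms=n) as w:
                for fr in traj.frames:
                    u.atoms.positions = fr.positions
                    u.dimensions = [box[0], box[1], 200.0, 90.0, 90.0, 90.0]
                    w.write(u.atoms)
        elif trajectory_format == "pdb":
            paths["trajectory"] = os.path.join(outdir, "traj.pdb")
            with mda.Writer(paths["trajectory"], multiframe=True) as w:
                for fr in traj.frames:
                    u.atoms.positions = fr.positions
                    w.write(u.atoms)
        else:
            raise ValueError(f"unknown trajectory_format {trajectory_format!r}")

    if traj.forces is not None:
        fidx, aidx = np.nonzero(~np.isnan(traj.forces[:, :, 0]))
        table = pd.DataFrame({
            "frame_index": fidx,
            "atom_id": aidx,
            "fx": traj.forces[fidx, aidx, 0],
            "fy": traj.forces[fidx, aidx, 1],
            "fz": traj.forces[fidx, aidx, 2],
        })
        paths["forces"] = os.path.join(outdir, "forces.csv")
        table.to_csv(paths["forces"], index=False)

    paths["truth"] = os.path.join(outdir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)
    return paths
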