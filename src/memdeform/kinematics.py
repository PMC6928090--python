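"""Leaflet kinematics: relative velocity, strain rate, thickness, net force.

The membrane is sheared by flow along x; the shear strain rate is the
single tensor component

    ε̇_zx = v̄_x,rel / d

where v̄_x,rel is the mean x-velocity of the upper leaflet's head heavy
atoms minus the lower leaflet's, and d the membrane thickness — either
a fixed constant (default 42 Å, the representative bilayer thickness)
or the frame's average local thickness.  Velocities default to finite
differences of consecutive 0.1-ns frames with minimum-image unwrapping
in the periodic plane; files that carry explicit velocities can use
them directly.  The net driving force is the mean x-force on the upper
leaflet's head heavy atoms, in pN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heightmap import GridSpec, build_height_map, local_thickness_map
from .model import ROLE_LOWER, ROLE_UPPER, Trajectory, minimum_image_displacement

_LEAFLET_ROLE = {"upper": ROLE_UPPER, "lower": ROLE_LOWER}
DEFAULT_THICKNESS = 42.0  # Å


@dataclass(frozen=True)
class KinematicsRecord:
    time: float  # ns
    v_x_upper: float  # Å/ns
    v_x_lower: float  # Å/ns
    v_x_rel: float  # Å/ns
    d: float  # Å
    strain_rate: float  # ns⁻¹
    f_x_net: float  # pN (NaN when no forces attached)
    v_z_upper_signed: float  # Å/ns
    v_z_upper_abs: float  # Å/ns


def leaflet_velocity(traj: Trajectory, leaflet: str, frame_index: int,
                     component: str = "x", method: str = "finite_difference") -> float:
    """Mean velocity component of one leaflet's head heavy atoms at a frame.

    Finite-difference mode uses (pos[t] − pos[t−dt]) / dt with
    minimum-image unwrapping in x, y; it is undefined at frame 0.
    Direct mode reads attached per-atom velocities.
    """
    axis = {"x": 0, "y": 1, "z": 2}.get(component)
    if axis is None:
        raise ValueError(f"component must be x, y or z, got {component!r}")
    role = _LEAFLET_ROLE.get(leaflet)
    if role is None:
        raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")
    idx = traj.topology.role_indices(role)
    if idx.size == 0:
        raise ValueError(f"no atoms with role {role!r}")

    if method == "finite_difference":
        if frame_index < 1:
            raise ValueError("finite-difference velocity is undefined at frame 0")
        delta = (traj.frames[frame_index].positions[idx]
                 - traj.frames[frame_index - 1].positions[idx])
        delta = minimum_image_displacement(delta, traj.frames[frame_index].box)
        return float(np.mean(delta[:, axis]) / traj.dt)
    if method == "direct":
        if traj.velocities is None:
            raise ValueError("trajectory carries no velocities; attach them first")
        v = traj.velocities[frame_index, idx, axis]
        if np.isnan(v).any():
            missing = idx[np.isnan(v)][0]
            raise ValueError(f"velocity missing for atom {missing} at frame {frame_index}")
        return float(np.mean(v))
    raise ValueError(f"method must be 'finite_difference' or 'direct', got {method!r}")


def strain_rate(v_upper_x: float, v_lower_x: float, d: float) -> float:
    """Shear strain rate ε̇_zx = (v_upper − v_lower) / d, sign preserved."""
    if d <= 0:
        raise ValueError(f"thickness d must be > 0, got {d}")
    return (v_upper_x - v_lower_x) / d


def net_force_x(traj: Trajectory, frame_index: int) -> float:
    """Mean x-force (pN) over the upper leaflet's head heavy atoms."""
    if traj.forces is None:
        raise ValueError("trajectory carries no forces; attach them first")
    idx = traj.topology.role_indices(ROLE_UPPER)
    if idx.size == 0:
        raise ValueError("no upper head heavy atoms")
    fx = traj.forces[frame_index, idx, 0]
    if np.isnan(fx).any():
        missing = idx[np.isnan(fx)][0]
        raise ValueError(f"force missing for atom {missing} at frame {frame_index}")
    return float(np.mean(fx))


def kinematics_series(traj: Trajectory, d_mode: str = "fixed",
                      d: float = DEFAULT_THICKNESS,
                      grid: GridSpec | None = None,
                      velocity_method: str = "finite_difference") -> tuple:
    """Per-frame kinematics records (frames 1..n−1) plus mean ± SE summaries.

    ``d_mode`` "fixed" uses the constant ``d``; "per_frame" derives d
    from each frame's average local thickness (requires both leaflets
    to rasterize, hence a grid or a box tiled by the default spacing).
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 frames")
    if d_mode not in ("fixed", "per_frame"):
        raise ValueError(f"d_mode must be 'fixed' or 'per_frame', got {d_mode!r}")

    have_forces = traj.forces is not None
    records = []
    start = 1 if velocity_method == "finite_difference" else 0
    for i in range(start, len(traj)):
        vxu = leaflet_velocity(traj, "upper", i, "x", velocity_method)
        vxl = leaflet_velocity(traj, "lower", i, "x", velocity_method)
        vzu = leaflet_velocity(traj, "upper", i, "z", velocity_method)
        # |v_z| averaged per atom, not |mean|: the diagnostic's magnitude form
        if velocity_method == "finite_difference":
            idx = traj.topology.role_indices(ROLE_UPPER)
            dz = (traj.frames[i].positions[idx, 2]
                  - traj.frames[i - 1].positions[idx, 2])
            vz_abs = float(np.mean(np.abs(dz)) / traj.dt)
        else:
            vz = traj.velocities[i, traj.topology.role_indices(ROLE_UPPER), 2]
            vz_abs = float(np.mean(np.abs(vz)))
        if d_mode == "per_frame":
            upper = build_height_map(traj.frames[i], traj.topology, "upper", grid)
            lower = build_height_map(traj.frames[i], traj.topology, "lower", grid)
            _, _, d_i = local_thickness_map(upper, lower)
        else:
            d_i = d
        records.append(KinematicsRecord(
            time=traj.frames[i].time,
            v_x_upper=vxu, v_x_lower=vxl, v_x_rel=vxu - vxl,
            d=d_i, strain_rate=strain_rate(vxu, vxl, d_i),
            f_x_net=net_force_x(traj, i) if have_forces else float("nan"),
            v_z_upper_signed=vzu, v_z_upper_abs=vz_abs,
        ))

    def _summary(values: np.ndarray) -> dict:
        values = values[~np.isnan(values)]
        if values.size < 2:
            return {"mean": float("nan"), "se": float("nan"), "n": int(values.size)}
        return {
            "mean": float(values.mean()),
            "se": float(values.std(ddof=1) / np.sqrt(values.size)),
            "n": int(values.size),
        }

    summaries = {
        name: _summary(np.array([getattr(r, name) for r in records]))
        for name in ("strain_rate", "v_x_rel", "d", "f_x_net",
                     "v_z_upper_signed", "v_z_upper_abs")
    }
    return records, summaries
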