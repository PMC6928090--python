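"""End-to-end orchestration from a single YAML configuration.

One config lists the cases (topology/trajectory/optional forces plus
role rules); the pipeline rasterizes height maps for both leaflets,
computes deformation statistics and category tallies, kinematics,
protein-proximity metrics, and a cross-case summary with ANOVA.  All
analysis defaults (5 Å grid, k = 5, 4/8 Å thresholds, d = 42 Å, 0.1 ns
sampling, 5-cell ring margin, 30 × 40 Å² protein rectangle) are the
config defaults, so a minimal config runs the standard analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time as _time
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from . import compare, deformation, heightmap, kinematics, proximity
from .io import RoleRule, attach_forces, read_topology, read_trajectory
from .model import ROLE_PROTEIN

log = logging.getLogger("memdeform")


@dataclass
class CaseConfig:
    label: str
    topology: str
    trajectory: str
    forces: str | None = None
    force_unit: str = "pN"
    box: tuple | None = None
    role_map: list = field(default_factory=list)


@dataclass
class PipelineConfig:
    cases: list
    output_dir: str = "memdeform_report"
    seed: int = 0
    grid_spacing: float = 5.0
    dt: float = 0.1
    k: int = 5
    thresholds: tuple = deformation.DEFAULT_THRESHOLDS
    d_mode: str = "fixed"
    d: float = kinematics.DEFAULT_THICKNESS
    bbox: object = "auto"  # "auto", (w, h) or (x0, x1, y0, y1)
    margin_cells: int = proximity.DEFAULT_MARGIN_CELLS
    base_case: str | None = None

    def __post_init__(self) -> None:
        labels = [c.label for c in self.cases]
        if len(labels) != len(set(labels)):
            raise ValueError(f"case labels must be unique, got {labels}")
        t1, t2 = self.thresholds
        if not (0 < t1 < t2):
            raise ValueError(f"thresholds must be strictly increasing and positive: {self.thresholds}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cases = []
        for c in raw.pop("cases"):
            rules = [RoleRule(**r) for r in c.pop("role_map", [])]
            box = c.pop("box", None)
            cases.append(CaseConfig(role_map=rules,
                                    box=tuple(box) if box else None, **c))
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        if isinstance(raw.get("bbox"), list):
            raw["bbox"] = tuple(raw["bbox"])
        return cls(cases=cases, **raw)


def _write_heights_h5(path, maps_by_leaflet: dict) -> None:
    with h5py.File(path, "w") as f:
        for leaflet, maps in maps_by_leaflet.items():
            grp = f.create_group(leaflet)
            grp.create_dataset("heights", data=np.stack([m.heights for m in maps]))
            grp.create_dataset("valid", data=np.stack([m.valid for m in maps]))
            grp.create_dataset("times", data=np.array([m.time for m in maps]))
            g = maps[0].grid
            grp.attrs.update({"origin": g.origin, "spacing": g.spacing,
                              "nx": g.nx, "ny": g.ny})


def _run_case(case: CaseConfig, cfg: PipelineConfig, outdir: str) -> dict:
    t0 = _time.perf_counter()
    topology = read_topology(case.topology, case.role_map)
    traj = read_trajectory(topology, case.trajectory, dt=cfg.dt, box=case.box)
    if case.forces:
        attach_forces(traj, case.forces, unit=case.force_unit)
    grid = heightmap.GridSpec.from_box(traj.frames[0].box, cfg.grid_spacing)
    log.info("case %s: %d atoms, %d frames, grid %dx%d",
             case.label, traj.n_atoms, len(traj), grid.nx, grid.ny)

    maps = {leaflet: heightmap.height_maps_series(traj, leaflet, grid)
            for leaflet in ("upper", "lower")}
    _write_heights_h5(os.path.join(outdir, "heights.h5"), maps)

    records, deform_summary = deformation.deformation_time_series(maps["upper"], k=cfg.k)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        os.path.join(outdir, "deformation.csv"), index=False)

    tallies = [deformation.classify_cells(hm, cfg.thresholds) for hm in maps["upper"]]
    cat_rows = []
    for t in tallies:
        row = {"time": t.time, "n_valid": t.n_valid, "zero_deviation": t.zero_deviation}
        row.update({f"hill_{c}": t.hills[c] for c in deformation.CATEGORIES})
        row.update({f"valley_{c}": t.valleys[c] for c in deformation.CATEGORIES})
        cat_rows.append(row)
    pd.DataFrame(cat_rows).to_csv(os.path.join(outdir, "categories.csv"), index=False)
    dist = deformation.cumulative_category_distribution(tallies)
    pd.DataFrame({
        "category": list(deformation.CATEGORIES),
        "hills": dist["hills"], "valleys": dist["valleys"],
    }).to_csv(os.path.join(outdir, "category_distribution.csv"), index=False)

    thick = [heightmap.local_thickness_map(u, l)[2]
             for u, l in zip(maps["upper"], maps["lower"])]
    metrics = {
        "deformation": [r.deformation for r in records],
        "skewness": [r.skewness for r in records],
        "global_height": [heightmap.global_mean_height(hm) for hm in maps["upper"]],
        "thickness": thick,
    }

    kin_records, kin_summary = kinematics.kinematics_series(
        traj, d_mode=cfg.d_mode, d=cfg.d, grid=grid)
    pd.DataFrame([dataclasses.asdict(r) for r in kin_records]).to_csv(
        os.path.join(outdir, "kinematics.csv"), index=False)
    metrics["strain_rate"] = [r.strain_rate for r in kin_records]
    if traj.forces is not None:
        metrics["f_x_net"] = [r.f_x_net for r in kin_records]

    if topology.role_indices(ROLE_PROTEIN).size:
        mode = "auto" if cfg.bbox == "auto" else "fixed"
        rect = proximity.DEFAULT_BBOX_DIMS if cfg.bbox == "auto" else cfg.bbox
        prox_records, _ = proximity.proximity_series(
            traj, grid, bbox_mode=mode, bbox_rect=rect,
            margin_cells=cfg.margin_cells)
        prox_df = pd.DataFrame([dataclasses.asdict(r) for r in prox_records])
        prox_df["lift"] = prox_df["local_height"] - prox_df["global_height"]
        prox_df.to_csv(os.path.join(outdir, "prox.csv"), index=False)
        metrics["local_height"] = list(prox_df["local_height"])
        metrics["com_z"] = list(prox_df["com_z"])
        metrics["lift"] = list(prox_df["lift"])

    log.info("case %s: done in %.2f s (%d deformation records)",
             case.label, _time.perf_counter() - t0, len(records))
    return metrics


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every case, write per-case tables and the cross-case summary.

    A failing case is logged and skipped; the others continue.  Returns
    {case label -> metric series} for the cases that completed.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.output_dir, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        import memdeform
        log.info("memdeform %s | numpy %s | seed %d",
                 memdeform.__version__, np.__version__, config.seed)
        log.info("config: %s", json.dumps(dataclasses.asdict(config), default=str))

        case_metrics = {}
        for case in config.cases:
            outdir = os.path.join(config.output_dir, case.label)
            os.makedirs(outdir, exist_ok=True)
            try:
                case_metrics[case.label] = _run_case(case, config, outdir)
            except Exception:
                log.exception("case %s failed; continuing with remaining cases",
                              case.label)

        if case_metrics:
            base = config.base_case or next(iter(case_metrics))
            table = compare.summary_table(case_metrics, base_label=base)
            table.to_csv(os.path.join(config.output_dir, "summary.csv"), index=False)
        return case_metrics
    finally:
        log.removeHandler(handler)
        handler.close()
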