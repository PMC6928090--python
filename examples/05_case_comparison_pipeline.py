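"""Full pipeline on two cases plus the cross-case summary with ANOVA.

Two synthetic conditions — flowing (drift difference 4.2 Å/ns) and
stationary (no drift) — are written to disk as PDB/DCD/CSV fixtures and
pushed through the whole pipeline: height maps, deformation, category
tallies, kinematics, proximity and a mean ± SE summary table with
one-way ANOVA against the base case.
"""

import tempfile

import pandas as pd

import memdeform as md
from memdeform.pipeline import CaseConfig, PipelineConfig, run_pipeline

ROLE_MAP = [
    md.RoleRule("upper_head_heavy", resname="UHD"),
    md.RoleRule("lower_head_heavy", resname="LHD"),
    md.RoleRule("protein", resname="PRO"),
]

with tempfile.TemporaryDirectory() as root:
    cases = []
    for label, drift in (("flow", 4.2), ("stationary", 0.0)):
        outdir = f"{root}/{label}"
        import os
        os.makedirs(outdir)
        params = md.SyntheticParams(n_frames=8, seed=10, drift_upper_x=drift,
                                    head_density=0.08)
        traj, topology, truth = md.generate(params)
        paths = md.write_fixture(traj, topology, truth, outdir)
        cases.append(CaseConfig(label=label, topology=paths["topology"],
                                trajectory=paths["trajectory"],
                                forces=paths["forces"], box=(320.0, 360.0),
                                role_map=ROLE_MAP))

    cfg = PipelineConfig(cases=cases, output_dir=f"{root}/report",
                         base_case="flow")
    run_pipeline(cfg)
    table = pd.read_csv(f"{root}/report/summary.csv")

view = table[table.metric.isin(["strain_rate", "deformation"])]
print(view[["metric", "case", "mean", "se", "p_vs_base", "stars_vs_base"]]
      .to_string(index=False))

# The strain rate separates the two conditions sharply (≈0.1 ns⁻¹ vs 0,
# p ≪ 0.001), while the deformation statistic — driven by the identical
# undulation field — does not.
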