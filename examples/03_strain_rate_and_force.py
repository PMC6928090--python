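"""Leaflet strain rate and net driving force.

The shear strain rate is ε̇_zx = v̄_x,rel / d: the relative x-velocity
between the leaflets' head heavy atoms (finite differences of the
0.1-ns frames, minimum-image unwrapped) over the membrane thickness
d = 42 Å.  The net force is the mean x-force on the upper leaflet's
head heavy atoms.
"""

import memdeform as md
from memdeform.kinematics import kinematics_series

params = md.SyntheticParams(n_frames=20, seed=3, include_protein=False,
                            bump_amplitude=0.0)
traj, topology, _ = md.generate(params)

records, summaries = kinematics_series(traj, d_mode="fixed", d=42.0)
s = summaries["strain_rate"]
print(f"strain rate:   {s['mean']:.4f} ± {s['se']:.4f} ns⁻¹ over {s['n']} frames")
print(f"rel. velocity: {summaries['v_x_rel']['mean']:.3f} Å/ns "
      f"(imposed drift difference {params.drift_upper_x - params.drift_lower_x})")
f = summaries["f_x_net"]
print(f"net x-force:   {f['mean']:.4f} ± {f['se']:.4f} pN "
      f"(imposed mean {params.force_mean_x} pN)")

# The imposed 4.2 Å/ns drift difference divided by d = 42 Å gives
# exactly 0.1 ns⁻¹; the net force estimate fluctuates around the
# imposed 0.5 pN with SE ≈ σ/√(n_atoms · n_frames).
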