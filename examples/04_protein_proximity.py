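"""Protein-proximity metrics and the two contribution decompositions.

The local membrane height is averaged over head heavy atoms in the ring
of grid cells five cells beyond the rectangle enclosing the protein,
and compared with the global mean surface height and the protein's
centre-of-mass elevation.
"""

import memdeform as md
from memdeform.proximity import flow_decomposition, lift_decomposition, proximity_series

# flat surface (no undulations) so the measured lift is purely the
# protein's Gaussian bump; a wider bump reaches further into the ring
params = md.SyntheticParams(n_frames=10, seed=4, modes=(),
                            bump_amplitude=2.5, bump_width=25.0)
traj, topology, _ = md.generate(params)

records, summaries = proximity_series(traj, bbox_mode="fixed", bbox_rect=(30.0, 40.0))
print(f"local height : {summaries['local_height']['mean']:.2f} Å "
      f"(ring of {records[0].ring_cells} cells around the 30 x 40 Å² box)")
print(f"global height: {summaries['global_height']['mean']:.2f} Å")
print(f"protein COM z: {summaries['com_z']['mean']:.2f} Å")
print(f"lift (local − global): {summaries['lift']['mean']:.3f} Å")

# The decompositions on two pairs of case means (Å): a flow case vs its
# stationary counterpart, and a local vs global height pair.
flow = flow_decomposition(22.2, 19.5)
lift = lift_decomposition(26.0, 23.5)
print(f"per-surface flow contribution for means 22.2/19.5: {flow:.2f} Å (~1.4)")
print(f"protein-lift contribution for means 26/23.5:       {lift:.1f} Å")

# The generator's Gaussian bump (L = 2.5 Å, w = 15 Å) decays over the
# ring region, so the measured lift is a ring-averaged fraction of L.
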