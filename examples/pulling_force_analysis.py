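"""Pull a crosslinked fibril at 1 nN per chain and locate the stressed bonds.

Runs an overdamped Langevin constant-force pulling simulation of the
reduced-geometry fibril, recomputes time-averaged pairwise bond forces,
and ranks ten-residue windows along the crosslink acceptor chains.
"""

import numpy as np

import colmech as cm

fibril = cm.build_fibril(cm.mini_config())
params = cm.SimulationParams(
    seed=7, per_chain_force=1.0, n_steps=40_000, record_every=100,
    equilibration_fraction=0.4,
)
trajectory = cm.simulate_pulling(fibril, params)
table = cm.compute_pairwise_forces(trajectory)

xl = table.entries[table.entries.kind == "crosslink"]
print(f"beads: {fibril.n_sites}, retained frames: "
      f"{trajectory.n_frames - trajectory.equilibration_frames}")
print(f"crosslink bond tensions (nN): {np.round(xl.F.values, 2)}")

profile = cm.windowed_profile(table, w=10)
ranked = cm.locate_maxima(profile, "N")
top = ranked.iloc[0]
print(f"strongest N-terminal window: center residue {top.center:.1f}, "
      f"mean force {top.mean_force:.2f} nN, "
      f"{top.distance_to_crosslink:.1f} residues from the crosslink")
# Tension entering a helix at the segment boundary exits through its HLKNL
# crosslinks, so the strongest windows hug the N-terminal crosslink while
# telopeptide tails beyond the junctions stay near zero force.
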