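"""Map redox-active residue conservation onto the fibril axis.

Generates a vertebrate-like synthetic MSA with Tyr/Phe/Met enrichment
planted around the crosslink acceptor positions, counts the redox-active
residues in overlapping ten-residue slices along the fibril, and tests
enrichment near the crosslinks with a circular-shift permutation null.
"""

import numpy as np

import colmech as cm
from colmech.synthetic_data import default_msa_spec

fibril = cm.build_fibril(cm.mini_config())
spec = default_msa_spec(fibril, n_sequences=64, seed=3)
alignment = cm.generate_msa(spec)
mapping = cm.map_to_reference(alignment, "reference")

profile = cm.slice_counts(alignment, mapping, fibril, slice_len=10)
t = profile.table
best = t.iloc[int(np.argmax(t.union.values))]
print(f"sequences: {profile.n_sequences}, slices: {len(t)}")
print(f"peak redox-residue slice: z = {best.z_start:.2f}-{best.z_end:.2f} nm, "
      f"mean count {best.union:.1f} per sequence")

enr = cm.enrichment_near_crosslinks(profile, fibril, radius=1.5)
print(f"enrichment within 1.5 nm of crosslinks: ratio {enr.ratio:.2f}, "
      f"permutation p = {enr.p_value:.3f}")
# A ratio above 1 with a small p-value says the Tyr/Phe/Met clusters sit
# preferentially where the mechanical stress concentrates.
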