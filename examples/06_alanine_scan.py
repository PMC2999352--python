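"""Per-residue binding contributions vs a synthetic alanine scan.

Each contact residue's contribution is E_tot(native) - E_tot(residue mutated
to Ala, all four terms recomputed).  A synthetic ddG table (model signal plus
Gaussian noise at 25 % of the signal sd) plays the role of an experimental
alanine-scanning data set.
"""

import numpy as np

from interolog3d import build_profile, build_template, parse_structure
from interolog3d.matrices import derive_matrix_set
from interolog3d.synthetic import ToyDimerSpec, make_alascan_set, make_toy_dimer

spec = ToyDimerSpec(seed=11, n_contacts=26,
                    special_bond_plan={0: "disulfide", 1: "salt_bridge"})
pdb_text, _, _, _ = make_toy_dimer(spec)
template = build_template(parse_structure(pdb_text), "A", "B",
                          template_id="toy")
matrices, _ = derive_matrix_set([template])
profile_a = build_profile([template.chain_a_seq], chain_id="A")
profile_b = build_profile([template.chain_b_seq], chain_id="B")

clean = make_alascan_set(template, matrices, profile_a, profile_b, n=50,
                         noise_sd=0.0, seed=10)
signal_sd = float(np.std([r.contribution for r in clean]))
noisy = make_alascan_set(template, matrices, profile_a, profile_b, n=50,
                         noise_sd=0.25 * signal_sd, seed=10)

top = max(noisy, key=lambda r: r.contribution)
print(f"{len(noisy)} mutated contact residues, signal sd {signal_sd:.2f}")
print(f"largest predicted hot spot: chain {top.chain} position "
      f"{top.position} ({top.wild_type}), contribution {top.contribution:.2f}")
r = float(np.corrcoef([x.contribution for x in noisy],
                      [x.ddg for x in noisy])[0, 1])
print(f"Pearson r between contributions and noisy ddG: {r:.3f}")
# High-contribution residues are the interface hot spots; the correlation
# shows the score recovers the planted binding-energy signal through noise.
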