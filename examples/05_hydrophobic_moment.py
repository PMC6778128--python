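"""Eisenberg helical hydrophobic moment µH.

µH measures how strongly a helix segregates hydrophobic from
hydrophilic residues around its axis.  A periodic leucine face scores
high; a homopolymer (or a shuffled sequence) scores near zero.  A
protein-level mean below 0.5 marks homogeneously distributed residues
— helices with no strongly amphipathic face.
"""

import numpy as np

from coronastat import (assign_ss, helix_uH, make_toy_protein,
                        protein_mean_uH)

amphipathic = "LKKLLKELLEKLLKKLLE"   # hydrophobic every 3-4 positions
print(f"amphipathic 18-mer: µH = {helix_uH(amphipathic):.3f}")
print(f"homopolymer LEU18:  µH = {helix_uH(['LEU'] * 18):.2e}")

rng = np.random.default_rng(0)
shuffled = list(amphipathic)
rng.shuffle(shuffled)
print(f"shuffled 18-mer:    µH = {helix_uH(shuffled):.3f}")

protein = make_toy_protein()
m = protein_mean_uH(protein, assign_ss(protein))
print(f"toy protein: {len(m.per_helix)} helices, mean µH = {m.mean_uH:.4f} "
      f"({'<' if m.amphipathic_flag else '>='} 0.5 threshold: "
      f"{'homogeneous' if m.amphipathic_flag else 'amphipathic'})")
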