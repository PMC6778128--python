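"""Secondary-structure content and its change on perturbation.

Assigns H/E/T/C labels to an ideal helix and an ideal hairpin, then
partially melts the helix and reports the free-minus-perturbed content
change: a positive helix delta means helix was lost, the signature of
adsorption-induced reconfiguration.
"""

import numpy as np

from coronastat import (assign_ss, delta_ss, make_hairpin, make_ideal_helix,
                        ss_content)

helix = make_ideal_helix("A" * 20)
hairpin = make_hairpin("V" * 12)
for name, s in (("ideal helix", helix), ("ideal hairpin", hairpin)):
    ss = assign_ss(s)
    c = ss_content(ss)
    print(f"{name:<14s} labels: {''.join(ss.labels)}")
    print(f"{'':14s} helix {c.helix:.2f}  sheet {c.sheet:.2f}  "
          f"turn {c.turn:.2f}  coil {c.coil:.2f}")

free = ss_content(assign_ss(helix))
melted = helix.copy()
coords = melted.coords
rng = np.random.default_rng(5)
coords[len(coords) // 2:] += rng.normal(0, 0.15,
                                        (len(coords) - len(coords) // 2, 3))
melted.set_coords(coords)
adsorbed = ss_content(assign_ss(melted))
d = delta_ss(free, adsorbed)
print(f"helix change (free - perturbed): {d['helix']:+.2f} "
      "(positive = helix lost)")
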