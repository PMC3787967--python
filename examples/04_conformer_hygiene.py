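"""Hydroxyl rotamer resetting and conformer energy-window filtering.

A seeded hierarchy is built with an aromatic hydroxyl whose proton starts
~1.2 rad out of the ring plane — the kind of high-energy rotamer 3-D
builders frequently emit.  Resetting yields the two in-plane rotamers.  The
energy-window filter then trims a conformer ensemble at the standard window
widths.
"""

import math

from minidock import EnergyWindow, energy_window_filter, reset_hydroxyls
from minidock.fixtures import make_hierarchy
from minidock.flexibase import dihedral

mol = make_hierarchy(n_atoms=9, n_conformers=4, n_hydroxyls=1, seed=5)
o = next(a.index for a in mol.atoms if a.element == "O")
h = next(a.index for a in mol.atoms if a.element == "H")
ring_c, ref = 1, 0  # hydroxyl sits on ring atom 1; ring atom 0 is the reference

conf = mol.conformers[0]
start = dihedral(conf[ref], conf[ring_c], conf[o], conf[h])
print(f"builder O-H dihedral: {start:+.3f} rad (out of plane)")

for i, rot in enumerate(reset_hydroxyls(mol, conf)):
    d = dihedral(rot[ref], rot[ring_c], rot[o], rot[h])
    print(f"rotamer {i}: dihedral {d:+.6f} rad "
          f"({'syn in-plane' if abs(d) < 1e-6 else 'anti in-plane'})")

print()
mol.conformer_energies = [0.0, 10.0, 14.0, 31.0]  # kcal/mol above minimum
for width in (12.5, 15.0, 30.0, math.inf):
    kept = energy_window_filter(mol, EnergyWindow(width))
    print(f"energy window {width:>5} kcal/mol keeps energies "
          f"{kept.conformer_energies}")
print("the minimum-energy conformer is always retained; wider windows keep supersets")
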