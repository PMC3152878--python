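"""Charged-surface patches and alanine-scan hotspots on a bundle.

Seeds acidic bands into the two chains (the membrane-distal negative
patch arrangement), detects them as a surface cluster, and runs the
alanine scan over the coiled-coil interface.
"""

import numpy as np

from bundledock.mapping import alanine_scan, coulomb_potential, find_charge_patches
from bundledock.potential import ContactDefinition, derive_matrix, PairPotentialMatrix
from bundledock.synthetic import make_bundle, make_charged_bundle

st = make_charged_bundle({"A": (50, 70), "B": (85, 95)}, seed=5)
patches = find_charge_patches(st, -1, linkage_distance=10.0, min_size=3)
print(f"negative patches: {len(patches)}; largest has {patches[0].size} residues")
print("members:", patches[0].members[:8], "...")
print(f"mean screened-Coulomb potential at patch: {patches[0].mean_potential:.4f} "
      "(negative = acidic environment)")

train = []
for k in range(6):
    b = make_bundle(2, 28, "L", seed=k + 1)
    train.append((b, (["A"], ["B"])))
scores = derive_matrix(train).scores
matrix = PairPotentialMatrix(scores, 1.0, ContactDefinition("heavy", 4.5))
spots = alanine_scan(st, (["A"], ["B"]), matrix)
print("top hotspots (residue, ddG proxy, interactions lost):")
for h in [s for s in spots if s.scannable][:5]:
    print("  ", h.residue, round(h.ddg_proxy, 2), h.interactions_lost)
# The patch members concentrate in the declared 50-70 / 85-95 bands; the
# hotspot list ranks core leucines and interfacial ion pairs highest.
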