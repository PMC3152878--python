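"""Derive a residue-pair contact potential and check what it learned.

A synthetic training set plants a known 2x enrichment of Leu-Leu
contacts; the derived log-odds should sit near ln 2 = 0.693.  The same
machinery trained on ideal bundles then separates a native zipper from
register-shuffled decoys.
"""

import math

from bundledock.potential import derive_matrix, score_complex
from bundledock.synthetic import make_bundle, make_decoys, make_training_set

ts = make_training_set(50, {("L", "L"): 2.0}, seed=7)
m = derive_matrix(ts, ts.contact_def)
print(f"planted enrichment 2.0 -> S(L,L) = {m.score('L', 'L'):.3f} "
      f"(ln 2 = {math.log(2):.3f})")

train = []
for k in range(8):
    st = make_bundle((2, 3, 4)[k % 3], 28, "L", seed=k + 1)
    sides = ([c for i, c in enumerate(st.chains) if i % 2 == 0],
             [c for i, c in enumerate(st.chains) if i % 2 == 1])
    train.append((st, sides))
family = derive_matrix(train)

native = make_bundle(2, 28, "L", seed=77)
decoys = make_decoys(2, 28, "L", n_decoys=20, seed=77)
ns = score_complex(native, (["A"], ["B"]), family)
ds = sorted(score_complex(d, (["A"], ["B"]), family) for d in decoys)
print(f"native score {ns:.2f}; decoy scores {ds[0]:.2f} .. {ds[-1]:.2f}; "
      f"{sum(1 for s in ds if s <= ns)}/20 decoys below the native")
# A positive S(L,L) means Leu-Leu pairs occur above compositional chance
# at family interfaces; the native zipper concentrates exactly those.
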