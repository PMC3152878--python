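# bundledock

Structural modelling toolkit for small membrane-anchored protein
subcomplexes that assemble around a coiled coil — the situation of the
bacterial divisome proteins FtsB, FtsL and FtsQ, whose periplasmic
segments form a two-protein leucine zipper of unknown stoichiometry that
then recruits a globular partner.

Given two periplasmic sequences and (optionally) a partner structure,
the package answers the modelling questions that arise in that setting:

1. **Which oligomeric states are candidates?**  It enumerates the 1:1,
   2:1, 1:2 and 2:2 bundles (a pentamer is screened out unless bulky
   Trp/Tyr occupy core positions) and builds each one as an idealized
   parallel coiled coil from the Crick parameterization: minor helices
   of ~3.5 residues/turn wound left-handed (pitch −148 Å) on a
   superhelical axis at radius R0 (4.9/6.7/7.6 Å for 2/3/4 helices),
   with heptad positions *a*/*d* facing the core and a declared
   four-residue turn available at a helix-break motif (GDHS).
2. **Which candidates look native?**  An empirical residue-pair contact
   potential is derived from a training family of two-chain interfaces:
   S(i,j) = ln[(O(i,j)+p)/(E(i,j)+p)] with E(i,j) = T·f(i)·f(j)·(2−δij),
   where O are observed interchain contact counts, f the interface
   residue frequencies, T the contact total and p a pseudocount.
   Complexes are scored by summing S over interchain contacts.
3. **Where does the partner bind?**  Rigid-body docking by grid shape
   complementarity: both molecules are discretized (surface skin +1,
   receptor interior −15, ligand body +1), the translational correlation
   C(t) = Σx R(x)·L(x−t) is evaluated by FFT for a deterministic lattice
   of rotations, and poses are filtered by declared biological
   restraints — a maximum heavy-atom distance between named residue sets
   (6 Å by default) and a membrane-coplanarity slab for all chain
   N-termini.
4. **Is the interface credible?**  For any chain partition it computes
   buried area ([ASA₁+ASA₂−ASA_complex]/2, Shrake–Rupley on a 960-point
   Fibonacci sphere), interface residues (>1 Å² buried), geometric
   hydrogen bonds (D–A ≤ 3.9 Å, donor angle ≥ 90°), salt bridges
   (opposite formal charges ≤ 4 Å), polarity composition of interface
   and exposed surface, interaction densities per 100 Å², model
   dimensions, an alanine-scan hotspot list, charged surface patches
   under a screened-Coulomb potential, and a verdict against a
   mean-stable-complex reference row.

Every input needed by the tests and examples is generated synthetically
(ideal bundles, register-shuffled decoys, training sets with planted
contact enrichments, a groove/rod docking toy); nothing is downloaded.

## Worked example

```python
from bundledock.synthetic import make_training_set, make_bundle, make_decoys
from bundledock.potential import derive_matrix, score_complex

ts = make_training_set(50, {("L", "L"): 2.0}, seed=7)
m = derive_matrix(ts, ts.contact_def)
print(m.score("L", "L"))          # 0.675  (planted ln 2 = 0.693)
```

The derived log-odds recovers the planted two-fold Leu–Leu enrichment to
within sampling error.  Trained on ideal zipper bundles instead, the
same matrix separates a native bundle from register-shuffled decoys:

```text
native score 1.05; decoy scores -4.96 .. -1.17; 20/20 decoys below the native
```

Interface characterization of the built 1:1 bundle
(`python examples/04_interface_report.py`):

```text
interface ASA      957.9 A^2 (8.8% of complex surface)
composition        30.6% polar / 38.8% nonpolar / 30.6% charged
interactions       3 H-bonds (0.31/100 A^2), 0 salt bridges (0.00/100 A^2)
dimensions (x,y,z) (25.8, 23.0, 99.3) A
stability verdict   borderline (4/6 fields within band)
```

The composition sits where stable transient heteromultimers do (~32%
polar / ~40% nonpolar / ~28% charged); the bare ideal-geometry dimer
buries less area and fewer bonds than an evolved interface, hence the
borderline call.

Each script in `examples/` demonstrates one capability (building,
potential derivation, docking, interface analysis, patches/hotspots,
the full pipeline).  The same workflow is scriptable from the shell:

```bash
bundledock run-all --seed 1 --out pipeline_out
```

which writes, per stoichiometry, the bundle PDB, pose manifests,
interface/stability reports and hotspot tables, plus the two summary
tables (interface parameters; surface composition) with the reference
row appended, and a ranking of stoichiometries labelled
"static-analysis only".

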