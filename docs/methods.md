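# Methods

This note records the models, parameter choices and numerical
conventions behind `bundledock`, and what its synthetic benchmarks do
and do not establish about real data.

## Coiled-coil construction

Bundles are generated on the Crick coil-of-coils parameterization.  The
superhelical axis is the global z axis; chain *c* of an *n*-helix bundle
follows the curve M(t) = (R0·cos θ, R0·sin θ, d·t) with
θ = ω0·t + 2πc/n, where t is the residue index, d the axial rise per
residue and ω0 = 2π·d/P the superhelical phase advance for pitch P.  The
minor (α-helical) frequency is ω1 = 2π/3.5 per residue, which makes the
heptad exact: seven residues advance the phase by exactly two turns, so
shifting a register by seven letters reproduces the identical geometry.
Backbone atoms are placed from a frozen cylindrical template of an ideal
α helix (per-atom radius, phase and axial offset relative to CA, derived
once from standard internal coordinates); the template is expressed in
the local frame (outward radial, in-plane binormal, tangent) of the
superhelical curve, so the helix follows the supercoil without further
bookkeeping.

Defaults: R0 = 4.9 Å (dimer), 6.7 Å (trimer), 7.6 Å (tetramer);
P = −148 Å (left-handed); d = 1.51 Å/residue.  These are canonical
leucine-zipper-family values; they give a ~28-residue dimer the ~42 Å
axial length and 9.8 Å axis separation the tests verify.  The phase of
register position *a* defaults to the value that centres the *a*/*d*
core on the bundle axis (205.71° for 3.5 residues/turn).

Side chains beyond CB are an **idealized extension**, not rotamers: the
atoms of each residue type lie along the CA→CB direction at declared
distances, with small lateral splits for branched termini.  Three
declared adjustments keep this caricature physical: the extension
direction is tilted toward the chain tangent (side chains run along the
helix surface); its inward radial component is capped so no arm crosses
a core-exclusion cylinder of 2.4 Å around the bundle axis (the compact
rotamers core-facing long side chains adopt); and a deterministic
steric relaxation pushes interchain side-chain atoms apart to a 2.3 Å
floor, moving only atoms beyond CB.  The relaxation is a pure function
of the geometry and preserves bundle symmetry exactly (cyclic-relabel
RMSD below 1e-6 Å in the tests).  A declared helix break is rendered as
a radial outward bulge over the break span — a placeholder turn, not a
modelled loop.

Consequences: contacts and buried areas on built bundles are reliable at
the residue level (knobs-into-holes CB packing, a/d burial) but not at
the rotamer level; hydrogen-bond geometry within idealized side chains
is approximate.  All interface thresholds used downstream (4.5 Å
contacts, 3.9 Å H-bonds, 4 Å bridges) tolerate this.

Orientation is fixed all-parallel (membrane-anchored N-termini on one
side); antiparallel requests are rejected.  A clash check raises if any
interchain heavy-atom pair remains closer than 2.0 Å after relaxation.

## Stoichiometry enumeration

Exactly four candidates are produced for two distinct proteins A and B:
1A:1B, 2A:1B, 1A:2B and 2A:2B, chains placed alternately around the
axis; the 2:2 bundle is organised as two heterodimeric faces and is the
only spec that declares the helix-break turn (over the GDHS motif of the
B-protein when present), mirroring the straight-vs-broken helix
conformers a two-state chain can adopt.  Pentamers are admitted only
when Trp/Tyr occupy core positions in at least half the chains; wider
cores need that bulk.

## Residue-pair contact potential

`derive_matrix` computes S(i,j) = ln[(O(i,j)+p)/(E(i,j)+p)] with
E(i,j) = T·f(i)·f(j)·(2−δij).  Two conventions matter:

* **Contacts**: a residue pair is in contact when the minimum heavy-atom
  distance is ≤ 4.5 Å (`heavy`) or the CB–CB distance is ≤ 6.5 Å (`cb`);
  interchain only by default; each residue pair counts once.
* **Marginals**: f is the composition of the contact-participating
  residues (each counted once), not of contact endpoints.  With endpoint
  marginals, an interface dominated by one pair type — precisely a
  leucine-zipper core — is its own expectation and scores ~0; with
  residue marginals the multiplicity of core contacts is informative,
  which is what lets a family-trained matrix rank a native bundle above
  register-shuffled decoys.

Pseudocount p = 1 (Laplace); natural log; dimensionless scores; the
matrix is symmetric and finite by construction and serializes as a
20×20 TSV with a JSON sidecar (contact rule, pseudocount, training
digest).  Ranking breaks score ties by fewer interchain clashes
(< 2.5 Å), then input order.

The synthetic training generator draws contact types from a distribution
solved so that its own marginals remain the declared background while
each enriched pair (i,j) has probability e·f_i·f_j·(2−δ): the population
log-odds is then exactly ln e, and the derived matrix is an unbiased
estimator of it (naive product tilting would bias the estimate by up to
~0.3 natural-log units at e = 4 through marginal inflation).  The
background alphabet is a minimal coiled-coil interface alphabet —
L, I, A, E, K, uniform — chosen so every pair type has a usable count at
the 10,000-contact scale used in validation.

## Docking

Discretization uses the surface/interior encoding with the surface as an
**outward skin**: body cells (centre within an atom's van der Waals
radius; radii C 1.70, N 1.55, O 1.52, S 1.80 Å) carry the interior
value, and open-space cells within `surface_thickness` of the body carry
+1.  The receptor takes interior −15, the ligand is body-only at +1, so
the correlation rewards ligand volume on the receptor skin and punishes
core overlap.  The skin-outside convention is what makes van der Waals
contact detectable at 1.5 Å spacing without interpenetration.

The translational correlation is computed with forward/inverse real
FFTs, zero-padded to the full linear-correlation size; it matches direct
spatial correlation to ~1e-16 relative.  Rotations come from an Euler
z-y-z lattice at the given angular step with duplicate orientations
pruned via canonicalized, rounded quaternions; there is no randomness
anywhere in docking.  Scores are rounded at 1e-6 before ranking so FFT
float noise cannot perturb the deterministic (score, rotation index,
offset) order, and the per-rotation number of retained translations is a
fixed parameter (3) independent of `keep_top`, which makes pose lists
prefix-stable as `keep_top` grows.

Defaults (1.5 Å spacing, 15° step) are desk-scale: a full toy-system
scan is minutes on one CPU; finer settings are plain parameters.

Restraints: a pose passes a distance restraint iff the minimum
heavy-atom distance between the named receptor and ligand residue sets
is ≤ the cutoff (default 6 Å, the knock-out-mutation-derived contact
distance for the partner's recruitment face); it passes coplanarity iff
the N-terminal main-chain atoms of all chains lie within one slab
(default 8 Å) perpendicular to the receptor's bundle axis (dominant
principal axis of its CA trace) — the membrane-anchoring surrogate.
Filtering preserves order, is idempotent and annotates every pose.

For the 2:2 bundle the pipeline docks the partner twice, with a C2
shortcut: the first accepted pose is mirrored through the bundle axis
for the second copy.

## Interface analysis

SASA is Shrake–Rupley with a deterministic Fibonacci sphere (960 points,
probe 1.4 Å); isolated-atom error is ~1e-14 relative and two-sphere
overlap agrees with the closed form to < 1%.  Interface area is
([ASA₁+ASA₂−ASA_complex])/2; the "interface %" denominator is the
complex ASA (declared, configurable reading of an otherwise undefined
percentage).  Interface residues lose > 1 Å² on binding.  Hydrogen bonds
are heavy-atom geometric — donor/acceptor roles from the chemistry
table, D–A ≤ 3.9 Å, angle at the donor (nearest-heavy-atom antecedent)
≥ 90° — because hydrogens are never modelled.  Salt bridges pair
oppositely charged side-chain atoms (Asp/Glu carboxylate O⁻; Lys NZ,
Arg guanidinium N, His ring N⁺ — His is counted charged throughout)
within 4.0 Å, one bridge per residue pair at the minimum-distance atoms.
The source convention's wording ("at least 4 Å apart") is read as
*within* 4 Å, the standard sense of the cited rule; this is the single
deliberate reinterpretation in the module.

Composition percentages use the three-way scheme charged = {D,E,K,R,H},
polar = {S,T,N,Q,Y,C,W,G}, nonpolar = {A,V,L,I,P,F,M}, shipped as data
so alternate schemes are one edit.  Surface composition is over residues
with relative side-chain exposure > 5% of the shipped per-residue
maxima.  Dimensions are bounding-box extents after aligning the
principal axis to z.

Stability classification compares six fields (interface %, three
interface composition percentages, both densities) against the shipped
mean-stable-complex row (11.2 / 32.2 / 39.5 / 28.2 / 1 / 2–6) using a
ratio-symmetric band [ref/1.5, ref·1.5]; ≥ 5 fields in band is
consistent, 4 borderline, fewer inconsistent; an empty interface is
inconsistent outright.  The multiplicative band is chosen over an
additive ±50% band so that a sparse ~6% interface falls outside the band
around 11.2%, as the underlying comparison intends.

## Hotspots and electrostatics

The alanine scan truncates each interface residue to CB and reports
ddG_proxy = Δ(pair-potential score) + w_HB·Δ(H-bonds) + w_SB·Δ(salt
bridges), weights 1.0 each.  Because truncation removes only that
residue's atoms, the deltas are computed on the residue-versus-partner
restriction, which is provably identical to rescoring the whole mutant
complex (the tests assert this identity).  The proxy ranks residues by
interface contribution; it is **not** a physical free energy and is not
comparable to kJ/mol alanine-scan values.  Since CB–CB contacts are
blind to truncation, the pipeline rebinds the trained scores to the
heavy-atom rule for scanning.  Interaction-type annotations follow the
declared precedence SB > HB > VW.

The electrostatic surrogate is a screened Coulomb sum
φ(p) = Σ_q sign(q)·exp(−d/λ)/d over formally charged atoms, d floored at
1 Å, Debye length λ = 8 Å (≈150 mM); units arbitrary, sign meaningful.
It is evaluated at charged side-chain atoms rather than a molecular
surface mesh.  Charged patches are single-linkage clusters (≤ 10 Å
between charged atoms) of exposed like-charged residues, minimum size 2,
sorted by size.

## Pipeline and determinism

`run_pipeline` is a pure function of (config, seed): fixed float
formats, no timestamps inside outputs, a config digest in every header
line.  Stage failures are logged, recorded and do not stop independent
later stages.  The summary ranking — restraint-passing pose count, then
stability verdict, then pair-potential score — is this package's
declared synthesis of a qualitative model-selection narrative and is
labelled "static-analysis only" in the output; dynamical stability is
outside scope.  Pipeline interface reports use 240 sphere points (SASA
accurate to ~0.5%, ample for percentage/density precision); the library
default stays 960.

## What the synthetic benchmarks show

The generators emulate the *structure* of the real inputs — heptad
geometry, contact-type statistics with known enrichments, a
shape-complementary partner, banded surface charge — with exact ground
truth, so the tests establish correctness of the machinery: the FFT scan
equals brute force, the potential recovers planted log-odds without
bias, docking recovers a known fit and rejects a known misfit, bond
detection equals an O(N²) scan, the report arithmetic is exact, and the
whole pipeline is byte-deterministic.  They do not establish biological
accuracy on real structures: ideal-geometry bundles bury less area than
evolved interfaces, the idealized side chains flatten rotamer detail,
the shipped FtsB/FtsL-like sequences are constructed stand-ins (labelled
synthetic), and the toy partner has no real chemistry.  Conclusions
about a real complex require real coordinates for the partner and
family-curated training interfaces, both of which the module interfaces
accept directly.

## Known limitations

Backbone is ideal-helical everywhere outside declared breaks; breaks are
geometric placeholders; no rotamer sampling, no flexibility, no
electrostatics inside the docking score, no solvation or dynamics.  The
stability verdict is a coarse screen against one reference row, not an
energy model.
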