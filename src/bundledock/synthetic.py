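"""Synthetic inputs with known ground truth for every pipeline stage.

Generators are pure functions of their parameters and seed:

* ideal coiled-coil bundles with a chosen core residue and seeded
  surface composition;
* register-shuffled decoys of a bundle;
* pair-potential training sets whose contact-type distribution realizes
  declared enrichment factors exactly (in expectation) while preserving
  the background marginal composition, so the log-odds a derivation
  should recover is ln(enrichment) with no compositional bias;
* a slab receptor with a rectangular groove and a rod ligand of known
  diameter, for docking recovery tests;
* bundles with acidic residues seeded into declared sequence bands, for
  charged-patch detection.

The training-set background uses a minimal coiled-coil interface
alphabet (Leu/Ile/Ala core plus the Glu/Lys salt-bridge pair) rather
than all twenty residue types: contact statistics of coiled-coil
interfaces are dominated by a few residue classes, and the compact
alphabet gives every pair type a usable count at desk-scale contact
numbers.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .coiledcoil import (
    HEPTAD,
    BundleSpec,
    ChainSpec,
    CrickParameters,
    assign_register,
    build_bundle,
    default_radius,
)
from .potential import CB_CONTACTS, ContactDefinition
from .structure import Atom, Residue, Structure, three_letter

__all__ = [
    "GenerationError",
    "TrainingSet",
    "make_bundle",
    "make_decoys",
    "make_training_set",
    "make_groove_receptor",
    "make_rod_ligand",
    "make_charged_bundle",
    "TRAINING_ALPHABET",
]


class GenerationError(ValueError):
    pass


#: surface alphabet for seeded random solvent-facing positions
SURFACE_ALPHABET = "AEKQRS"
#: background alphabet of synthetic pair-potential training interfaces
TRAINING_ALPHABET = "LIAEK"


# ---------------------------------------------------------------------------
# bundles and decoys
# ---------------------------------------------------------------------------

def _bundle_sequence(length: int, core_residue: str, rng: np.random.Generator) -> str:
    reg = [HEPTAD[i % 7] for i in range(length)]
    out = []
    for r in reg:
        if r in ("a", "d"):
            out.append(core_residue)
        else:
            out.append(SURFACE_ALPHABET[rng.integers(len(SURFACE_ALPHABET))])
    return "".join(out)


def make_bundle(n_chains: int, length: int, core_residue: str = "L",
                seed: int = 0) -> Structure:
    """Ideal parallel bundle with ``core_residue`` at every a/d position.

    Chains alternate identity labels A/B; the register starts at 'a' and
    is recorded in the structure metadata.  Deterministic in (arguments,
    seed).
    """
    if length < 14:
        raise GenerationError("bundle length must be >= 14 (two heptads)")
    if n_chains not in (2, 3, 4):
        raise GenerationError("n_chains must be 2, 3 or 4")
    rng = np.random.default_rng(seed)
    chains = []
    register = "".join(HEPTAD[i % 7] for i in range(length))
    for k in range(n_chains):
        seq = _bundle_sequence(length, core_residue, rng)
        chains.append(ChainSpec(seq, register, 1, "AB"[k % 2], "ABCD"[k]))
    spec = BundleSpec(chains)
    st = build_bundle(spec, CrickParameters(superhelix_radius=default_radius(n_chains)))
    idents = ",".join(c.identity for c in chains)
    st.metadata = (f"synthetic bundle n={n_chains} len={length} core={core_residue} "
                   f"seed={seed} identities={idents} register={register}")
    return st


def make_decoys(n_chains: int, length: int, core_residue: str = "L",
                n_decoys: int = 20, seed: int = 0) -> list[Structure]:
    """Register-shuffled decoys: same composition, core packing destroyed.

    Each decoy permutes the native chain sequences with a seeded rng so
    that a/d positions receive arbitrary residues, then rebuilds the
    bundle on identical geometry.
    """
    rng = np.random.default_rng(seed)
    native = make_bundle(n_chains, length, core_residue, seed)
    seqs = ["".join(three_to_one(r.name) for r in native.chains[cid]) for cid in native.chains]
    register = "".join(HEPTAD[i % 7] for i in range(length))
    decoys = []
    for _ in range(n_decoys):
        chains = []
        for k, s in enumerate(seqs):
            perm = rng.permutation(len(s))
            shuffled = "".join(s[i] for i in perm)
            chains.append(ChainSpec(shuffled, register, 1, "AB"[k % 2], "ABCD"[k]))
        decoys.append(build_bundle(BundleSpec(chains)))
    return decoys


def three_to_one(resname: str) -> str:
    from .structure import one_letter

    return one_letter(resname)


# ---------------------------------------------------------------------------
# pair-potential training sets
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Synthetic two-chain interfaces with recorded contact ground truth."""

    interfaces: list[tuple[Structure, tuple[list[str], list[str]]]]
    realized_counts: Counter
    pair_probabilities: dict[tuple[str, str], float]
    enrichment: dict[tuple[str, str], float]
    contact_def: ContactDefinition = field(default_factory=lambda: CB_CONTACTS)

    def __iter__(self):
        return iter(self.interfaces)

    def __len__(self):
        return len(self.interfaces)


def _pair_distribution(letters: str, enrichment: dict[tuple[str, str], float]):
    """Solve for a contact-type distribution with declared log-odds.

    Enriched pairs get probability e_ij * f_i * f_j * (2 - delta) where f
    are the distribution's *own* marginals, pinned to the uniform
    background; unenriched pairs share the remaining mass as a product
    measure t_i t_j.  Solving the marginal-consistency system makes the
    population log-odds of each enriched pair exactly ln(e), so matrix
    derivation is unbiased.
    """
    nL = len(letters)
    idx = {a: i for i, a in enumerate(letters)}
    f = np.full(nL, 1.0 / nL)
    enr = np.ones((nL, nL))
    for (a, b), e in enrichment.items():
        if e <= 0:
            raise GenerationError("enrichment factors must be positive")
        if a not in idx or b not in idx:
            raise GenerationError(
                f"enriched pair ({a},{b}) outside training alphabet {letters!r}"
            )
        enr[idx[a], idx[b]] = enr[idx[b], idx[a]] = e
    enriched_mask = enr != 1.0

    def equations(t):
        g = np.empty(nL)
        for i in range(nL):
            acc = 0.0
            for j in range(nL):
                if enriched_mask[i, j]:
                    acc += enr[i, j] * f[i] * f[j]
                elif i == j:
                    acc += t[i] * t[i]
                else:
                    acc += t[i] * t[j]
            g[i] = acc - f[i]
        return g

    sol = root(equations, f.copy(), method="hybr")
    t = sol.x
    if not sol.success or np.any(t < 0):
        raise GenerationError(
            f"infeasible enrichment map {enrichment}: no valid contact distribution"
        )
    pairs: dict[tuple[str, str], float] = {}
    for i in range(nL):
        for j in range(i, nL):
            mult = 1.0 if i == j else 2.0
            if enriched_mask[i, j]:
                p = enr[i, j] * f[i] * f[j] * mult
            else:
                p = t[i] * t[j] * mult
            pairs[(letters[i], letters[j])] = p
    total = sum(pairs.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise GenerationError(
            f"enrichment map {enrichment} leaves non-unit probability mass ({total:.4f})"
        )
    return {k: v / total for k, v in pairs.items()}


def _contact_pair_residues(resname_a: str, resname_b: str, seq_id: int,
                           x: float) -> tuple[Residue, Residue]:
    """Two minimal residues facing each other with CB-CB = 5.0 A."""

    def mini(resname, cid, zsign):
        z = 2.5 * zsign
        ca = np.array([x, 0.0, z + 1.5 * zsign])
        atoms = [
            Atom("N", "N", ca + np.array([-1.2, 0.3 * zsign, 0.6 * zsign])),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + np.array([1.2, 0.3 * zsign, 0.6 * zsign])),
            Atom("O", "O", ca + np.array([1.6, 1.3 * zsign, 0.8 * zsign])),
        ]
        if resname != "GLY":
            atoms.append(Atom("CB", "C", np.array([x, 0.0, z])))
        return Residue(resname, seq_id, cid, atoms)

    return mini(resname_a, "A", +1), mini(resname_b, "B", -1)


def make_training_set(
    n_interfaces: int,
    enrichment: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
    contacts_per_interface: int = 200,
    letters: str = TRAINING_ALPHABET,
) -> TrainingSet:
    """Two-chain interfaces realizing declared contact-type enrichments.

    Every contact is an isolated facing residue pair (CB-CB 5.0 A, pairs
    spaced far apart), so the CB 6.5 A contact rule recovers exactly the
    drawn multiset; realized counts are recorded for oracle checks.
    """
    if n_interfaces < 1:
        raise GenerationError("need at least one interface")
    enrichment = {tuple(sorted(k)): v for k, v in (enrichment or {}).items()}
    probs = _pair_distribution(letters, enrichment)
    pair_list = list(probs)
    p = np.array([probs[k] for k in pair_list])
    rng = np.random.default_rng(seed)
    per_iface = [contacts_per_interface] * n_interfaces
    interfaces = []
    realized: Counter = Counter()
    for n_c in per_iface:
        counts = rng.multinomial(n_c, p)
        chain_a: list[Residue] = []
        chain_b: list[Residue] = []
        seq_id = 1
        for k, c in zip(pair_list, counts):
            for _ in range(c):
                a3, b3 = three_letter(k[0]), three_letter(k[1])
                # randomize which side carries which type
                if rng.random() < 0.5:
                    a3, b3 = b3, a3
                ra, rb = _contact_pair_residues(a3, b3, seq_id, 25.0 * seq_id)
                chain_a.append(ra)
                chain_b.append(rb)
                seq_id += 1
                realized[k] += 1
        st = Structure({"A": chain_a, "B": chain_b},
                       metadata=f"synthetic training interface seed={seed}")
        interfaces.append((st, (["A"], ["B"])))
    return TrainingSet(interfaces, realized, probs, enrichment)


# ---------------------------------------------------------------------------
# docking toys
# ---------------------------------------------------------------------------

def _point_structure(points: np.ndarray, chain_id: str, resname: str = "GLY") -> Structure:
    residues = [
        Residue(resname, i + 1, chain_id, [Atom("CA", "C", p)])
        for i, p in enumerate(points)
    ]
    return Structure({chain_id: residues})


def make_groove_receptor(groove_width: float = 12.0, groove_depth: float = 8.0,
                         seed: int = 0, size: float = 30.0,
                         thickness: float = 12.0, spacing: float = 2.0) -> Structure:
    """Pseudo-atomic slab with a rectangular groove along its x axis."""
    xs = np.arange(-size / 2, size / 2 + 1e-9, spacing)
    ys = np.arange(-size / 2, size / 2 + 1e-9, spacing)
    zs = np.arange(0.0, thickness + 1e-9, spacing)
    pts = []
    top = zs.max()
    for x in xs:
        for y in ys:
            for z in zs:
                in_groove = abs(y) < groove_width / 2 and z > top - groove_depth
                if not in_groove:
                    pts.append((x, y, z))
    if not pts:
        raise GenerationError("degenerate slab")
    return _point_structure(np.array(pts), "R")


def make_rod_ligand(length: float = 16.0, diameter: float = 7.0,
                    spacing: float = 2.0) -> Structure:
    """Cylindrical rod of CA-like pseudo-atoms along x, given diameter."""
    ring_r = max(diameter / 2.0 - 1.7, 0.0)  # atom centres inset by the C radius
    xs = np.arange(-length / 2, length / 2 + 1e-9, spacing)
    pts = []
    for x in xs:
        if ring_r < 0.1:
            pts.append((x, 0.0, 0.0))
        else:
            for ang in (0.0, 90.0, 180.0, 270.0):
                a = math.radians(ang)
                pts.append((x, ring_r * math.cos(a), ring_r * math.sin(a)))
    return _point_structure(np.array(pts), "L")


# ---------------------------------------------------------------------------
# charged bundles
# ---------------------------------------------------------------------------

def make_charged_bundle(
    acidic_bands: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    chain_layout: dict[str, tuple[int, int]] | None = None,
    basic_rate: float = 0.3,
) -> Structure:
    """Two-chain bundle with acidic residues seeded into declared bands.

    ``chain_layout`` maps chain id -> (start seq id, length); the default
    mimics the periplasmic segments of a membrane-proximal two-protein
    coiled coil (chain A 25-88, chain B 61-109).  Within the acidic bands
    every exposed (non-core) position becomes Glu/Asp; elsewhere exposed
    positions are Lys/Arg at ``basic_rate`` and neutral polar otherwise.
    """
    chain_layout = chain_layout or {"A": (25, 64), "B": (61, 49)}
    acidic_bands = {} if acidic_bands is None else acidic_bands
    rng = np.random.default_rng(seed)
    chains = []
    for k, (cid, (start, length)) in enumerate(chain_layout.items()):
        band = acidic_bands.get(cid)
        if band is not None and not (start <= band[0] <= band[1] <= start + length - 1):
            raise GenerationError(f"band {band} outside chain {cid}")
        seq = []
        for i in range(length):
            sid = start + i
            letter = HEPTAD[i % 7]
            if letter in ("a", "d"):
                seq.append("L")
            elif band is not None and band[0] <= sid <= band[1]:
                seq.append("ED"[rng.integers(2)])
            elif rng.random() < basic_rate:
                seq.append("KR"[rng.integers(2)])
            else:
                seq.append("QNSAT"[rng.integers(5)])
        register = "".join(HEPTAD[i % 7] for i in range(length))
        chains.append(ChainSpec("".join(seq), register, start, "AB"[k % 2], cid))
    st = build_bundle(BundleSpec(chains))
    st.metadata = f"synthetic charged bundle bands={acidic_bands} seed={seed}"
    return st
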