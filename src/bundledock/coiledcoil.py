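"""Parametric coiled-coil bundle construction.

Bundles are generated on Crick coil-of-coils geometry: each chain's
backbone follows an idealized alpha-helix (the "minor" helix) whose axis
winds around a common superhelical axis at radius ``R0`` with a declared
pitch (negative pitch = left-handed supercoil, the canonical case).
Heptad register letters a..g determine the minor-helix phase so that the
``a`` and ``d`` positions face the bundle core.  Side chains beyond CB are
placed by an idealized extension along the CA->CB vector with per-residue
declared lengths -- a deliberate simplification in place of rotamer
sampling, adequate for the contact/SASA tolerances used downstream.

The module also encodes the oligomer-enumeration policy for a two-protein
coiled-coil subcomplex: dimer, the two trimers, and a tetramer built as
two heterodimeric faces; pentamers are screened out unless bulky aromatic
residues (Trp/Tyr) occupy core positions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Residue, Structure, three_letter

__all__ = [
    "CrickParameters",
    "ChainSpec",
    "BundleSpec",
    "GeometryError",
    "RegisterError",
    "assign_register",
    "build_bundle",
    "enumerate_stoichiometries",
    "pentamer_admissible",
    "default_radius",
]

HEPTAD = "abcdefg"
CORE_POSITIONS = ("a", "d")
#: hydrophobics counted when auto-picking a register frame
CORE_HYDROPHOBICS = set("LIVM")

#: default superhelical radius (Angstrom) per helix count, canonical
#: GCN4-family values
DEFAULT_RADIUS = {2: 4.9, 3: 6.7, 4: 7.6}


def default_radius(n_chains: int) -> float:
    return DEFAULT_RADIUS[n_chains]


class GeometryError(ValueError):
    pass


class RegisterError(ValueError):
    pass


@dataclass
class CrickParameters:
    """Superhelix geometry.

    superhelix_radius
        R0, distance from the bundle axis to each chain axis (Angstrom).
    residues_per_turn
        minor-helix periodicity in the superhelical frame; 3.5 makes the
        heptad repeat exact (two turns per seven residues).
    rise_per_residue
        axial translation per residue along the bundle axis (Angstrom).
    pitch
        superhelix pitch (Angstrom); the sign encodes handedness and the
        canonical left-handed supercoil is negative.
    interface_phase_deg
        minor-helix phase assigned to register position 'a'; the default
        centres the a/d core on the bundle axis.
    """

    superhelix_radius: float = 4.9
    residues_per_turn: float = 3.5
    rise_per_residue: float = 1.51
    pitch: float = -148.0
    interface_phase_deg: float | None = None

    def __post_init__(self) -> None:
        if self.superhelix_radius <= 0:
            raise ValueError("superhelix radius must be positive")
        if not 1.0 < self.rise_per_residue < 2.0:
            raise ValueError("rise per residue outside the helical range (1, 2) A")
        if self.pitch == 0:
            raise ValueError("pitch must be nonzero")
        if self.interface_phase_deg is None:
            # phase bisecting a and d points at the bundle axis (180 deg)
            omega1 = 360.0 / self.residues_per_turn
            self.interface_phase_deg = 180.0 + (360.0 - (3.0 * omega1) % 360.0) / 2.0

    @property
    def omega1_deg(self) -> float:
        """Minor-helix phase advance per residue (degrees)."""
        return 360.0 / self.residues_per_turn

    @property
    def omega0_deg(self) -> float:
        """Superhelical phase advance per residue (degrees, signed)."""
        return 360.0 * self.rise_per_residue / self.pitch


# ---------------------------------------------------------------------------
# heptad registers
# ---------------------------------------------------------------------------

def assign_register(sequence: str, anchor_positions: list[int] | None = None) -> str:
    """Assign heptad letters to ``sequence``.

    ``anchor_positions`` are 1-based indices forced to position 'a'; they
    must agree modulo 7.  Without anchors the frame maximizing Leu/Ile/
    Val/Met occupancy of the a and d positions is chosen (ties to the
    lowest frame offset).
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    if anchor_positions:
        offsets = {(p - 1) % 7 for p in anchor_positions}
        if len(offsets) > 1:
            raise RegisterError(
                f"anchor positions {anchor_positions} are not congruent modulo 7"
            )
        off = offsets.pop()
    else:
        def core_count(off: int) -> int:
            reg = [HEPTAD[(i - off) % 7] for i in range(n)]
            return sum(1 for i, c in enumerate(sequence) if reg[i] in CORE_POSITIONS and c in CORE_HYDROPHOBICS)

        off = max(range(7), key=lambda o: (core_count(o), -o))
    return "".join(HEPTAD[(i - off) % 7] for i in range(n))


def _register_phases(register: str, omega1_deg: float, phase_a_deg: float) -> np.ndarray:
    """Cumulative minor-helix phase per residue from register letters.

    Advances by omega1 * (letter step) between consecutive residues, which
    follows the cyclic a..g order and absorbs declared register jumps at
    breaks.
    """
    idx = [HEPTAD.index(c) for c in register]
    phases = np.empty(len(idx))
    phases[0] = phase_a_deg + omega1_deg * idx[0]
    for i in range(1, len(idx)):
        step = (idx[i] - idx[i - 1]) % 7
        phases[i] = phases[i - 1] + omega1_deg * step
    return phases


def validate_register(register: str) -> None:
    for a, b in zip(register, register[1:]):
        if a not in HEPTAD or b not in HEPTAD:
            raise RegisterError(f"invalid register letter in {register!r}")


# ---------------------------------------------------------------------------
# bundle specification
# ---------------------------------------------------------------------------

@dataclass
class ChainSpec:
    sequence: str  # 1-letter codes
    register: str
    start_seq_id: int = 1
    identity: str = "A"  # protein identity label (e.g. FtsB / FtsL)
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.register):
            raise ValueError("sequence and register lengths differ")
        validate_register(self.register)


@dataclass
class BundleSpec:
    """Declarative description of a parallel coiled-coil bundle."""

    chains: list[ChainSpec]
    orientation: str = "parallel"
    #: (chain index, (first seq_id, last seq_id), turn type)
    breaks: list[tuple[int, tuple[int, int], str]] = field(default_factory=list)
    #: for 4-helix bundles: chain-index pairs forming heterodimeric faces
    pairing: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 2 <= len(self.chains) <= 4:
            raise ValueError("bundles must have 2 to 4 chains")
        if self.orientation != "parallel":
            raise GeometryError(
                "only all-parallel bundles are supported (membrane-anchored "
                "N-termini on one side); antiparallel topologies are rejected"
            )
        for ci, (lo, hi), _ in self.breaks:
            ch = self.chains[ci]
            first, last = ch.start_seq_id, ch.start_seq_id + len(ch.sequence) - 1
            if not (first <= lo <= hi <= last):
                raise ValueError(f"break {lo}-{hi} outside chain {ci} ({first}-{last})")

    @property
    def composition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ch in self.chains:
            out[ch.identity] = out.get(ch.identity, 0) + 1
        return out


# ---------------------------------------------------------------------------
# idealized helix template (cylindrical coordinates relative to CA)
# ---------------------------------------------------------------------------

#: backbone atoms of an idealized alpha helix expressed in the minor-helix
#: cylinder frame as (radius A, phase offset deg, axial offset A) relative
#: to CA; derived once from standard internal coordinates
#: (phi/psi ~ -62/-41, 100 deg/residue) and frozen here.
HELIX_TEMPLATE: dict[str, tuple[str, float, float, float]] = {
    "N": ("N", 1.525, -25.89, -0.923),
    "CA": ("C", 2.283, 0.00, 0.000),
    "C": ("C", 1.697, 26.60, 1.078),
    "O": ("O", 2.042, 21.53, 2.248),
    "CB": ("C", 3.301, 17.20, -0.776),
}

#: idealized side-chain extension beyond CB: per residue, atoms given as
#: (name, element, distance from CA along the CA->CB direction, lateral
#: offset).  Declared simple geometry, not a rotamer library.
SIDE_CHAIN_EXTENSION: dict[str, list[tuple[str, str, float, float]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "O", 2.9, 0.0)],
    "CYS": [("SG", "S", 3.1, 0.0)],
    "THR": [("OG1", "O", 2.8, 0.7), ("CG2", "C", 2.8, -0.8)],
    "VAL": [("CG1", "C", 2.7, 0.8), ("CG2", "C", 2.7, -0.8)],
    "LEU": [("CG", "C", 2.9, 0.0), ("CD1", "C", 4.0, 0.8), ("CD2", "C", 4.0, -0.8)],
    "ILE": [("CG1", "C", 2.9, 0.6), ("CG2", "C", 2.6, -0.9), ("CD1", "C", 4.2, 0.6)],
    "MET": [("CG", "C", 2.9, 0.0), ("SD", "S", 4.4, 0.4), ("CE", "C", 5.8, 0.0)],
    "PRO": [("CG", "C", 2.4, 0.8), ("CD", "C", 1.9, 1.5)],
    "PHE": [("CG", "C", 3.0, 0.0), ("CD1", "C", 3.9, 1.1), ("CD2", "C", 3.9, -1.1),
            ("CZ", "C", 5.4, 0.0)],
    "TYR": [("CG", "C", 3.0, 0.0), ("CD1", "C", 3.9, 1.1), ("CD2", "C", 3.9, -1.1),
            ("CZ", "C", 5.4, 0.0), ("OH", "O", 6.8, 0.0)],
    "TRP": [("CG", "C", 3.0, 0.0), ("CD1", "C", 3.9, 1.0), ("NE1", "N", 5.0, 1.2),
            ("CE2", "C", 5.0, -0.2), ("CZ2", "C", 6.3, 0.0)],
    "ASP": [("CG", "C", 3.0, 0.0), ("OD1", "O", 4.1, 0.9), ("OD2", "O", 4.1, -0.9)],
    "GLU": [("CG", "C", 2.9, 0.0), ("CD", "C", 4.2, 0.0), ("OE1", "O", 5.3, 0.9),
            ("OE2", "O", 5.3, -0.9)],
    "ASN": [("CG", "C", 3.0, 0.0), ("OD1", "O", 4.1, 0.9), ("ND2", "N", 4.1, -0.9)],
    "GLN": [("CG", "C", 2.9, 0.0), ("CD", "C", 4.2, 0.0), ("OE1", "O", 5.3, 0.9),
            ("NE2", "N", 5.3, -0.9)],
    "LYS": [("CG", "C", 2.9, 0.0), ("CD", "C", 4.2, 0.3), ("CE", "C", 5.5, 0.0),
            ("NZ", "N", 6.5, 0.0)],
    "ARG": [("CG", "C", 2.9, 0.0), ("CD", "C", 4.2, 0.3), ("NE", "N", 5.4, 0.0),
            ("CZ", "C", 6.5, 0.0), ("NH1", "N", 7.3, 0.9), ("NH2", "N", 7.3, -0.9)],
    "HIS": [("CG", "C", 3.0, 0.0), ("ND1", "N", 4.0, 1.0), ("CD2", "C", 4.0, -1.0),
            ("CE1", "C", 5.2, 0.7), ("NE2", "N", 5.1, -0.4)],
}


# ---------------------------------------------------------------------------
# bundle construction
# ---------------------------------------------------------------------------

def _chain_frames(params: CrickParameters, n_res: int, chain_phase_deg: float):
    """Per-residue superhelix points and local orthonormal frames.

    Returns (M, u0, e2, T): the chain-axis point, the outward radial unit
    vector, the in-plane binormal and the unit tangent for each residue.
    """
    d = params.rise_per_residue
    R0 = params.superhelix_radius
    w0 = math.radians(params.omega0_deg)
    t = np.arange(n_res)
    theta = w0 * t + math.radians(chain_phase_deg)
    M = np.stack([R0 * np.cos(theta), R0 * np.sin(theta), d * t], axis=1)
    u0 = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
    T = np.stack([-R0 * w0 * np.sin(theta), R0 * w0 * np.cos(theta),
                  np.full_like(theta, d)], axis=1)
    T /= np.linalg.norm(T, axis=1, keepdims=True)
    e2 = np.cross(T, u0)
    return M, u0, e2, T


def _place_residue(resname: str, M, u0, e2, T, psi_deg: float) -> list[Atom]:
    atoms: list[Atom] = []
    backbone = dict(HELIX_TEMPLATE)
    if resname == "GLY":
        backbone.pop("CB")
    pos: dict[str, np.ndarray] = {}
    for name, (element, r, dphi, dz) in backbone.items():
        ang = math.radians(psi_deg + dphi)
        p = M + r * math.cos(ang) * u0 + r * math.sin(ang) * e2 + dz * T
        pos[name] = p
        atoms.append(Atom(name, element, p))
    ext = SIDE_CHAIN_EXTENSION.get(resname, [])
    if ext and "CB" in pos:
        direction = pos["CB"] - pos["CA"]
        direction /= np.linalg.norm(direction)
        # tilt the extension toward the chain direction: side chains run
        # along the helix surface instead of radiating perpendicular to it
        direction = direction + SIDE_CHAIN_AXIAL_TILT * T
        direction /= np.linalg.norm(direction)
        max_dist = max(d for _, _, d, _ in ext)
        direction = _limit_inward(direction, pos["CA"], max_dist)
        lateral = np.cross(direction, T)
        nl = np.linalg.norm(lateral)
        lateral = lateral / nl if nl > 1e-8 else u0
        for name, element, dist, lat in ext:
            atoms.append(Atom(name, element, pos["CA"] + dist * direction + lat * lateral))
    return atoms


#: axial tilt mixed into the CA->CB extension direction
SIDE_CHAIN_AXIAL_TILT = 0.35
#: cylindrical exclusion radius (A) around the bundle axis; side-chain
#: extensions are bent so they cannot reach inside it, emulating the
#: compact rotamers that core-facing long side chains adopt
CORE_EXCLUSION_RADIUS = 2.4


def _limit_inward(direction: np.ndarray, ca: np.ndarray, max_dist: float) -> np.ndarray:
    """Cap the component of ``direction`` pointing at the bundle (z) axis.

    The farthest extension atom travels ``max_dist`` along the direction;
    its inward radial travel is limited to the clearance between the CA
    and the core exclusion cylinder, so no side chain crosses the core.
    """
    rho = math.hypot(ca[0], ca[1])
    radial = np.array([ca[0] / rho, ca[1] / rho, 0.0]) if rho > 1e-9 else np.array([1.0, 0.0, 0.0])
    inward = -float(np.dot(direction, radial))  # >0 means pointing at the axis
    if inward <= 0:
        return direction
    clearance = max(rho - CORE_EXCLUSION_RADIUS, 0.0)
    allowed = min(clearance / max_dist, 1.0)
    if inward <= allowed:
        return direction
    # rebuild a unit vector with the inward component clamped exactly and
    # the orthogonal part rescaled, so the cap survives normalization
    other = direction + inward * radial
    n_other = np.linalg.norm(other)
    if n_other < 1e-9:
        other, n_other = np.array([0.0, 0.0, 1.0]), 1.0
    return -allowed * radial + other * (math.sqrt(1.0 - allowed**2) / n_other)


def build_bundle(spec: BundleSpec, params: CrickParameters | None = None) -> Structure:
    """Generate an all-atom (idealized) bundle from a :class:`BundleSpec`.

    Chains are offset by 360/n degrees around the superhelical axis (the
    global z axis); register positions a/d face the axis.  Declared helix
    breaks are rendered as a short non-helical excursion: the affected
    residues are displaced radially outward on a smooth bulge joining the
    two Crick segments.

    Raises :class:`GeometryError` if any interchain heavy-atom pair comes
    closer than 2.0 A.
    """
    n = len(spec.chains)
    if params is None:
        params = CrickParameters(superhelix_radius=default_radius(n))
    chains: dict[str, list[Residue]] = {}
    break_lookup: dict[tuple[int, int], int] = {}
    for ci, (lo, hi), _kind in spec.breaks:
        for j, sid in enumerate(range(lo, hi + 1)):
            break_lookup[(ci, sid)] = j

    for ci, ch in enumerate(spec.chains):
        n_res = len(ch.sequence)
        phases = _register_phases(ch.register, params.omega1_deg, params.interface_phase_deg)
        M, u0, e2, T = _chain_frames(params, n_res, 360.0 * ci / n)
        residues: list[Residue] = []
        for i, code in enumerate(ch.sequence):
            resname = three_letter(code)
            seq_id = ch.start_seq_id + i
            atoms = _place_residue(resname, M[i], u0[i], e2[i], T[i], phases[i])
            j = break_lookup.get((ci, seq_id))
            if j is not None:
                # non-helical turn: radial outward bulge over the break span
                bulge = 1.8 * math.sin(math.pi * (j + 1) / 5.0)
                for a in atoms:
                    a.coord = a.coord + bulge * u0[i]
            residues.append(Residue(resname, seq_id, ch.chain_id, atoms))
        chains[ch.chain_id] = residues

    st = Structure(chains, metadata=f"bundle n={n} composition={spec.composition}")
    _relax_side_chains(st)
    _check_clashes(st, min_dist=2.0)
    return st


BACKBONE_ATOMS = {"N", "CA", "C", "O", "CB"}


def _relax_side_chains(st: Structure, target: float = 2.3, max_iter: int = 80) -> None:
    """Deterministic steric relaxation of the idealized side chains.

    Straight-arm extensions of adjacent chains can interdigitate; pairs of
    interchain heavy atoms closer than ``target`` are pushed apart along
    their separation vector.  Only extension atoms beyond CB move, so the
    Crick backbone is untouched.  The procedure is a pure function of the
    input geometry (no randomness) and preserves any symmetry of the
    bundle.
    """
    entries = []  # (chain_id, movable, coord index)
    coords = []
    for res in st.residues():
        for atom in res.atoms:
            entries.append((res.chain_id, atom.name not in BACKBONE_ATOMS, atom))
            coords.append(atom.coord)
    X = np.array(coords)
    chain_ids = np.array([e[0] for e in entries])
    movable = np.array([e[1] for e in entries])
    for _ in range(max_iter):
        tree = cKDTree(X)
        pairs = tree.query_pairs(target, output_type="ndarray")
        if len(pairs) == 0:
            break
        inter = pairs[chain_ids[pairs[:, 0]] != chain_ids[pairs[:, 1]]]
        inter = inter[movable[inter[:, 0]] | movable[inter[:, 1]]]
        if len(inter) == 0:
            break
        disp = np.zeros_like(X)
        moved = False
        for i, j in inter:
            v = X[i] - X[j]
            d = np.linalg.norm(v)
            v = v / d if d > 1e-9 else np.array([0.0, 0.0, 1.0])
            push = 0.5 * (target - d) + 0.05
            if movable[i] and movable[j]:
                disp[i] += push * v
                disp[j] -= push * v
            elif movable[i]:
                disp[i] += 2 * push * v
            else:
                disp[j] -= 2 * push * v
            moved = True
        if not moved:
            break
        X = X + disp
    for (cid, mv, atom), x in zip(entries, X):
        atom.coord = x


def _check_clashes(st: Structure, min_dist: float) -> None:
    ids = list(st.chains)
    for ca, cb in itertools.combinations(ids, 2):
        xa = st.coords([ca])
        xb = st.coords([cb])
        tree = cKDTree(xb)
        d, idx = tree.query(xa, k=1)
        if np.min(d) < min_dist:
            i = int(np.argmin(d))
            raise GeometryError(
                f"interchain clash between chains {ca} and {cb}: "
                f"{np.min(d):.2f} A at atom index {i}"
            )


# ---------------------------------------------------------------------------
# stoichiometry enumeration
# ---------------------------------------------------------------------------

def enumerate_stoichiometries(
    protein_a: str,
    protein_b: str,
    name_a: str = "A",
    name_b: str = "B",
    register_a: str | None = None,
    register_b: str | None = None,
    start_a: int = 1,
    start_b: int = 1,
    break_motif: str = "GDHS",
) -> list[BundleSpec]:
    """Enumerate the candidate oligomers of a two-protein coiled coil.

    Returns four specs -- 1:1, 2:1, 1:2 and 2:2 -- with chains placed
    alternately around the axis.  The 2:2 bundle is built as two
    heterodimeric faces (pairing recorded on the bundle spec) and, if the second
    protein carries the helix-break motif (``GDHS`` by default), a
    four-residue turn is declared over that motif for the 2:2 bundle only,
    mirroring the two admissible conformations of a straight-vs-broken
    helix.
    """
    reg_a = register_a or assign_register(protein_a)
    reg_b = register_b or assign_register(protein_b)
    if protein_a == protein_b:
        warnings.warn("identical proteins given; stoichiometries collapse to homomers")

    def chain(identity, seq, reg, start, cid):
        return ChainSpec(seq, reg, start, identity, cid)

    cids = "ABCD"
    specs: list[BundleSpec] = []
    layouts = [
        [(name_a, protein_a, reg_a, start_a), (name_b, protein_b, reg_b, start_b)],
        [(name_a, protein_a, reg_a, start_a), (name_b, protein_b, reg_b, start_b),
         (name_a, protein_a, reg_a, start_a)],
        [(name_b, protein_b, reg_b, start_b), (name_a, protein_a, reg_a, start_a),
         (name_b, protein_b, reg_b, start_b)],
        [(name_a, protein_a, reg_a, start_a), (name_b, protein_b, reg_b, start_b),
         (name_a, protein_a, reg_a, start_a), (name_b, protein_b, reg_b, start_b)],
    ]
    for layout in layouts:
        chains = [chain(idn, seq, reg, start, cids[k])
                  for k, (idn, seq, reg, start) in enumerate(layout)]
        pairing = [(0, 1), (2, 3)] if len(layout) == 4 else []
        breaks = []
        if len(layout) == 4 and break_motif:
            for k, ch in enumerate(chains):
                pos = ch.sequence.find(_motif_one_letter(break_motif))
                if ch.identity == name_b and pos >= 0:
                    lo = ch.start_seq_id + pos
                    breaks.append((k, (lo, lo + len(break_motif) - 1), "turn"))
        specs.append(BundleSpec(chains, breaks=breaks, pairing=pairing))
    return specs


def _motif_one_letter(motif: str) -> str:
    return motif.upper()


def pentamer_admissible(sequences: list[str], registers: list[str]) -> tuple[bool, str]:
    """Screen for five-helix admissibility.

    A pentamer is considered only when bulky aromatic residues (Trp/Tyr)
    occupy core a/d positions in at least half of the chains; coiled coils
    lacking them cannot stabilize the wider five-helix core.
    """
    if len(sequences) != len(registers):
        raise ValueError("sequences and registers differ in length")
    hits = 0
    for seq, reg in zip(sequences, registers):
        if len(seq) != len(reg):
            raise ValueError("sequence/register length mismatch")
        if any(c in "WY" and r in CORE_POSITIONS for c, r in zip(seq, reg)):
            hits += 1
    ok = len(sequences) > 0 and hits >= math.ceil(len(sequences) / 2)
    reason = (
        f"bulky aromatic (Trp/Tyr) at core a/d positions in {hits}/{len(sequences)} chains; "
        + ("admissible" if ok else "pentamer excluded for lack of bulky hydrophobic core residues")
    )
    return ok, reason
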