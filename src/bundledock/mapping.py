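"""Hotspot mapping and charged-surface-patch detection.

Hotspots are located by a computational alanine scan: each interface
residue's side chain is truncated to CB and the complex rescored.  The
reported ddG proxy is the pair-potential score lost plus weighted counts
of hydrogen bonds and salt bridges lost; it ranks residues by their
contribution to the interface but is an arbitrary-unit proxy, not a
physical free energy.

Electrostatic character of the surface is summarized with a screened
Coulomb potential phi(p) = sum_q sign(q) exp(-d/lambda)/d over formally
charged side-chain atoms (Debye length lambda, default 8 A, roughly
physiological ionic strength), and charged patches are single-linkage
clusters of exposed like-charged residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from .interface import (
    EXPOSURE_CUTOFF,
    detect_hbonds,
    detect_salt_bridges,
    interface_residues,
    compute_sasa,
    _sidechain_sasa,
)
from .potential import PairPotentialMatrix, extract_contacts, score_complex
from .structure import CHEMISTRY, Structure, charged_atoms

__all__ = [
    "HotspotResult",
    "ChargePatch",
    "alanine_scan",
    "coulomb_potential",
    "find_charge_patches",
]

SIDE_CHAIN_STUB = {"N", "CA", "C", "O", "CB", "OXT"}
DEBYE_LENGTH = 8.0


@dataclass
class HotspotResult:
    residue: tuple[str, int, str]  # chain, seq_id, residue name
    ddg_proxy: float
    interactions_lost: list[str]   # subset of {"SB", "HB", "VW"}
    partner_chain: str | None
    scannable: bool = True


def _truncated(structure: Structure, key: tuple[str, int]) -> Structure:
    out = structure.copy()
    for res in out.chains[key[0]]:
        if res.seq_id == key[1]:
            res.atoms = [a for a in res.atoms if a.name in SIDE_CHAIN_STUB]
    return out


def _involves(bond_end: tuple[str, int, str], key: tuple[str, int]) -> bool:
    return bond_end[0] == key[0] and bond_end[1] == key[1]


def alanine_scan(
    complex_structure: Structure,
    partition,
    matrix: PairPotentialMatrix,
    w_hbond: float = 1.0,
    w_salt_bridge: float = 1.0,
    interface_residue_keys: list[tuple[str, int]] | None = None,
) -> list[HotspotResult]:
    """Alanine-substitution rescoring of every interface residue.

    Each interface residue's side chain is truncated to CB and the
    interchain pair-potential score, hydrogen bonds and salt bridges
    recomputed; since truncation only removes that residue's atoms, the
    deltas are evaluated on the residue-versus-partner-side restriction,
    which equals a full complex rescoring.  Gly/Ala have nothing to
    truncate and are annotated non-scannable with ddG 0.  Interaction
    annotations are ordered by the declared precedence SB > HB > VW.
    ``interface_residue_keys`` (e.g. from a precomputed report) skips the
    surface-area pass that locates interface residues.
    """
    base_hb = detect_hbonds(complex_structure, partition)
    base_sb = detect_salt_bridges(complex_structure, partition)
    if interface_residue_keys is None:
        ifres = interface_residues(complex_structure, partition)
    else:
        wanted = {tuple(k) for k in interface_residue_keys}
        ifres = [r for r in complex_structure.residues(list(partition[0]) + list(partition[1]))
                 if r.key in wanted]

    side1 = set(partition[0])
    results: list[HotspotResult] = []
    for res in ifres:
        rec = (res.chain_id, res.seq_id, res.name)
        partner = _nearest_partner_chain(complex_structure, partition, res)
        if res.name in ("GLY", "ALA"):
            results.append(HotspotResult(rec, 0.0, [], partner, scannable=False))
            continue
        other_side = list(partition[1] if res.chain_id in side1 else partition[0])
        # restriction of the complex to this residue vs. the partner side
        focus = Structure(
            {res.chain_id: [res]} |
            {cid: complex_structure.chains[cid] for cid in other_side}
        )
        focus_part = ([res.chain_id], other_side)
        before_contacts = extract_contacts(focus, focus_part, matrix.contact_def)
        before_score = score_complex(focus, focus_part, matrix)
        n_hb_before = sum(1 for b in base_hb
                          if _involves(b.donor, res.key) or _involves(b.acceptor, res.key))
        n_sb_before = sum(1 for b in base_sb
                          if _involves(b.positive, res.key) or _involves(b.negative, res.key))
        mutant = _truncated(focus, res.key)
        d_score = before_score - score_complex(mutant, focus_part, matrix)
        d_hb = n_hb_before - len(detect_hbonds(mutant, focus_part))
        d_sb = n_sb_before - len(detect_salt_bridges(mutant, focus_part))
        d_contacts = (sum(before_contacts.values())
                      - sum(extract_contacts(mutant, focus_part, matrix.contact_def).values()))
        lost = []
        if d_sb > 0:
            lost.append("SB")
        if d_hb > 0:
            lost.append("HB")
        if d_contacts > 0:
            lost.append("VW")
        ddg = d_score + w_hbond * max(d_hb, 0) + w_salt_bridge * max(d_sb, 0)
        if d_contacts == 0 and d_hb == 0 and d_sb == 0:
            ddg = 0.0
        results.append(HotspotResult(rec, round(float(ddg), 4), lost, partner))
    results.sort(key=lambda h: (-h.ddg_proxy, h.residue))
    return results


def _nearest_partner_chain(structure: Structure, partition, res) -> str | None:
    other = partition[1] if res.chain_id in set(partition[0]) else partition[0]
    best, bd = None, np.inf
    own = res.coords()
    for cid in other:
        pts = structure.coords([cid])
        if len(pts) == 0:
            continue
        d = float(cKDTree(pts).query(own, k=1)[0].min())
        if d < bd:
            best, bd = cid, d
    return best


# ---------------------------------------------------------------------------
# screened Coulomb potential and charge patches
# ---------------------------------------------------------------------------

def _charge_list(structure: Structure):
    charges = []
    for res in structure.residues():
        for atom, sign in charged_atoms(res):
            charges.append((res, atom, sign))
    return charges


def coulomb_potential(
    structure: Structure,
    test_points: np.ndarray,
    debye_length: float = DEBYE_LENGTH,
) -> np.ndarray:
    """Screened Coulomb potential at each test point (arbitrary units).

    phi(p) = sum over formally charged atoms of sign * exp(-d/lambda)/d
    with d floored at 1 A; the sign pattern is meaningful, the magnitude
    is not calibrated to any physical unit.
    """
    if debye_length <= 0:
        raise ValueError("debye length must be positive")
    pts = np.atleast_2d(np.asarray(test_points, float))
    phi = np.zeros(len(pts))
    for _, atom, sign in _charge_list(structure):
        d = np.linalg.norm(pts - atom.coord, axis=1)
        d = np.maximum(d, 1.0)
        phi += sign * np.exp(-d / debye_length) / d
    return phi


@dataclass
class ChargePatch:
    members: list[tuple[str, int, str]]
    sign: int
    mean_potential: float
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def size(self) -> int:
        return len(self.members)


def find_charge_patches(
    structure: Structure,
    sign: int,
    linkage_distance: float = 10.0,
    min_size: int = 2,
    exposure_cutoff: float = EXPOSURE_CUTOFF,
    debye_length: float = DEBYE_LENGTH,
) -> list[ChargePatch]:
    """Single-linkage clusters of exposed charged residues of one sign.

    Residues qualify when their side-chain relative exposure exceeds the
    cutoff and they carry charged atoms of the requested sign; two
    residues link when any of their charged atoms lie within
    ``linkage_distance``.  Patches smaller than ``min_size`` are dropped;
    the result is sorted by decreasing size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    areas = compute_sasa(structure)
    sc = _sidechain_sasa(structure, areas)
    ref = CHEMISTRY["max_sasa_sidechain"]

    members = []  # (residue, [charged atom coords])
    for res in structure.residues():
        atoms = [a for a, s in charged_atoms(res) if s == sign]
        if not atoms:
            continue
        rel = sc.get(res.key, 0.0) / float(ref.get(res.name, 100.0))
        if rel > exposure_cutoff:
            members.append((res, np.array([a.coord for a in atoms])))
    if len(members) == 0:
        return []
    n = len(members)
    if n == 1:
        return []
    # pairwise minimum charged-atom distance
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(members[i][1][:, None, :] - members[j][1][None, :, :], axis=2).min()
            dist[i, j] = dist[j, i] = d
    condensed = dist[np.triu_indices(n, 1)]
    labels = fcluster(linkage(condensed, method="single"), t=linkage_distance,
                      criterion="distance")
    patches: list[ChargePatch] = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if len(idx) < min_size:
            continue
        res_keys = [(members[i][0].chain_id, members[i][0].seq_id, members[i][0].name)
                    for i in idx]
        atom_coords = np.vstack([members[i][1] for i in idx])
        centroid = atom_coords.mean(axis=0)
        # potential at member charged atoms from all *other* charges
        phi_vals = []
        for i in idx:
            for coord in members[i][1]:
                phi = 0.0
                for res2, atom2, s2 in _charge_list(structure):
                    d = float(np.linalg.norm(coord - atom2.coord))
                    if d < 1e-9:
                        continue
                    phi += s2 * np.exp(-max(d, 1.0) / debye_length) / max(d, 1.0)
                phi_vals.append(phi)
        patches.append(ChargePatch(sorted(res_keys), int(sign),
                                   float(np.mean(phi_vals)), centroid))
    patches.sort(key=lambda p: (-p.size, p.members))
    return patches
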