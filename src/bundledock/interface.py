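"""Quantitative interface and surface characterization of a complex.

Implements the descriptors used to judge whether a modelled complex looks
like a stable transient heteromultimer: solvent-accessible surface area
(Shrake-Rupley on a deterministic Fibonacci sphere), interface area
(mean area buried per side), interface residues (buried-area threshold
1.0 A^2), geometric hydrogen bonds (heavy-atom donor-acceptor <= 3.9 A
with donor angle >= 90 deg), salt bridges (oppositely charged side-chain
atoms within 4 A), polarity-composition percentages of interface and
exposed-surface residues, interaction densities per 100 A^2 of
interface, overall model dimensions, and a verdict against a reference
"mean stable complex" row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structure import CHEMISTRY, Atom, Residue, Structure, charged_atoms
from .potential import PartitionError, _partition_sides

__all__ = [
    "HBond",
    "SaltBridge",
    "HBondCriteria",
    "InterfaceReport",
    "compute_sasa",
    "total_sasa",
    "interface_area",
    "interface_residues",
    "detect_hbonds",
    "detect_salt_bridges",
    "interface_report",
    "classify_stability",
    "load_reference_row",
    "residue_sasa",
]

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960
#: relative side-chain exposure above which a residue counts as surface
EXPOSURE_CUTOFF = 0.05


# ---------------------------------------------------------------------------
# solvent accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * k
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def compute_sasa(
    structure: Structure,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom accessible area (A^2), in structure atom order.

    Shrake-Rupley: each atom's solvent-extended sphere is sampled on a
    deterministic Fibonacci point set; a point is accessible when outside
    every neighbour's extended sphere.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a meaningful estimate")
    coords = structure.coords()
    if len(coords) == 0:
        return np.zeros(0)
    radii = np.array([a.vdw_radius for _, a in structure.atoms()]) + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.zeros(len(coords))
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * sphere
        neighbours = [j for j in tree.query_ball_point(c, r + rmax) if j != i]
        if neighbours:
            nb = np.array(neighbours)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r * r * frac
    return areas


def total_sasa(structure: Structure, probe_radius: float = PROBE_RADIUS,
               n_points: int = N_SPHERE_POINTS) -> float:
    return float(compute_sasa(structure, probe_radius, n_points).sum())


def residue_sasa(structure: Structure, probe_radius: float = PROBE_RADIUS,
                 n_points: int = N_SPHERE_POINTS) -> dict[tuple[str, int], float]:
    """Summed per-residue SASA keyed by (chain_id, seq_id)."""
    areas = compute_sasa(structure, probe_radius, n_points)
    out: dict[tuple[str, int], float] = {}
    for (res, _), a in zip(structure.atoms(), areas):
        out[res.key] = out.get(res.key, 0.0) + a
    return out


def _sidechain_sasa(structure: Structure, areas: np.ndarray) -> dict[tuple[str, int], float]:
    backbone = {"N", "CA", "C", "O", "OXT"}
    out: dict[tuple[str, int], float] = {}
    for (res, atom), a in zip(structure.atoms(), areas):
        if res.name == "GLY" or atom.name not in backbone:
            out[res.key] = out.get(res.key, 0.0) + a
        else:
            out.setdefault(res.key, out.get(res.key, 0.0))
    return out


# ---------------------------------------------------------------------------
# interface area and residues
# ---------------------------------------------------------------------------

class _PartitionSasa:
    """SASA bookkeeping for one complex partition, computed once."""

    def __init__(self, complex_structure: Structure, partition,
                 probe: float = PROBE_RADIUS, n_points: int = N_SPHERE_POINTS):
        self.side1, self.side2 = _partition_sides(complex_structure, partition)
        self.sub = complex_structure.subset(self.side1 + self.side2)
        self.atom_areas = compute_sasa(self.sub, probe, n_points)
        self.per_res_complex: dict[tuple[str, int], float] = {}
        for (res, _), a in zip(self.sub.atoms(), self.atom_areas):
            self.per_res_complex[res.key] = self.per_res_complex.get(res.key, 0.0) + a
        self.total_complex = float(self.atom_areas.sum())
        self.per_res_alone: dict[tuple[str, int], float] = {}
        self.total_alone = 0.0
        for side in (self.side1, self.side2):
            alone = residue_sasa(complex_structure.subset(side), probe, n_points)
            self.per_res_alone.update(alone)
            self.total_alone += sum(alone.values())

    def area(self) -> tuple[float, float]:
        area = (self.total_alone - self.total_complex) / 2.0
        pct = 100.0 * area / self.total_complex if self.total_complex > 0 else 0.0
        return float(area), float(pct)

    def buried_residues(self, threshold: float) -> list[tuple[str, int]]:
        out = []
        for key, alone in self.per_res_alone.items():
            if alone - self.per_res_complex[key] > threshold:
                out.append(key)
        return out


def interface_area(complex_structure: Structure, partition, probe: float = PROBE_RADIUS,
                   n_points: int = N_SPHERE_POINTS) -> tuple[float, float]:
    """(interface area A^2, percent of complex SASA).

    Area buried on complex formation, averaged over the two sides:
    ([ASA(side1) + ASA(side2)] - ASA(complex)) / 2.  The percent uses the
    complex ASA as denominator (declared convention).
    """
    return _PartitionSasa(complex_structure, partition, probe, n_points).area()


def interface_residues(complex_structure: Structure, partition, threshold: float = 1.0,
                       probe: float = PROBE_RADIUS, n_points: int = N_SPHERE_POINTS) -> list[Residue]:
    """Residues whose ASA drops by more than ``threshold`` on binding."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cache = _PartitionSasa(complex_structure, partition, probe, n_points)
    buried = set(cache.buried_residues(threshold))
    return [r for r in complex_structure.residues(cache.side1 + cache.side2)
            if r.key in buried]


# ---------------------------------------------------------------------------
# hydrogen bonds and salt bridges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    max_distance: float = 3.9
    min_donor_angle: float = 90.0


@dataclass
class HBond:
    donor: tuple[str, int, str]     # chain, seq_id, atom name
    acceptor: tuple[str, int, str]
    distance: float
    donor_angle: float


@dataclass
class SaltBridge:
    positive: tuple[str, int, str]
    negative: tuple[str, int, str]
    distance: float


def _hbond_role(res: Residue, atom: Atom, table: dict[str, str]) -> bool:
    if f"{res.name}:{atom.name}" in table:
        return True
    if f"*:{atom.name}" in table:
        # backbone role; Pro backbone N has no H to donate
        if atom.name == "N" and res.name == "PRO" and table is CHEMISTRY["donor"]:
            return False
        return True
    return False


def _antecedent(res: Residue, atom: Atom) -> Atom | None:
    """Nearest other heavy atom in the residue (covalent neighbour proxy)."""
    best, bd = None, np.inf
    for other in res.atoms:
        if other is atom:
            continue
        d = float(np.linalg.norm(other.coord - atom.coord))
        if d < bd:
            best, bd = other, d
    return best


def detect_hbonds(complex_structure: Structure, partition,
                  criteria: HBondCriteria = HBondCriteria()) -> list[HBond]:
    """Interchain hydrogen bonds across the partition, heavy-atom geometric.

    A donor-acceptor pair qualifies when the D-A distance is within the
    cutoff and the angle at the donor (antecedent-donor-acceptor) is at
    least the declared minimum; each pair is reported once.
    """
    side1, side2 = _partition_sides(complex_structure, partition)
    donors_t, acceptors_t = CHEMISTRY["donor"], CHEMISTRY["acceptor"]

    def collect(side, table):
        items = []
        for res in complex_structure.residues(side):
            for atom in res.atoms:
                if _hbond_role(res, atom, table):
                    items.append((res, atom))
        return items

    bonds: list[HBond] = []
    seen: set[tuple] = set()
    for sideA, sideB in ((side1, side2), (side2, side1)):
        donors = collect(sideA, donors_t)
        acceptors = collect(sideB, acceptors_t)
        if not donors or not acceptors:
            continue
        acc_pts = np.array([a.coord for _, a in acceptors])
        tree = cKDTree(acc_pts)
        for dres, datom in donors:
            for j in tree.query_ball_point(datom.coord, criteria.max_distance):
                ares, aatom = acceptors[j]
                ante = _antecedent(dres, datom)
                if ante is None:
                    continue
                v1 = ante.coord - datom.coord
                v2 = aatom.coord - datom.coord
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < criteria.min_donor_angle:
                    continue
                key = ((dres.chain_id, dres.seq_id, datom.name),
                       (ares.chain_id, ares.seq_id, aatom.name))
                if key in seen:
                    continue
                seen.add(key)
                bonds.append(HBond(key[0], key[1],
                                   float(np.linalg.norm(v2)), angle))
    return bonds


def detect_salt_bridges(complex_structure: Structure, partition,
                        cutoff: float = 4.0) -> list[SaltBridge]:
    """Oppositely charged side-chain atoms within ``cutoff`` across chains.

    One bridge per residue pair, reported at the minimum-distance atom
    pair.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    side1, side2 = _partition_sides(complex_structure, partition)

    def collect(side):
        items = []
        for res in complex_structure.residues(side):
            for atom, sign in charged_atoms(res):
                items.append((res, atom, sign))
        return items

    set1, set2 = collect(side1), collect(side2)
    best: dict[tuple, SaltBridge] = {}
    for res1, atom1, s1 in set1:
        for res2, atom2, s2 in set2:
            if s1 * s2 >= 0:
                continue
            d = float(np.linalg.norm(atom1.coord - atom2.coord))
            if d > cutoff:
                continue
            rkey = (res1.key, res2.key)
            pos, neg = ((res1, atom1), (res2, atom2)) if s1 > 0 else ((res2, atom2), (res1, atom1))
            bridge = SaltBridge(
                (pos[0].chain_id, pos[0].seq_id, pos[1].name),
                (neg[0].chain_id, neg[0].seq_id, neg[1].name),
                d,
            )
            if rkey not in best or d < best[rkey].distance:
                best[rkey] = bridge
    return sorted(best.values(), key=lambda b: (b.positive, b.negative))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class InterfaceReport:
    interface_asa: float
    interface_asa_percent: float
    interface_polar_pct: float
    interface_nonpolar_pct: float
    interface_charged_pct: float
    hbonds_per_100A2: float
    saltbridges_per_100A2: float
    n_hbonds: int
    n_salt_bridges: int
    surface_polar_pct: float
    surface_nonpolar_pct: float
    surface_charged_pct: float
    interface_residue_keys: list[tuple[str, int]] = field(default_factory=list)
    dimensions: tuple[float, float, float] = (0.0, 0.0, 0.0)
    zero_interface: bool = False

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["interface_residue_keys"] = [list(k) for k in self.interface_residue_keys]
        d["dimensions"] = list(self.dimensions)
        return d


def _composition(residues) -> tuple[float, float, float]:
    n = len(residues)
    if n == 0:
        return 0.0, 0.0, 0.0
    counts = {"polar": 0, "nonpolar": 0, "charged": 0}
    for r in residues:
        counts[r.polarity_class] += 1
    return tuple(100.0 * counts[k] / n for k in ("polar", "nonpolar", "charged"))


def _dimensions(structure: Structure) -> tuple[float, float, float]:
    """Bounding-box extents after aligning the principal axis to z."""
    X = structure.coords()
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    # principal axis -> z, second -> x, third -> y
    order = np.array([vt[1], vt[2], vt[0]])
    if np.linalg.det(order) < 0:
        order[1] = -order[1]
    Y = Xc @ order.T
    ext = Y.max(axis=0) - Y.min(axis=0)
    return (float(ext[0]), float(ext[1]), float(ext[2]))


def interface_report(complex_structure: Structure, partition,
                     probe: float = PROBE_RADIUS, n_points: int = N_SPHERE_POINTS,
                     hbond_criteria: HBondCriteria = HBondCriteria(),
                     salt_bridge_cutoff: float = 4.0,
                     interface_threshold: float = 1.0,
                     exposure_cutoff: float = EXPOSURE_CUTOFF) -> InterfaceReport:
    """Assemble the full descriptor row for a partitioned complex.

    Interface composition is computed over interface residues; surface
    composition over residues whose relative side-chain exposure in the
    complex exceeds ``exposure_cutoff``.  Interaction densities are per
    100 A^2 of interface area (zero, flagged, if the interface is empty).
    """
    cache = _PartitionSasa(complex_structure, partition, probe, n_points)
    sub = cache.sub
    area, pct = cache.area()
    buried = set(cache.buried_residues(interface_threshold))
    ifres = [r for r in sub.residues() if r.key in buried]
    hbonds = detect_hbonds(complex_structure, partition, hbond_criteria)
    bridges = detect_salt_bridges(complex_structure, partition, salt_bridge_cutoff)
    ip, inp, ic = _composition(ifres)

    sc = _sidechain_sasa(sub, cache.atom_areas)
    ref = CHEMISTRY["max_sasa_sidechain"]
    exposed = [
        r for r in sub.residues()
        if sc.get(r.key, 0.0) / float(ref.get(r.name, 100.0)) > exposure_cutoff
    ]
    sp, snp, schg = _composition(exposed)

    zero = area <= 0.0
    return InterfaceReport(
        interface_asa=round(area, 2),
        interface_asa_percent=round(pct, 2),
        interface_polar_pct=round(ip, 2),
        interface_nonpolar_pct=round(inp, 2),
        interface_charged_pct=round(ic, 2),
        hbonds_per_100A2=0.0 if zero else round(100.0 * len(hbonds) / area, 2),
        saltbridges_per_100A2=0.0 if zero else round(100.0 * len(bridges) / area, 2),
        n_hbonds=len(hbonds),
        n_salt_bridges=len(bridges),
        surface_polar_pct=round(sp, 2),
        surface_nonpolar_pct=round(snp, 2),
        surface_charged_pct=round(schg, 2),
        interface_residue_keys=[r.key for r in ifres],
        dimensions=_dimensions(sub),
        zero_interface=zero,
    )


# ---------------------------------------------------------------------------
# stability classification
# ---------------------------------------------------------------------------

def load_reference_row() -> dict:
    """The shipped 'mean stable complex' reference row (editable data file)."""
    text = resources.files("bundledock").joinpath("data/mean_stable_complex.json").read_text()
    return json.loads(text)


def classify_stability(report: InterfaceReport, reference: dict | None = None,
                       band: float = 0.5) -> dict:
    """Compare a report against the mean-stable-complex reference.

    Each of six fields (interface ASA %, the three interface composition
    percentages, and both interaction densities) is 'within band' when it
    falls inside the ratio-symmetric band [ref/(1+band), ref*(1+band)]
    (range-valued references use the band around their ends).  Verdict:
    >= 5 fields in band -> consistent; 4 -> borderline; else
    inconsistent.  An empty interface is inconsistent outright.
    """
    ref = reference or load_reference_row()
    fields = {
        "interface_asa_percent": report.interface_asa_percent,
        "interface_polar_pct": report.interface_polar_pct,
        "interface_nonpolar_pct": report.interface_nonpolar_pct,
        "interface_charged_pct": report.interface_charged_pct,
        "hbonds_per_100A2": report.hbonds_per_100A2,
        "saltbridges_per_100A2": report.saltbridges_per_100A2,
    }
    result: dict = {"fields": {}, "verdict": None}
    if report.zero_interface:
        for name, value in fields.items():
            result["fields"][name] = {"value": value, "within_band": False, "deviation": None}
        result["verdict"] = "inconsistent"
        return result
    n_ok = 0
    for name, value in fields.items():
        r = ref[name]
        if isinstance(r, (list, tuple)):
            lo, hi = float(r[0]) / (1 + band), float(r[1]) * (1 + band)
            centre = (float(r[0]) + float(r[1])) / 2.0
        else:
            lo, hi = float(r) / (1 + band), float(r) * (1 + band)
            centre = float(r)
        ok = lo <= value <= hi
        n_ok += ok
        deviation = (value - centre) / centre if centre != 0 else None
        result["fields"][name] = {"value": value, "within_band": bool(ok),
                                  "deviation": None if deviation is None else round(deviation, 3)}
    result["verdict"] = ("consistent" if n_ok >= 5 else
                         "borderline" if n_ok == 4 else "inconsistent")
    result["n_within_band"] = int(n_ok)
    return result
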