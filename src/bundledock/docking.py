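"""Rigid-body docking by grid shape complementarity with FFT translation scans.

Both partners are discretized onto cubic lattices with the classic
surface/interior encoding: cells inside any atom's van der Waals sphere
are occupied; occupied cells near open space form a thin surface layer
scored +1, while the receptor's deep interior carries a large penalty
(default -15) and the ligand interior +1.  The translational correlation

    C(t) = sum_x R(x) * L(x - t)

rewards surface-surface apposition and punishes core overlap; it is
evaluated for every lattice offset at once with forward/inverse FFTs.
Rotations come from a deterministic Euler-angle lattice with duplicate
orientations pruned, so a scan is exactly reproducible.

After pose generation, declared biological restraints prune the list:
maximum heavy-atom distances between named residue sets, and a
membrane-coplanarity condition requiring every chain's N-terminal
main-chain atom to sit in one slab perpendicular to the bundle axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfftn, rfftn
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure import Structure

__all__ = [
    "Grid",
    "DockPose",
    "DistanceRestraint",
    "CoplanarityRestraint",
    "RestraintSet",
    "GridError",
    "discretize",
    "fft_translation_scan",
    "rotation_set",
    "generate_poses",
    "apply_restraints",
    "transform_ligand",
    "bundle_axis",
]


class GridError(ValueError):
    pass


@dataclass
class Grid:
    spacing: float
    origin: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GridError("grid spacing must be positive")
        self.origin = np.asarray(self.origin, float)
        self.values = np.asarray(self.values)


def discretize(
    structure: Structure,
    spacing: float = 1.5,
    surface_thickness: float = 1.5,
    interior_value: float = 1.0,
    padding: float = 2.0,
) -> Grid:
    """Encode a structure on a cubic lattice (surface skin 1, body penalty).

    A cell is occupied (molecular body) when its centre lies within the
    van der Waals radius of any atom; body cells take ``interior_value``.
    Open-space cells within ``surface_thickness`` of the body form the
    surface skin (value 1), so two molecules in van der Waals contact
    overlap skin-on-body without interpenetrating.  A ligand grid is
    conventionally body-only (``surface_thickness=0``, interior 1)."""
    if spacing <= 0:
        raise GridError("grid spacing must be positive")
    coords = structure.coords()
    if len(coords) == 0:
        raise GridError("cannot discretize an empty structure")
    radii = np.array([a.vdw_radius for _, a in structure.atoms()])
    rmax = radii.max()
    lo = coords.min(axis=0) - rmax - padding
    hi = coords.max(axis=0) + rmax + padding
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    occupied = np.zeros(shape, dtype=bool)
    # mark each atom's sphere on the lattice
    for xyz, r in zip(coords, radii):
        c0 = np.floor((xyz - r - lo) / spacing).astype(int)
        c1 = np.ceil((xyz + r - lo) / spacing).astype(int) + 1
        c0 = np.maximum(c0, 0)
        c1 = np.minimum(c1, shape)
        ax = [np.arange(c0[k], c1[k]) * spacing + lo[k] for k in range(3)]
        dx2 = [(ax[k] - xyz[k]) ** 2 for k in range(3)]
        mask = (
            dx2[0][:, None, None] + dx2[1][None, :, None] + dx2[2][None, None, :]
        ) <= r * r
        occupied[c0[0]:c1[0], c0[1]:c1[1], c0[2]:c1[2]] |= mask
    if not occupied.any():
        raise GridError("discretization produced an all-zero grid")
    values = np.zeros(shape, dtype=float)
    values[occupied] = interior_value
    layers = int(round(surface_thickness / spacing))
    if layers > 0:
        skin = binary_dilation(occupied, iterations=layers) & ~occupied
        values[skin] = 1.0
    return Grid(spacing, lo, values)


def fft_translation_scan(receptor_grid: Grid, ligand_grid: Grid) -> np.ndarray:
    """Full cross-correlation lattice C(t) = sum_x R(x) L(x - t) via FFT.

    Output shape is ``nR + nL - 1`` per axis; index ``k`` corresponds to a
    shift of ``k - (nL - 1)`` cells of the ligand lattice relative to the
    receptor lattice.  Agrees with direct spatial correlation to machine
    precision.
    """
    if not math.isclose(receptor_grid.spacing, ligand_grid.spacing):
        raise GridError("grids must share spacing")
    R = receptor_grid.values
    L = ligand_grid.values
    fshape = tuple(nr + nl - 1 for nr, nl in zip(R.shape, L.shape))
    # next fast FFT lengths
    from scipy.fft import next_fast_len

    fast = tuple(next_fast_len(n, real=True) for n in fshape)
    C = irfftn(rfftn(R, fast) * np.conj(rfftn(L, fast)), fast)
    # circular correlation: t >= 0 at the front, negative shifts wrapped;
    # roll so index k corresponds to t = k - (nL - 1)
    C = np.roll(C, shift=[n - 1 for n in L.shape], axis=(0, 1, 2))
    return C[tuple(slice(0, n) for n in fshape)]


@dataclass(eq=False)
class DockPose:
    """A rigid placement x -> R x + t of the ligand, with its scores."""

    rotation: np.ndarray
    translation: np.ndarray
    complementarity_score: float
    rotation_index: int = 0
    cell_offset: tuple[int, int, int] = (0, 0, 0)
    pair_potential_score: float | None = None
    restraint_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")


def rotation_set(angular_step_deg: float) -> list[Rotation]:
    """Deterministic SO(3) sample: Euler z-y-z lattice, duplicates pruned."""
    if angular_step_deg <= 0:
        raise ValueError("angular step must be positive")
    step = angular_step_deg
    alphas = np.arange(0.0, 360.0, step)
    betas = np.arange(0.0, 180.0 + 1e-9, step)
    gammas = np.arange(0.0, 360.0, step)
    rots: list[Rotation] = []
    seen: set[tuple[int, ...]] = set()
    for b in betas:
        for a in alphas:
            for g in gammas:
                rot = Rotation.from_euler("zyz", [a, b, g], degrees=True)
                q = np.round(rot.as_quat(), 4)  # tolerance far below the grid step
                if q[3] < 0:
                    q = -q
                elif q[3] == 0:
                    nz = np.nonzero(q)[0]
                    if len(nz) and q[nz[0]] < 0:
                        q = -q
                key = tuple(q + 0.0)  # fold -0.0 into 0.0
                if key in seen:
                    continue
                seen.add(key)
                rots.append(rot)
    return rots


def transform_ligand(ligand: Structure, pose: DockPose) -> Structure:
    return ligand.transformed(pose.rotation, pose.translation)


def generate_poses(
    receptor: Structure,
    ligand: Structure,
    angular_step: float = 15.0,
    spacing: float = 1.5,
    keep_top: int = 10000,
    surface_thickness: float = 1.5,
    receptor_interior: float = -15.0,
    translations_per_rotation: int = 3,
) -> list[DockPose]:
    """Exhaustive rotation/translation scan, best poses by complementarity.

    For every rotation of the deterministic set, the ligand is re-gridded
    and the FFT translation scan scored; the best
    ``translations_per_rotation`` offsets per rotation enter a global pool
    which is sorted by score (ties: lower rotation index, then offset) and
    truncated to ``keep_top``.  Fully deterministic.
    """
    if keep_top < 1:
        raise ValueError("keep_top must be >= 1")
    rec_grid = discretize(receptor, spacing, surface_thickness, receptor_interior)
    rots = rotation_set(angular_step)
    centroid = ligand.coords().mean(axis=0)
    pool: list[tuple[float, int, tuple[int, int, int], np.ndarray, np.ndarray]] = []
    for ridx, rot in enumerate(rots):
        R = rot.as_matrix()
        rotated = ligand.transformed(R, centroid - R @ centroid)
        lig_grid = discretize(rotated, spacing, 0.0, 1.0)
        C = fft_translation_scan(rec_grid, lig_grid)
        # round away FFT float noise so equal-contact poses tie exactly and
        # the deterministic (rotation index, offset) tie-break applies
        Cr = np.round(C, 6)
        flat = np.lexsort((np.arange(Cr.size), -Cr.ravel()))[:translations_per_rotation]
        nl = lig_grid.values.shape
        for f in flat:
            idx = np.unravel_index(f, C.shape)
            t_cells = tuple(int(idx[k]) - (nl[k] - 1) for k in range(3))
            delta = rec_grid.origin + np.array(t_cells) * spacing - lig_grid.origin
            translation = centroid - R @ centroid + delta
            pool.append((float(Cr[idx]), ridx, t_cells, R, translation))
    pool.sort(key=lambda e: (-e[0], e[1], e[2]))
    if len(pool) < keep_top:
        warnings.warn(
            f"angular step {angular_step} deg too coarse for keep_top={keep_top}: "
            f"returning {len(pool)} poses"
        )
    poses = [
        DockPose(R, t, score, rotation_index=ridx, cell_offset=cells)
        for score, ridx, cells, R, t in pool[:keep_top]
    ]
    return poses


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------

@dataclass
class DistanceRestraint:
    """Max heavy-atom distance between receptor and ligand residue sets.

    Residue selectors are lists of (chain_id, seq_id).
    """

    receptor_residues: list[tuple[str, int]]
    ligand_residues: list[tuple[str, int]]
    max_distance: float = 6.0

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("restraint distance must be positive")


@dataclass
class CoplanarityRestraint:
    """All chain N-terminal main-chain atoms within one slab.

    The slab normal is the bundle axis of the receptor; thickness in
    Angstrom.  Models the shared membrane anchoring of every chain's
    N-terminus.
    """

    slab_thickness: float = 8.0
    atom_name: str = "N"

    def __post_init__(self) -> None:
        if self.slab_thickness <= 0:
            raise ValueError("slab thickness must be positive")


@dataclass
class RestraintSet:
    distance_restraints: list[DistanceRestraint] = field(default_factory=list)
    coplanarity: CoplanarityRestraint | None = None


class RestraintDefinitionError(ValueError):
    pass


def bundle_axis(structure: Structure) -> np.ndarray:
    """Dominant principal axis of the CA trace (unit vector)."""
    cas = [r.atom("CA").coord for r in structure.residues() if r.atom("CA")]
    X = np.array(cas if cas else [a.coord for _, a in structure.atoms()])
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    axis = vt[0]
    return axis if axis[2] >= 0 else -axis


def _select_coords(structure: Structure, selectors: list[tuple[str, int]], label: str) -> np.ndarray:
    pts = []
    for cid, sid in selectors:
        res = None
        for r in structure.chains.get(cid, []):
            if r.seq_id == sid:
                res = r
                break
        if res is not None:
            pts.extend(a.coord for a in res.atoms)
    if not pts:
        raise RestraintDefinitionError(f"{label} selector {selectors} matches no atoms")
    return np.array(pts)


def _nterm_points(structure: Structure, atom_name: str) -> np.ndarray:
    pts = []
    for cid, residues in structure.chains.items():
        if not residues:
            continue
        first = residues[0]
        atom = first.atom(atom_name) or first.atoms[0]
        pts.append(atom.coord)
    return np.array(pts)


def apply_restraints(
    poses: list[DockPose],
    receptor: Structure,
    ligand: Structure,
    restraints: RestraintSet,
) -> list[DockPose]:
    """Keep poses satisfying every restraint; order preserved.

    Each pose's ``restraint_flags`` is filled with a pass/fail entry per
    restraint, also for poses that end up filtered out.
    """
    rec_sets = [
        _select_coords(receptor, dr.receptor_residues, "receptor")
        for dr in restraints.distance_restraints
    ]
    # validate ligand selectors once, on the untransformed ligand
    for dr in restraints.distance_restraints:
        _select_coords(ligand, dr.ligand_residues, "ligand")
    axis = bundle_axis(receptor)
    rec_nterm = _nterm_points(receptor, restraints.coplanarity.atom_name) if restraints.coplanarity else None

    kept: list[DockPose] = []
    for pose in poses:
        moved = transform_ligand(ligand, pose)
        ok = True
        for k, dr in enumerate(restraints.distance_restraints):
            lig_pts = _select_coords(moved, dr.ligand_residues, "ligand")
            dmin = float(cKDTree(rec_sets[k]).query(lig_pts, k=1)[0].min())
            passed = bool(dmin <= dr.max_distance)
            pose.restraint_flags[f"distance_{k}"] = passed
            ok = ok and passed
        if restraints.coplanarity is not None:
            pts = np.vstack([rec_nterm, _nterm_points(moved, restraints.coplanarity.atom_name)])
            proj = pts @ axis
            passed = bool((proj.max() - proj.min()) <= restraints.coplanarity.slab_thickness)
            pose.restraint_flags["coplanarity"] = passed
            ok = ok and passed
        if ok:
            kept.append(pose)
    return kept
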