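"""Grid encoding, FFT translation scans, pose generation and restraints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from scipy.signal import correlate
from scipy.spatial.transform import Rotation

from bundledock.docking import (
    CoplanarityRestraint,
    DistanceRestraint,
    DockPose,
    Grid,
    GridError,
    RestraintDefinitionError,
    RestraintSet,
    apply_restraints,
    bundle_axis,
    discretize,
    fft_translation_scan,
    generate_poses,
    rotation_set,
    transform_ligand,
)
from bundledock.structure import Structure
from bundledock.synthetic import make_groove_receptor, make_rod_ligand
from .conftest import ala, lys, glu


def grid(values, spacing=1.0):
    return Grid(spacing, np.zeros(3), np.asarray(values, float))


class TestDiscretize:
    def test_single_carbon_volume(self):
        st = Structure({"A": [ala("A", 1)]})
        st.chains["A"][0].atoms = [a for a in st.chains["A"][0].atoms if a.name == "CA"]
        g = discretize(st, spacing=1.0, surface_thickness=0.0, interior_value=1.0)
        body = int((g.values == 1.0).sum())
        expect = 4.0 / 3.0 * np.pi * 1.7**3
        assert abs(body - expect) / expect < 0.30

    def test_empty_structure_rejected(self):
        with pytest.raises(GridError):
            discretize(Structure({}), 1.0)

    def test_bad_spacing_rejected(self, ideal_dimer):
        with pytest.raises(GridError):
            discretize(ideal_dimer, spacing=-1.0)

    def test_disjoint_atoms_give_two_components(self):
        st = Structure({"A": [ala("A", 1), ala("A", 2, (20.0, 0.0, 0.0))]})
        for res in st.chains["A"]:
            res.atoms = [a for a in res.atoms if a.name == "CA"]
        g = discretize(st, spacing=1.0, surface_thickness=0.0, interior_value=1.0)
        _, n = ndimage.label(g.values != 0)
        assert n == 2

    def test_surface_skin_surrounds_body(self):
        st = Structure({"A": [ala("A", 1)]})
        g = discretize(st, spacing=1.0, surface_thickness=1.0, interior_value=-15.0)
        assert (g.values == -15.0).any() and (g.values == 1.0).any()
        body = g.values == -15.0
        skin = g.values == 1.0
        grown = ndimage.binary_dilation(body)
        assert np.all(skin <= (grown & ~body) | skin)  # skin touches the body boundary


class TestFftScan:
    @pytest.mark.parametrize("shape", [(8, 8, 8), (12, 12, 12), (5, 9, 7)])
    def test_matches_direct_correlation(self, shape):
        rng = np.random.default_rng(42)
        R = rng.integers(-15, 2, size=shape).astype(float)
        L = rng.integers(0, 2, size=(4, 5, 3)).astype(float)
        C = fft_translation_scan(grid(R), grid(L))
        D = correlate(R, L, mode="full", method="direct")
        assert np.abs(C - D).max() <= 1e-6 * max(1.0, np.abs(D).max())

    @given(seed=st.integers(0, 2**16),
           nr=st.tuples(*[st.integers(2, 8)] * 3),
           nl=st.tuples(*[st.integers(1, 6)] * 3))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_direct_correlation_property(self, seed, nr, nl):
        rng = np.random.default_rng(seed)
        R = rng.normal(size=nr)
        L = rng.normal(size=nl)
        C = fft_translation_scan(grid(R), grid(L))
        D = correlate(R, L, mode="full", method="direct")
        assert np.abs(C - D).max() <= 1e-9 * max(1.0, np.abs(D).max())

    def test_swap_symmetry(self):
        rng = np.random.default_rng(7)
        A = rng.integers(0, 3, size=(6, 6, 6)).astype(float)
        B = rng.integers(0, 3, size=(6, 6, 6)).astype(float)
        CAB = fft_translation_scan(grid(A), grid(B))
        CBA = fft_translation_scan(grid(B), grid(A))
        assert np.allclose(CAB, CBA[::-1, ::-1, ::-1], atol=1e-9)

    def test_single_cells_adjoin(self):
        R = np.zeros((4, 4, 4)); R[1, 1, 1] = 1.0
        L = np.zeros((4, 4, 4)); L[2, 2, 2] = 1.0
        C = fft_translation_scan(grid(R), grid(L))
        idx = np.unravel_index(np.argmax(C), C.shape)
        t = tuple(i - 3 for i in idx)
        assert C[idx] == pytest.approx(1.0)
        assert t == (-1, -1, -1)  # shift mapping L's cell onto R's cell

    def test_interior_overlap_is_penalized(self):
        R = np.full((3, 3, 3), -15.0)
        L = np.zeros((3, 3, 3)); L[1, 1, 1] = 1.0
        C = fft_translation_scan(grid(R), grid(L))
        assert C[2, 2, 2] == pytest.approx(-15.0)  # t=0: ligand inside receptor

    def test_mismatched_spacing_rejected(self):
        with pytest.raises(GridError):
            fft_translation_scan(grid(np.ones((2, 2, 2)), 1.0),
                                 grid(np.ones((2, 2, 2)), 1.5))


class TestRotationSet:
    def test_no_duplicate_orientations(self):
        rots = rotation_set(45.0)
        quats = []
        for r in rots:
            q = r.as_quat()
            if q[3] < 0:
                q = -q
            quats.append(tuple(np.round(q, 5)))
        assert len(quats) == len(set(quats))

    def test_identity_included(self):
        rots = rotation_set(30.0)
        assert any(np.allclose(r.as_matrix(), np.eye(3), atol=1e-9) for r in rots)


@pytest.fixture(scope="module")
def toy():
    rec = make_groove_receptor(12.0, 8.0, size=20.0, thickness=8.0)
    rod = make_rod_ligand(10.0, 7.0)
    return rec, rod


class TestGeneratePoses:

    def test_deterministic(self, toy):
        rec, rod = toy
        p1 = generate_poses(rec, rod, angular_step=60.0, keep_top=5)
        p2 = generate_poses(rec, rod, angular_step=60.0, keep_top=5)
        assert len(p1) == len(p2) == 5
        for a, b in zip(p1, p2):
            assert np.allclose(a.rotation, b.rotation)
            assert np.allclose(a.translation, b.translation)
            assert a.complementarity_score == b.complementarity_score

    def test_keep_top_prefix_stability(self, toy):
        rec, rod = toy
        small = generate_poses(rec, rod, angular_step=60.0, keep_top=4)
        large = generate_poses(rec, rod, angular_step=60.0, keep_top=12)
        for a, b in zip(small, large):
            assert np.allclose(a.rotation, b.rotation)
            assert a.cell_offset == b.cell_offset

    def test_too_coarse_warns_and_returns_fewer(self, toy):
        rec, rod = toy
        with pytest.warns(UserWarning, match="coarse"):
            poses = generate_poses(rec, rod, angular_step=120.0, keep_top=10**6,
                                   translations_per_rotation=1)
        assert 0 < len(poses) < 10**6

    def test_scores_sorted_descending(self, toy):
        rec, rod = toy
        poses = generate_poses(rec, rod, angular_step=60.0, keep_top=20)
        scores = [p.complementarity_score for p in poses]
        assert scores == sorted(scores, reverse=True)


class TestDockPose:
    def test_rotation_validation(self):
        with pytest.raises(ValueError):
            DockPose(np.eye(3) * 2.0, np.zeros(3), 0.0)
        with pytest.raises(ValueError):
            DockPose(np.diag([1.0, 1.0, -1.0]), np.zeros(3), 0.0)


class TestRestraints:
    def receptor(self):
        # LYS arm points +x, NZ exactly at the origin
        return Structure({"A": [lys("A", 1, (0.0, 0.0, 0.0))]})

    def ligand(self):
        # GLU arm points -x, OE1 exactly at the origin
        return Structure({"B": [glu("B", 1, (0.0, 0.0, 0.0))]})

    def pose_with_min_distance(self, d):
        """Identity-rotation pose placing GLU OE1 at distance d from LYS NZ."""
        return DockPose(np.eye(3), np.array([d, 0.0, 0.0]), 0.0)

    def test_distance_restraint_pass_and_fail(self):
        rec, lig = self.receptor(), self.ligand()
        rs = RestraintSet([DistanceRestraint([("A", 1)], [("B", 1)], 6.0)])
        # OE2 sits 1.1 A off OE1 laterally; min distance is to OE1
        passing = apply_restraints([self.pose_with_min_distance(5.0)], rec, lig, rs)
        failing = apply_restraints([self.pose_with_min_distance(7.0)], rec, lig, rs)
        assert len(passing) == 1 and passing[0].restraint_flags["distance_0"]
        assert len(failing) == 0

    def test_coplanarity_rejects_axial_displacement(self, ideal_dimer):
        lig = self.ligand()
        rs = RestraintSet(coplanarity=CoplanarityRestraint(slab_thickness=8.0))
        axis = bundle_axis(ideal_dimer)
        assert abs(axis[2]) > 0.99  # bundles are built along z
        near = DockPose(np.eye(3), np.array([12.0, 0.0, 0.0]), 0.0)
        far = DockPose(np.eye(3), np.array([12.0, 0.0, 20.0]), 0.0)
        kept = apply_restraints([near, far], ideal_dimer, lig, rs)
        assert [p is near for p in kept] == [True]
        assert far.restraint_flags["coplanarity"] is False

    def test_unresolvable_selector_rejected(self):
        rec, lig = self.receptor(), self.ligand()
        rs = RestraintSet([DistanceRestraint([("A", 99)], [("B", 1)], 6.0)])
        with pytest.raises(RestraintDefinitionError):
            apply_restraints([self.pose_with_min_distance(5.0)], rec, lig, rs)

    def test_filtering_is_idempotent_order_preserving_subset(self):
        rec, lig = self.receptor(), self.ligand()
        rs = RestraintSet([DistanceRestraint([("A", 1)], [("B", 1)], 6.0)])
        poses = [self.pose_with_min_distance(d) for d in (5.5, 7.5, 3.0, 6.0)]
        kept = apply_restraints(poses, rec, lig, rs)
        idx = [poses.index(p) for p in kept]
        assert idx == sorted(idx)
        assert set(id(p) for p in kept) <= set(id(p) for p in poses)
        again = apply_restraints(kept, rec, lig, rs)
        assert [id(p) for p in again] == [id(p) for p in kept]

    def test_transform_ligand_applies_pose(self):
        lig = self.ligand()
        pose = DockPose(np.eye(3), np.array([1.0, 2.0, 3.0]), 0.0)
        moved = transform_ligand(lig, pose)
        assert np.allclose(moved.coords(), lig.coords() + [1.0, 2.0, 3.0])
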