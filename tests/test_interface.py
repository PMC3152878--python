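"""Surface area, interface descriptors, bond detection and stability calls."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bundledock.interface import (
    HBondCriteria,
    classify_stability,
    compute_sasa,
    detect_hbonds,
    detect_salt_bridges,
    interface_area,
    interface_report,
    interface_residues,
    load_reference_row,
    total_sasa,
)
from bundledock.structure import Structure
from .conftest import ala, glu, lys, residue


def single_atom(name="N", element="N", where=(0.0, 0.0, 0.0), chain="A", seq=1):
    return residue("ALA", chain, seq, [(name, element, where)])


class TestSasa:
    def test_isolated_nitrogen_matches_analytic_sphere(self):
        st = Structure({"A": [single_atom()]})
        area = compute_sasa(st)[0]
        assert area == pytest.approx(4 * np.pi * (1.55 + 1.4) ** 2, rel=0.01)

    def test_additivity_for_separated_atoms(self):
        st = Structure({"A": [single_atom(seq=1),
                              single_atom(where=(50.0, 0.0, 0.0), seq=2)]})
        areas = compute_sasa(st)
        assert areas[0] == pytest.approx(areas[1])
        assert areas.sum() == pytest.approx(2 * areas[0])

    def test_caged_atom_is_buried(self):
        centre = single_atom("C1", "C", (0.0, 0.0, 0.0), seq=1)
        cage_atoms = []
        k = 0
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    k += 1
                    v = np.array([dx, dy, dz], float)
                    v = v / np.linalg.norm(v) * 2.2
                    cage_atoms.append((f"C{k}", "C", tuple(v)))
        cage = residue("ALA", "A", 2, cage_atoms)
        st = Structure({"A": [centre, cage]})
        assert compute_sasa(st)[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_sphere_overlap_matches_closed_form(self):
        st = Structure({"A": [residue("ALA", "A", 1, [("C1", "C", (0, 0, 0)),
                                                      ("C2", "C", (2.0, 0, 0))])]})
        areas = compute_sasa(st)
        r, d = 1.7 + 1.4, 2.0
        cap = 2 * np.pi * r * (r - d / 2)
        assert areas.sum() == pytest.approx(2 * (4 * np.pi * r * r - cap), rel=0.01)

    def test_point_count_floor(self):
        with pytest.raises(ValueError):
            compute_sasa(Structure({"A": [ala("A", 1)]}), n_points=50)


class TestInterfaceArea:
    def test_separated_chains_bury_nothing(self):
        st = Structure({"A": [ala("A", 1)], "B": [ala("B", 1, (50.0, 0.0, 0.0))]})
        area, pct = interface_area(st, (["A"], ["B"]))
        assert abs(area) < 0.5 and abs(pct) < 0.5

    def test_matches_per_atom_bookkeeping(self, ideal_dimer, dimer_partition):
        area, _ = interface_area(ideal_dimer, dimer_partition)
        # independent recomputation from raw per-atom areas
        asa_c = total_sasa(ideal_dimer)
        asa_a = total_sasa(ideal_dimer.subset(["A"]))
        asa_b = total_sasa(ideal_dimer.subset(["B"]))
        assert area == pytest.approx((asa_a + asa_b - asa_c) / 2, abs=1e-6)
        assert area > 100  # a zipper dimer buries real surface

    def test_symmetric_homodimer_buries_equal_sides(self, ideal_dimer):
        asa_c = compute_sasa(ideal_dimer)
        keys = [(r.chain_id, a.name, r.seq_id) for r, a in ideal_dimer.atoms()]
        per_chain_complex = {"A": 0.0, "B": 0.0}
        for (cid, _, _), v in zip(keys, asa_c):
            per_chain_complex[cid] += v
        buried_a = total_sasa(ideal_dimer.subset(["A"])) - per_chain_complex["A"]
        buried_b = total_sasa(ideal_dimer.subset(["B"])) - per_chain_complex["B"]
        assert abs(buried_a - buried_b) / buried_a < 0.01

    def test_partition_order_symmetric(self, ideal_dimer):
        a1, _ = interface_area(ideal_dimer, (["A"], ["B"]))
        a2, _ = interface_area(ideal_dimer, (["B"], ["A"]))
        assert a1 == a2


class TestInterfaceResidues:
    def test_far_apart_chains_give_empty_set(self):
        st = Structure({"A": [ala("A", 1)], "B": [ala("B", 1, (50.0, 0.0, 0.0))]})
        assert interface_residues(st, (["A"], ["B"])) == []

    def test_built_dimer_interface_includes_core_leucines(self, ideal_dimer, dimer_partition):
        found = {(r.chain_id, r.seq_id) for r in
                 interface_residues(ideal_dimer, dimer_partition)}
        # register 'a' leucines at seq ids 1, 8, 15, 22 on both chains
        for cid in "AB":
            for sid in (8, 15, 22):
                assert (cid, sid) in found

    def test_monotone_in_threshold(self, ideal_dimer, dimer_partition):
        small = interface_residues(ideal_dimer, dimer_partition, threshold=1.0)
        large = interface_residues(ideal_dimer, dimer_partition, threshold=20.0)
        huge = interface_residues(ideal_dimer, dimer_partition, threshold=1e6)
        assert {r.key for r in large} <= {r.key for r in small}
        assert huge == []


class TestHbonds:
    def backbone_pair(self, distance, angle_deg):
        """Chain A amide N donating to chain B carbonyl O at given geometry."""
        n = np.array([0.0, 0.0, 0.0])
        ca = np.array([1.46, 0.0, 0.0])  # antecedent of N
        theta = np.radians(angle_deg)
        o = n + distance * np.array([np.cos(theta), np.sin(theta), 0.0])
        donor = residue("ALA", "A", 1, [("N", "N", tuple(n)), ("CA", "C", tuple(ca))])
        c = o + np.array([0.0, 1.23, 0.0])
        acceptor = residue("ALA", "B", 1, [("C", "C", tuple(c)), ("O", "O", tuple(o))])
        return Structure({"A": [donor], "B": [acceptor]})

    def test_good_geometry_detected(self):
        st = self.backbone_pair(2.9, 160.0)
        bonds = detect_hbonds(st, (["A"], ["B"]))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)

    def test_long_distance_rejected(self):
        assert detect_hbonds(self.backbone_pair(4.5, 160.0), (["A"], ["B"])) == []

    def test_sharp_angle_rejected(self):
        assert detect_hbonds(self.backbone_pair(3.0, 60.0), (["A"], ["B"])) == []

    def test_count_monotone_in_distance_cutoff(self, ideal_dimer, dimer_partition):
        loose = detect_hbonds(ideal_dimer, dimer_partition, HBondCriteria(3.9, 90.0))
        tight = detect_hbonds(ideal_dimer, dimer_partition, HBondCriteria(3.2, 90.0))
        assert len(tight) <= len(loose)


class TestSaltBridges:
    def pair(self, d):
        return Structure({"A": [lys("A", 1, (0.0, 0.0, 0.0))],
                          "B": [glu("B", 1, (d, 0.0, 0.0))]})

    def test_close_opposite_charges_bridge(self):
        st = self.pair(3.5)
        bridges = detect_salt_bridges(st, (["A"], ["B"]))
        assert len(bridges) == 1
        assert bridges[0].positive[2] == "NZ"
        assert bridges[0].negative[2] in ("OE1", "OE2")
        # reported at the minimum-distance charged pair
        nz = st.chains["A"][0].atom("NZ").coord
        dmin = min(np.linalg.norm(nz - st.chains["B"][0].atom(n).coord)
                   for n in ("OE1", "OE2"))
        assert bridges[0].distance == pytest.approx(dmin)

    def test_beyond_cutoff_rejected(self):
        assert detect_salt_bridges(self.pair(4.5), (["A"], ["B"])) == []

    def test_same_sign_pairs_rejected(self):
        st = Structure({"A": [lys("A", 1, (0.0, 0.0, 0.0))],
                        "B": [lys("B", 1, (3.0, 0.0, 0.0))]})
        assert detect_salt_bridges(st, (["A"], ["B"])) == []

    def test_one_bridge_per_residue_pair(self):
        # both OE1 and OE2 within 4 A of NZ: still a single bridge
        bridges = detect_salt_bridges(self.pair(2.5), (["A"], ["B"]))
        assert len(bridges) == 1


class TestReportAndStability:
    def test_report_self_consistency(self, ideal_dimer, dimer_partition):
        rep = interface_report(ideal_dimer, dimer_partition)
        area, pct = interface_area(ideal_dimer, dimer_partition)
        assert rep.interface_asa == pytest.approx(area, abs=0.01)
        assert rep.interface_asa_percent == pytest.approx(pct, abs=0.01)
        n_hb = len(detect_hbonds(ideal_dimer, dimer_partition))
        n_sb = len(detect_salt_bridges(ideal_dimer, dimer_partition))
        assert rep.n_hbonds == n_hb and rep.n_salt_bridges == n_sb
        assert rep.hbonds_per_100A2 == pytest.approx(100 * n_hb / area, abs=0.01)
        assert rep.saltbridges_per_100A2 == pytest.approx(100 * n_sb / area, abs=0.01)

    def test_composition_percentages_sum_to_100(self, ideal_dimer, dimer_partition):
        rep = interface_report(ideal_dimer, dimer_partition)
        assert (rep.interface_polar_pct + rep.interface_nonpolar_pct
                + rep.interface_charged_pct) == pytest.approx(100.0, abs=0.1)
        assert (rep.surface_polar_pct + rep.surface_nonpolar_pct
                + rep.surface_charged_pct) == pytest.approx(100.0, abs=0.1)

    def test_all_leu_interface_is_fully_nonpolar(self):
        from bundledock.coiledcoil import BundleSpec, ChainSpec, assign_register, build_bundle

        seq = "L" * 21
        reg = assign_register(seq, [1])
        st = build_bundle(BundleSpec([ChainSpec(seq, reg, 1, "A", "A"),
                                      ChainSpec(seq, reg, 1, "B", "B")]))
        rep = interface_report(st, (["A"], ["B"]))
        assert rep.interface_nonpolar_pct == pytest.approx(100.0)

    def test_metrics_invariant_under_rigid_transform(self, ideal_dimer, dimer_partition):
        R = Rotation.from_euler("xyz", [17, -31, 59], degrees=True).as_matrix()
        moved = ideal_dimer.transformed(R, np.array([7.0, -4.0, 11.0]))
        rep0 = interface_report(ideal_dimer, dimer_partition)
        rep1 = interface_report(moved, dimer_partition)
        assert rep1.interface_asa == pytest.approx(rep0.interface_asa, rel=0.005)
        assert rep1.n_hbonds == rep0.n_hbonds
        assert rep1.n_salt_bridges == rep0.n_salt_bridges

    def test_uninvolved_chain_does_not_change_report(self, ideal_dimer, dimer_partition):
        with_extra = ideal_dimer.merged(
            Structure({"Z": [ala("Z", 1, (200.0, 0.0, 0.0))]}))
        rep0 = interface_report(ideal_dimer, dimer_partition)
        rep1 = interface_report(with_extra, dimer_partition)
        assert rep1.interface_asa == rep0.interface_asa
        assert rep1.interface_residue_keys == rep0.interface_residue_keys

    def test_reference_row_is_consistent_with_itself(self):
        ref = load_reference_row()
        from bundledock.interface import InterfaceReport

        rep = InterfaceReport(
            interface_asa=1000.0,
            interface_asa_percent=ref["interface_asa_percent"],
            interface_polar_pct=ref["interface_polar_pct"],
            interface_nonpolar_pct=ref["interface_nonpolar_pct"],
            interface_charged_pct=ref["interface_charged_pct"],
            hbonds_per_100A2=ref["hbonds_per_100A2"],
            saltbridges_per_100A2=sum(ref["saltbridges_per_100A2"]) / 2,
            n_hbonds=10, n_salt_bridges=10,
            surface_polar_pct=30.0, surface_nonpolar_pct=40.0, surface_charged_pct=30.0,
        )
        out = classify_stability(rep)
        assert out["verdict"] == "consistent"
        assert out["fields"]["interface_asa_percent"]["deviation"] == 0.0

    def test_sparse_interface_fraction_flags_field(self):
        ref = load_reference_row()
        rep = interface_report_like(ref, interface_asa_percent=6.12)
        out = classify_stability(rep)
        assert out["fields"]["interface_asa_percent"]["within_band"] is False

    def test_empty_interface_is_inconsistent(self):
        st = Structure({"A": [ala("A", 1)], "B": [ala("B", 1, (60.0, 0.0, 0.0))]})
        rep = interface_report(st, (["A"], ["B"]))
        assert rep.zero_interface
        assert classify_stability(rep)["verdict"] == "inconsistent"


def interface_report_like(ref, **overrides):
    from bundledock.interface import InterfaceReport

    values = dict(
        interface_asa=1000.0,
        interface_asa_percent=ref["interface_asa_percent"],
        interface_polar_pct=ref["interface_polar_pct"],
        interface_nonpolar_pct=ref["interface_nonpolar_pct"],
        interface_charged_pct=ref["interface_charged_pct"],
        hbonds_per_100A2=ref["hbonds_per_100A2"],
        saltbridges_per_100A2=3.0,
        n_hbonds=10, n_salt_bridges=10,
        surface_polar_pct=30.0, surface_nonpolar_pct=40.0, surface_charged_pct=30.0,
    )
    values.update(overrides)
    return InterfaceReport(**values)
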