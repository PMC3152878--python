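"""Crick-parameterized bundle construction and stoichiometry enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bundledock.coiledcoil import (
    BundleSpec,
    ChainSpec,
    CrickParameters,
    GeometryError,
    RegisterError,
    assign_register,
    build_bundle,
    enumerate_stoichiometries,
    pentamer_admissible,
)


def chain_axis_point(structure, chain_id, start, window=7):
    """Centroid of a full-heptad CA window: cancels the minor helix."""
    cas = [r.atom("CA").coord for r in structure.chains[chain_id]]
    return np.mean(cas[start:start + window], axis=0)


class TestAssignRegister:
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60),
           st.integers(1, 7))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_letters_advance_cyclically(self, seq, anchor):
        anchor = min(anchor, len(seq))
        reg = assign_register(seq, [anchor])
        heptad = "abcdefg"
        assert reg[anchor - 1] == "a"
        for a, b in zip(reg, reg[1:]):
            assert heptad[(heptad.index(a) + 1) % 7] == b

    def test_anchor_cyclic_fill(self):
        seq = "LAAAAAALAAAAAAL"
        assert assign_register(seq, [1]) == "abcdefgabcdefga"

    def test_auto_frame_matches_anchored(self):
        seq = "LAAAAAALAAAAAAL"
        assert assign_register(seq) == assign_register(seq, [1])

    def test_incongruent_anchors_rejected(self):
        with pytest.raises(RegisterError):
            assign_register("L" * 20, [1, 9])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            assign_register("")


class TestBuildGeometry:
    def test_chain_axis_separation_is_twice_radius(self, ideal_dimer):
        a = chain_axis_point(ideal_dimer, "A", 10)
        b = chain_axis_point(ideal_dimer, "B", 10)
        sep = np.linalg.norm((a - b)[:2])
        assert sep == pytest.approx(2 * 4.9, abs=0.2)

    def test_axial_length_matches_rise(self, ideal_dimer):
        z = [a.coord[2] for r in ideal_dimer.residues() for a in r.atoms
             if a.name in ("N", "CA", "C")]
        assert max(z) - min(z) == pytest.approx(28 * 1.51, abs=1.5)

    def test_ca_ca_virtual_bond(self, ideal_dimer):
        for cid in "AB":
            cas = np.array([r.atom("CA").coord for r in ideal_dimer.chains[cid]])
            d = np.linalg.norm(np.diff(cas, axis=0), axis=1)
            assert d.min() > 3.7 and d.max() < 3.9

    def test_core_positions_have_shortest_interchain_cb(self, ideal_dimer):
        reg = "abcdefg" * 4
        cb_b = [r.atom("CB").coord for r in ideal_dimer.chains["B"] if r.atom("CB")]
        mins = {}
        for i, r in enumerate(ideal_dimer.chains["A"]):
            if r.atom("CB") is None:
                continue
            d = min(np.linalg.norm(r.atom("CB").coord - q) for q in cb_b)
            mins.setdefault(reg[i], []).append(d)
        core = np.mean(mins["a"] + mins["d"])
        rim = np.mean(sum((mins[k] for k in "bcefg"), []))
        assert core < rim
        means = {k: np.mean(v) for k, v in mins.items()}
        two_smallest = sorted(means, key=means.get)[:2]
        assert set(two_smallest) == {"a", "d"}

    def test_register_shift_by_seven_leaves_geometry_unchanged(self):
        seq = "LAAKQAE" * 4
        reg = assign_register(seq, [1])
        shifted = reg[7:] + reg[:7]
        st1 = build_bundle(BundleSpec([ChainSpec(seq, reg, 1, "A", "A"),
                                       ChainSpec(seq, reg, 1, "B", "B")]))
        st2 = build_bundle(BundleSpec([ChainSpec(seq, shifted, 1, "A", "A"),
                                       ChainSpec(seq, shifted, 1, "B", "B")]))
        assert np.abs(st1.coords() - st2.coords()).max() < 1e-9

    def test_left_handed_supercoil(self, ideal_dimer):
        # chain-axis azimuth must decrease as z grows: left-handed wind
        phases = []
        for start in (0, 7, 14, 21):
            p = chain_axis_point(ideal_dimer, "A", start)
            phases.append(np.degrees(np.arctan2(p[1], p[0])))
        unwrapped = np.unwrap(np.radians(phases))
        assert np.all(np.diff(unwrapped) < 0)

    def test_cyclic_symmetry_of_identical_chains(self, ideal_dimer):
        xa = np.array([a.coord for r in ideal_dimer.chains["A"] for a in r.atoms])
        xb = np.array([a.coord for r in ideal_dimer.chains["B"] for a in r.atoms])
        flip = np.diag([-1.0, -1.0, 1.0])  # 180 deg about the bundle axis
        rmsd = np.sqrt(((xa @ flip.T - xb) ** 2).sum(axis=1).mean())
        assert rmsd < 1e-6

    def test_backbone_clash_raises_geometry_error(self):
        seq = "LAAKQAE" * 2
        reg = assign_register(seq, [1])
        spec = BundleSpec([ChainSpec(seq, reg, 1, "A", "A"),
                           ChainSpec(seq, reg, 1, "B", "B")])
        with pytest.raises(GeometryError, match="clash"):
            build_bundle(spec, CrickParameters(superhelix_radius=1.5))

    def test_antiparallel_rejected(self):
        seq = "LAAKQAE" * 2
        reg = assign_register(seq, [1])
        with pytest.raises(GeometryError, match="parallel"):
            BundleSpec([ChainSpec(seq, reg, 1, "A", "A"),
                        ChainSpec(seq, reg, 1, "B", "B")],
                       orientation="antiparallel")

    def test_declared_break_bulges_outward(self):
        seq = "LAAKQAE" * 4
        reg = assign_register(seq, [1])
        spec = BundleSpec([ChainSpec(seq, reg, 1, "A", "A"),
                           ChainSpec(seq, reg, 1, "B", "B")],
                          breaks=[(0, (13, 16), "turn")])
        st = build_bundle(spec)
        ref = build_bundle(BundleSpec([ChainSpec(seq, reg, 1, "A", "A"),
                                       ChainSpec(seq, reg, 1, "B", "B")]))
        moved = [np.linalg.norm(r1.atom("CA").coord - r2.atom("CA").coord)
                 for r1, r2 in zip(st.chains["A"], ref.chains["A"])]
        assert max(moved[12:16]) > 0.5
        assert max(moved[:10]) < 1e-9


class TestCrickParameters:
    @pytest.mark.parametrize("kwargs", [
        {"superhelix_radius": -1.0},
        {"rise_per_residue": 0.5},
        {"rise_per_residue": 2.5},
        {"pitch": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CrickParameters(**kwargs)

    def test_default_interface_phase_centres_core(self):
        p = CrickParameters()
        # phases of a and d bracket the inward direction (180 deg):
        # circular mean of the two unit vectors points at 180
        psi_a = np.radians(p.interface_phase_deg)
        psi_d = np.radians(p.interface_phase_deg + 3 * p.omega1_deg)
        v = np.array([np.cos(psi_a) + np.cos(psi_d), np.sin(psi_a) + np.sin(psi_d)])
        mid = np.degrees(np.arctan2(v[1], v[0])) % 360
        assert mid == pytest.approx(180.0, abs=1e-6)


class TestEnumerateStoichiometries:
    SEQ_A = "LAAKQAE" * 4
    SEQ_B = "LQEKVAE" * 4

    def test_four_specs_with_expected_helix_counts(self):
        specs = enumerate_stoichiometries(self.SEQ_A, self.SEQ_B, "FtsB", "FtsL")
        assert [len(s.chains) for s in specs] == [2, 3, 3, 4]
        assert specs[0].composition == {"FtsB": 1, "FtsL": 1}
        assert specs[1].composition == {"FtsB": 2, "FtsL": 1}
        assert specs[2].composition == {"FtsB": 1, "FtsL": 2}
        assert specs[3].composition == {"FtsB": 2, "FtsL": 2}

    def test_tetramer_alternates_and_pairs_heterodimers(self):
        specs = enumerate_stoichiometries(self.SEQ_A, self.SEQ_B, "FtsB", "FtsL")
        tet = specs[3]
        assert [c.identity for c in tet.chains] == ["FtsB", "FtsL", "FtsB", "FtsL"]
        assert tet.pairing == [(0, 1), (2, 3)]

    def test_identical_proteins_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            enumerate_stoichiometries(self.SEQ_A, self.SEQ_A)

    def test_break_motif_declared_only_for_tetramer(self):
        seq_b = self.SEQ_B[:14] + "GDHS" + self.SEQ_B[18:]
        specs = enumerate_stoichiometries(self.SEQ_A, seq_b, "FtsB", "FtsL")
        assert all(not s.breaks for s in specs[:3])
        breaks = specs[3].breaks
        assert len(breaks) == 2  # both FtsL-identity chains
        for ci, (lo, hi), kind in breaks:
            assert kind == "turn" and hi - lo == 3
            assert specs[3].chains[ci].identity == "FtsL"


class TestPentamerRule:
    def test_trp_at_core_admits(self):
        seq = "WAALAAA" * 3
        reg = assign_register(seq, [1])
        ok, reason = pentamer_admissible([seq] * 5, [reg] * 5)
        assert ok

    def test_no_bulky_core_rejects(self):
        seq = "LAAKQAE" * 3
        reg = assign_register(seq, [1])
        ok, reason = pentamer_admissible([seq] * 5, [reg] * 5)
        assert not ok
        assert "excluded" in reason

    def test_fixture_sequences_rejected(self):
        from bundledock.pipeline import _fixture_sequences

        a, b, _, _ = _fixture_sequences()
        ra, rb = assign_register(a), assign_register(b)
        ok, _ = pentamer_admissible([a, b, a, b, a], [ra, rb, ra, rb, ra])
        assert not ok

    def test_empty_core_occupancy_false(self):
        ok, _ = pentamer_admissible([], [])
        assert not ok
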