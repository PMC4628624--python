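"""Ensemble conformational analysis: torsions, turns, H-bonds, Rg, rings."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepmicelle.conformation import (
    TURN_TEMPLATES,
    backbone_angles,
    classify_fragment,
    detect_turns,
    ensemble_rmsd,
    hbond_occupancy,
    radius_of_gyration,
    ring_descriptors,
)
from pepmicelle.core import (
    Atom,
    AtomSelection,
    Conformation,
    Ensemble,
    PeptideTopology,
    Residue,
    dihedral_angle,
    parse_selection,
)
from pepmicelle.synthetic import AVP_SEQUENCE, BuildSpec, build_peptide, jittered_ensemble

from conftest import peptide_with_angles, turn_angles


class TestBackboneAngles:
    def test_builder_round_trip(self):
        angles = [(-57.0, -47.0, 180.0)] * 9
        topo, conf = peptide_with_angles(angles)
        ba = backbone_angles(Ensemble(topo, [conf]))
        np.testing.assert_allclose(ba.phi[0, 1:], -57.0, atol=0.5)
        np.testing.assert_allclose(ba.psi[0, :-1], -47.0, atol=0.5)

    def test_mirror_negates_angles(self):
        angles = [(-57.0, -47.0, 180.0)] * 9
        topo, conf = peptide_with_angles(angles)
        mirrored = Conformation(conf.coordinates * np.array([1.0, 1.0, -1.0]))
        a = backbone_angles(Ensemble(topo, [conf]))
        b = backbone_angles(Ensemble(topo, [mirrored]))
        mask = ~np.isnan(a.phi)
        np.testing.assert_allclose(b.phi[mask], -a.phi[mask], atol=1e-8)

    def test_terminal_angles_undefined(self, single_frame_ensemble):
        ba = backbone_angles(single_frame_ensemble)
        assert np.isnan(ba.phi[0, 0]) and np.isnan(ba.omega[0, 0])
        assert np.isnan(ba.psi[0, -1])  # Gly9


class TestTurnTyping:
    def test_primed_templates_are_negated(self):
        for label, t in TURN_TEMPLATES.items():
            partner = TURN_TEMPLATES[t.mirrored().label]
            assert partner.angles == tuple(-a for a in t.angles)

    def test_type_ii_template_constant(self):
        # the type II ideal geometry fixes phi(i+2) at +80 degrees
        assert TURN_TEMPLATES["II"].angles == (-60.0, 120.0, 80.0, 0.0)

    def test_exact_ii_prime_fragment(self):
        topo, conf = peptide_with_angles(turn_angles(60.0, -120.0, -80.0, 0.0))
        ens = Ensemble(topo, [conf])
        turns = detect_turns(backbone_angles(ens), ens)
        best = [t for t in turns if t.start_residue == 6]
        assert best and best[0].turn_type == "II'"
        assert best[0].max_deviation == pytest.approx(0.0, abs=1e-6)
        assert best[0].occupancy == 1.0

    def test_mirror_gives_primed_partner(self):
        topo, conf = peptide_with_angles(turn_angles(60.0, -120.0, -80.0, 0.0))
        mirrored = Conformation(conf.coordinates * np.array([-1.0, 1.0, 1.0]))
        ens = Ensemble(topo, [mirrored])
        turns = [t for t in detect_turns(backbone_angles(ens), ens) if t.start_residue == 6]
        assert turns and turns[0].turn_type == "II"

    @pytest.mark.parametrize("label", ["I", "I'", "II", "II'", "III", "VIII'"])
    def test_typing_commutes_with_mirror(self, label):
        t = TURN_TEMPLATES[label]
        got, dev = classify_fragment(*t.angles)
        assert got == label and dev == pytest.approx(0.0)
        mirrored, _ = classify_fragment(*(-a for a in t.angles))
        assert mirrored == t.mirrored().label

    def test_zero_tolerance_accepts_only_exact(self):
        t = TURN_TEMPLATES["II"]
        assert classify_fragment(*t.angles, tol_main=0.0, tol_one=0.0)[0] == "II"
        off = (t.angles[0] + 5.0,) + t.angles[1:]
        assert classify_fragment(*off, tol_main=0.0, tol_one=0.0)[0] in ("IV", "VII")

    def test_one_torsion_within_wider_band_still_matches(self):
        t = TURN_TEMPLATES["II"]
        off = (t.angles[0] + 40.0,) + t.angles[1:]  # one deviation in (30, 45]
        assert classify_fragment(*off)[0] == "II"
        off2 = (t.angles[0] + 40.0, t.angles[1] + 40.0) + t.angles[2:]
        assert classify_fragment(*off2)[0] != "II"  # two wide deviations

    def test_type_vii_kink(self):
        label, dev = classify_fragment(-120.0, 175.0, 20.0, 130.0)
        assert label == "VII" and dev == pytest.approx(5.0)

    def test_extended_chain_has_no_turn(self):
        angles = [(-120.0, 130.0, 180.0)] * 9
        topo, conf = peptide_with_angles(angles)
        ens = Ensemble(topo, [conf])
        assert detect_turns(backbone_angles(ens), ens) == []

    def test_distance_gated_fallback_is_type_iv(self):
        # torsions that close the chain but match no template
        topo, conf = peptide_with_angles(turn_angles(-100.0, 60.0, 70.0, 60.0))
        ens = Ensemble(topo, [conf])
        turns = {t.start_residue: t for t in detect_turns(backbone_angles(ens), ens)}
        if 6 in turns:  # distance criterion satisfied for this geometry
            assert turns[6].turn_type in ("IV", "VII")

    def test_occupancy_counts_matching_frames(self):
        t_on, c_on = peptide_with_angles(turn_angles(60.0, -120.0, -80.0, 0.0))
        _, c_off = peptide_with_angles([(-120.0, 130.0, 180.0)] * 9)
        frames = [c_on] * 8 + [c_off] * 2
        ens = Ensemble(t_on, frames)
        turns = [t for t in detect_turns(backbone_angles(ens), ens)
                 if t.start_residue == 6 and t.turn_type == "II'"]
        assert turns and turns[0].occupancy == pytest.approx(0.8)


def _hbond_toy(n_o_distance, angle_deg):
    """Two-residue topology with an explicit donor H placed to give the
    requested N...O distance and N-H...O angle."""
    res1 = Residue("ALA", "L", [Atom("N", "N"), Atom("CA", "C"), Atom("C", "C"), Atom("O", "O")])
    res2 = Residue("ALA", "L", [Atom("N", "N"), Atom("H", "H"), Atom("CA", "C"),
                                Atom("C", "C"), Atom("O", "O")])
    topo = PeptideTopology([res1, res2])
    # residue 1 backbone far away except its carbonyl O; residue 2 donor
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.01, 0.0, 0.0])
    # acceptor O placed so that angle(N-H...O) = angle_deg and |N-O| = d
    theta = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    o = None
    # solve for O along 'direction' from H such that |N-O| = n_o_distance
    a = 1.0
    b = 2 * np.dot(h - n, direction)
    c = np.dot(h - n, h - n) - n_o_distance**2
    t = (-b + np.sqrt(b * b - 4 * a * c)) / 2
    o = h + t * direction
    coords = np.array([
        [20.0, 0, 0], [21.5, 0, 0], [23.0, 0, 0], o,      # res1: N CA C O
        n, h, [-1.5, 0.5, 0], [-3.0, 0.5, 0], [-4.0, 1.5, 0],  # res2
    ])
    return Ensemble(topo, [Conformation(coords)])


class TestHydrogenBonds:
    def test_geometry_inside_cutoffs_counted(self):
        ens = _hbond_toy(2.9, 165.0)
        bonds = hbond_occupancy(ens, rebuild_h=False)
        assert any(b.donor_residue == 2 and b.acceptor_residue == 1 for b in bonds)

    def test_long_distance_not_counted(self):
        ens = _hbond_toy(3.6, 165.0)
        assert hbond_occupancy(ens, rebuild_h=False) == []

    def test_bent_geometry_not_counted(self):
        ens = _hbond_toy(2.9, 100.0)
        assert hbond_occupancy(ens, rebuild_h=False) == []

    def test_planted_occupancy_recovered(self):
        """A bond present in exactly 80% of frames reports occupancy 0.80."""
        on = _hbond_toy(2.9, 165.0)
        off = _hbond_toy(3.6, 165.0)
        ens = Ensemble(on.topology, [on.frames[0]] * 16 + [off.frames[0]] * 4)
        bonds = hbond_occupancy(ens, rebuild_h=False)
        assert bonds and bonds[0].occupancy == pytest.approx(0.80)
        assert bonds[0].label == "HN2-CO1"

    def test_missing_h_without_rebuild_raises(self, single_frame_ensemble):
        topo = single_frame_ensemble.topology
        stripped = PeptideTopology(
            [Residue(r.name, r.chirality, [a for a in r.atoms if a.name != "H"])
             for r in topo.residues]
        )
        keep = [i for i, nm in enumerate(topo.atom_names()) if nm != "H"
                or topo.atom_residue_indices()[i] == 1]
        names = topo.atom_names()
        keep = [i for i in range(len(names))
                if not (names[i] == "H")]
        coords = single_frame_ensemble.frames[0].coordinates[keep]
        ens = Ensemble(stripped, [Conformation(coords)])
        with pytest.raises(ValueError):
            hbond_occupancy(ens, rebuild_h=False)
        assert isinstance(hbond_occupancy(ens, rebuild_h=True), list)


class TestRadiusOfGyration:
    def _topo(self, n, masses=None):
        masses = masses or [12.0] * n
        return PeptideTopology(
            [Residue("UNK", "achiral", [Atom(f"C{i}", "C", m) for i, m in enumerate(masses)])]
        )

    def test_single_atom_zero(self):
        topo = self._topo(1)
        rg = radius_of_gyration(topo, Conformation(np.array([[1.0, 2, 3]])), AtomSelection((0,)))
        assert rg == 0.0

    def test_two_unit_masses(self):
        topo = self._topo(2)
        frame = Conformation(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert radius_of_gyration(topo, frame, AtomSelection((0, 1))) == pytest.approx(1.0)

    def test_cube_corners_closed_form(self):
        a = 3.0
        corners = np.array([[x, y, z] for x in (0, a) for y in (0, a) for z in (0, a)], float)
        topo = self._topo(8)
        rg = radius_of_gyration(topo, Conformation(corners), AtomSelection(tuple(range(8))))
        assert rg == pytest.approx(a * np.sqrt(3) / 2)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(2)
        xyz = rng.normal(size=(10, 3)) * 3
        topo = self._topo(10, list(rng.uniform(1, 16, 10)))
        sel = AtomSelection(tuple(range(10)))
        R = Rotation.random(random_state=np.random.RandomState(9)).as_matrix()
        r1 = radius_of_gyration(topo, Conformation(xyz), sel)
        r2 = radius_of_gyration(topo, Conformation(xyz @ R.T + 5.0), sel)
        assert r1 == pytest.approx(r2, abs=1e-10)


def _ring_pair_ensemble(thetas, ring_offset=2.0, ca_sep=3.0):
    """Minimal aromatic pair: ring b rotated about the CA-CA axis by theta."""
    def ring_atoms():
        return [Atom("CA", "C"), Atom("CG", "C"), Atom("CE1", "C"), Atom("CE2", "C")]

    topo = PeptideTopology([Residue("TYR", "L", ring_atoms()),
                            Residue("PHE", "L", ring_atoms())])
    frames = []
    spread = np.array([[0.0, 0.3, 0.0], [0.0, -0.15, 0.2], [0.0, -0.15, -0.2]])
    for th in np.atleast_1d(thetas):
        th = np.radians(th)
        ca_a, ca_b = np.array([0.0, 0, 0]), np.array([ca_sep, 0, 0])
        com_a = ca_a + np.array([0.0, ring_offset, 0.0])
        com_b = ca_b + ring_offset * np.array([0.0, np.cos(th), np.sin(th)])
        ring_a = com_a + spread
        ring_b = com_b + spread @ Rotation.from_euler("x", th).as_matrix().T
        coords = np.vstack([[ca_a], ring_a, [ca_b], ring_b])
        frames.append(Conformation(coords))
    return Ensemble(topo, frames)


class TestRingDescriptors:
    def test_coplanar_same_side_is_zero(self):
        d = ring_descriptors(_ring_pair_ensemble([0.0]), res_a=1, res_b=2)
        assert d.angles[0] == pytest.approx(0.0, abs=1e-8)

    def test_coplanar_opposite_side_is_180(self):
        d = ring_descriptors(_ring_pair_ensemble([180.0]), res_a=1, res_b=2)
        assert abs(d.angles[0]) == pytest.approx(180.0, abs=1e-8)

    def test_angle_sign_flips_under_reflection(self):
        ens = _ring_pair_ensemble([35.0])
        ref = Conformation(ens.frames[0].coordinates * np.array([1.0, 1.0, -1.0]))
        d1 = ring_descriptors(ens, res_a=1, res_b=2)
        d2 = ring_descriptors(Ensemble(ens.topology, [ref]), res_a=1, res_b=2)
        assert d2.angles[0] == pytest.approx(-d1.angles[0], abs=1e-8)

    def test_circular_mean_recovers_planted_angle(self):
        rng = np.random.default_rng(8)
        thetas = rng.normal(20.0, 10.0, 200)
        d = ring_descriptors(_ring_pair_ensemble(thetas), res_a=1, res_b=2)
        assert abs(d.circular_mean_angle) == pytest.approx(20.0, abs=3.0)
        assert d.circular_std_angle == pytest.approx(10.0, abs=3.0)

    def test_distance_matches_construction(self):
        d = ring_descriptors(_ring_pair_ensemble([90.0], ring_offset=2.0, ca_sep=3.0),
                             res_a=1, res_b=2)
        expected = np.linalg.norm([3.0, -2.0, 2.0] - np.array([0.0, 0, 0]))
        assert d.distances[0] == pytest.approx(expected, abs=1e-8)

    def test_avp_like_peptide_descriptors_finite(self, helix_ensemble):
        d = ring_descriptors(helix_ensemble)
        assert np.all(d.distances > 0)
        assert -180.0 < d.circular_mean_angle <= 180.0


class TestEnsembleRmsd:
    def test_identical_frames_zero(self, helix):
        topo, conf = helix
        ens = Ensemble(topo, [conf, conf, conf])
        sel = parse_selection(topo, "backbone:1-6")
        assert ensemble_rmsd(ens, sel) == pytest.approx(0.0, abs=1e-10)

    def test_rigid_rotation_only_zero(self, helix):
        topo, conf = helix
        R = Rotation.random(random_state=np.random.RandomState(4)).as_matrix()
        rotated = Conformation(conf.coordinates @ R.T + 3.0)
        ens = Ensemble(topo, [conf, rotated])
        sel = parse_selection(topo, "heavy")
        assert ensemble_rmsd(ens, sel) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_jitter_expectation(self, helix):
        """Isotropic jitter sigma per coordinate gives mean frame-to-mean
        RMSD ~ sigma*sqrt(3)*sqrt((F-1)/F), slightly reduced by the fit."""
        topo, conf = helix
        sigma, n_frames = 0.2, 60
        ens = jittered_ensemble(topo, conf, n_frames, sigma=sigma, seed=23)
        sel = parse_selection(topo, "heavy")
        expected = sigma * np.sqrt(3) * np.sqrt((n_frames - 1) / n_frames)
        assert ensemble_rmsd(ens, sel) == pytest.approx(expected, rel=0.08)

    def test_pairwise_method_two_frames(self, helix):
        topo, conf = helix
        jit = Conformation(conf.coordinates + 0.3)
        jit.coordinates[0] += [1.0, 0, 0]
        ens = Ensemble(topo, [conf, jit])
        sel = parse_selection(topo, "heavy")
        pairwise = ensemble_rmsd(ens, sel, method="pairwise")
        assert pairwise > 0
        with pytest.raises(ValueError):
            ensemble_rmsd(ens, sel, method="nope")
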