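"""NMR observable -> restraint conversion rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepmicelle.datasets import ARG8_COUPLINGS, PRO7_SHIFTS
from pepmicelle.nmr import (
    CouplingRecord,
    NOEPeak,
    ShiftTable,
    TempSeries,
    build_restraint_set,
    calibrate_noe,
    classify_hbond,
    ispa_distance,
    j_to_phi_interval,
    proline_isomer,
    reference_carbon,
    temp_coefficient,
)
from pepmicelle.synthetic import AVP_SEQUENCE, BuildSpec, build_peptide


class TestJToPhi:
    @pytest.mark.parametrize(
        "j,chir,lo,hi",
        [
            (10.2, "D", 100.0, 140.0),    # measured d-Arg8 coupling
            (11.8, "L", -140.0, -100.0),  # measured l-Arg8 coupling (inverso analogue)
            (5.0, "L", -90.0, -30.0),
            (5.0, "D", 30.0, 90.0),
            (7.0, "L", -120.0, -60.0),
            (8.5, "L", -160.0, -80.0),
            # left-closed bins: boundary J goes to the higher-J rule
            (6.0, "L", -120.0, -60.0),
            (8.0, "L", -160.0, -80.0),
            (9.0, "L", -140.0, -100.0),
        ],
    )
    def test_interval_rules(self, j, chir, lo, hi):
        r = j_to_phi_interval(CouplingRecord(8, j, chir))
        assert (r.lo, r.hi) == (lo, hi)
        assert r.force_constant == 2.0

    def test_measured_couplings_from_dataset(self):
        assert j_to_phi_interval(ARG8_COUPLINGS["DAVP"]).lo == 100.0
        assert j_to_phi_interval(ARG8_COUPLINGS["iDAVP"]).hi == -100.0

    @given(st.floats(min_value=0.0, max_value=15.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_mirror_symmetry(self, j):
        """d interval = l interval negated and endpoint-swapped; equal widths."""
        l = j_to_phi_interval(CouplingRecord(1, j, "L"))
        d = j_to_phi_interval(CouplingRecord(1, j, "D"))
        assert (d.lo, d.hi) == (-l.hi, -l.lo)
        assert d.width == l.width

    def test_negative_j_rejected(self):
        with pytest.raises(ValueError):
            CouplingRecord(1, -0.1, "L")


class TestCalibrateNoe:
    def test_identity_at_reference_volume(self):
        assert ispa_distance(5.0, 5.0, 2.2) == pytest.approx(2.2)

    def test_sixty_fourfold_volume_is_double_distance(self):
        # 64^(1/6) = 2 exactly
        assert ispa_distance(1.0, 64.0, 2.0) == pytest.approx(4.0, abs=1e-12)

    def test_monotone_and_clipped(self):
        peaks = [NOEPeak("a", "b", v) for v in (100.0, 10.0, 1.0, 0.001)]
        out = calibrate_noe(peaks, reference=(("x", "y"), 2.5), reference_volume=10.0)
        uppers = [r.upper for r in out]
        assert uppers == sorted(uppers)
        assert all(u <= 6.0 for u in uppers)

    def test_pseudo_atom_corrections(self):
        base, methyl, arom = calibrate_noe(
            [NOEPeak("a", "b", 1.0), NOEPeak("a", "m", 1.0, methyl=True),
             NOEPeak("a", "q", 1.0, aromatic=True)],
            reference=(("x", "y"), 3.0), reference_volume=1.0,
        )
        assert methyl.upper == pytest.approx(base.upper + 1.0)
        assert arom.upper == pytest.approx(base.upper + 0.9)

    @given(st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=2, max_size=20),
           st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, volumes, c):
        peaks = [NOEPeak(f"a{i}", f"b{i}", v) for i, v in enumerate(volumes)]
        scaled = [NOEPeak(f"a{i}", f"b{i}", v * c) for i, v in enumerate(volumes)]
        r1 = calibrate_noe(peaks, reference=(("x", "y"), 2.0), reference_volume=1.0)
        r2 = calibrate_noe(scaled, reference=(("x", "y"), 2.0), reference_volume=c)
        for a, b in zip(r1, r2):
            assert a.upper == pytest.approx(b.upper, rel=1e-9)

    def test_distance_order_reverses_volume_order(self):
        rng = np.random.default_rng(5)
        vols = rng.uniform(0.01, 50.0, 30)
        peaks = [NOEPeak(f"a{i}", f"b{i}", v) for i, v in enumerate(vols)]
        out = calibrate_noe(peaks, reference=(("x", "y"), 2.0), reference_volume=1.0)
        d = np.array([ispa_distance(p.volume, 1.0, 2.0) for p in peaks])
        by_distance = np.argsort(d)
        by_volume_desc = np.argsort(-vols)
        np.testing.assert_array_equal(by_distance, by_volume_desc)
        assert len(out) == len(peaks)


class TestTempCoefficient:
    def test_constant_shifts_zero_slope(self):
        s = TempSeries(3, [(t, 8.1) for t in (5.0, 20.0, 50.0)])
        assert temp_coefficient(s) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        s = TempSeries(3, [(300.0, 8.000), (310.0, 7.990)])
        assert temp_coefficient(s) == pytest.approx(-1.0)

    def test_exact_linear_recovery(self):
        temps = [5.0, 10.0, 20.0, 32.0, 40.0, 50.0]
        s = TempSeries(6, [(t, 8.5 - 4.2e-3 * t) for t in temps])
        assert temp_coefficient(s) == pytest.approx(-4.2, abs=1e-10)

    def test_noisy_recovery_within_ci(self):
        rng = np.random.default_rng(17)
        temps = np.linspace(5, 50, 10)
        vals = []
        for _ in range(50):
            s = TempSeries(1, [(t, 8.5 - 4.2e-3 * t + rng.normal(0, 0.005)) for t in temps])
            vals.append(temp_coefficient(s))
        assert np.mean(vals) == pytest.approx(-4.2, abs=3 * np.std(vals) / np.sqrt(50) + 0.05)

    def test_identical_temperatures_raise(self):
        with pytest.raises(ValueError):
            TempSeries(1, [(300.0, 8.0), (300.0, 8.1)])

    def test_classification_invariant_to_shift_offset(self):
        temps = [5.0, 20.0, 50.0]
        for offset in (0.0, 0.5, -1.0):
            s = TempSeries(1, [(t, 8.0 + offset - 2.0e-3 * t) for t in temps])
            assert classify_hbond(temp_coefficient(s)) == "strong"


class TestClassifyHbond:
    @pytest.mark.parametrize(
        "coef,cls",
        [(-2.7, "strong"), (-3.5, "weak"), (-5.0, "none"), (-7.0, "none"),
         (-3.0, "weak"), (0.0, "strong"), (1.2, "strong")],
    )
    def test_classes(self, coef, cls):
        assert classify_hbond(coef) == cls

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_hbond(float("nan"))


class TestProlineIsomer:
    def test_avp_pro7_is_trans(self):
        isomer, delta = proline_isomer(PRO7_SHIFTS("AVP"), 7)
        assert isomer == "trans"
        assert delta == pytest.approx(29.46 - 25.17, abs=1e-9)
        assert delta > 4.2  # clears the published trans lower bound

    def test_large_delta_is_cis(self):
        table = ShiftTable({(7, "CB"): 34.0, (7, "CG"): 24.4}, residue_names={7: "PRO"})
        assert proline_isomer(table, 7)[0] == "cis"

    def test_missing_gamma_undetermined(self):
        isomer, delta = proline_isomer(PRO7_SHIFTS("DAVP"), 7)
        assert isomer == "undetermined" and delta is None

    def test_non_proline_rejected(self):
        table = ShiftTable({(2, "CB"): 30.0, (2, "CG"): 25.0}, residue_names={2: "TYR"})
        with pytest.raises(ValueError):
            proline_isomer(table, 2)


class TestReferenceCarbon:
    def test_multiplication(self):
        assert reference_carbon(500.0e6) == pytest.approx(125.724765e6)

    def test_zero_and_linearity(self):
        assert reference_carbon(0.0) == 0.0
        assert reference_carbon(800.0) / reference_carbon(400.0) == pytest.approx(2.0)


class TestBuildRestraintSet:
    def _topology(self):
        return build_peptide(BuildSpec(sequence=AVP_SEQUENCE))[0]

    def test_peak_count_preserved(self):
        peaks = [NOEPeak(f"a{i}", f"b{i}", 1.0 + i) for i in range(75)]
        rset = build_restraint_set(peaks=peaks, noe_reference_volume=10.0)
        assert rset.counts()["distance"] == 75
        assert rset.metadata["calibration"] == "ispa-standin"

    def test_empty_inputs_give_empty_set(self):
        rset = build_restraint_set()
        assert rset.counts() == {"distance": 0, "phi": 0, "omega": 0}

    def test_duplicate_pair_keeps_tighter(self):
        # same pair at two volumes; the larger volume gives the tighter bound
        peaks = [NOEPeak("a", "b", 1.0), NOEPeak("a", "b", 8.0)]
        rset = build_restraint_set(peaks=peaks, noe_reference_volume=1.0,
                                   noe_reference=(("x", "y"), 3.0))
        assert rset.counts()["distance"] == 1
        tight = calibrate_noe([peaks[1]], reference=(("x", "y"), 3.0),
                              reference_volume=1.0)[0]
        assert rset.distances[0].upper == pytest.approx(tight.upper)

    def test_phi_atoms_and_gly_exclusion(self):
        topo = self._topology()
        couplings = [CouplingRecord(4, 9.1, "L"), CouplingRecord(9, 6.0, "L")]
        rset = build_restraint_set(couplings=couplings, topology=topo)
        assert rset.counts()["phi"] == 1  # Gly9 dropped
        atoms = rset.dihedrals[0].atom_indices
        names = topo.atom_names()
        assert [names[i] for i in atoms] == ["C", "N", "CA", "C"]

    def test_omega_restraints_force_constant(self):
        topo = self._topology()
        rset = build_restraint_set(omega_trans=True, topology=topo)
        assert rset.counts()["omega"] == 8  # peptide bonds 2..9
        assert all(d.force_constant == 50.0 for d in rset.dihedrals)
        assert all(d.lo < 180.0 < d.hi for d in rset.dihedrals)
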