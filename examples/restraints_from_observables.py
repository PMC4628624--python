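"""Convert measured NMR observables into conformational restraints.

Uses the published residue-8 couplings and Pro7 carbon shifts of the
vasopressin analogues, plus a small synthetic NOE peak list, and prints
the derived phi intervals, the proline isomer call and the distance
bounds.  The phi intervals show the d-amino-acid mirror rule in action:
the same high coupling maps to opposite Ramachandran regions for l and d
residues.
"""

from pepmicelle.datasets import ARG8_COUPLINGS, PRO7_SHIFTS
from pepmicelle.nmr import NOEPeak, build_restraint_set, j_to_phi_interval, proline_isomer

for name, rec in ARG8_COUPLINGS.items():
    r = j_to_phi_interval(rec)
    print(f"{name:6s} Arg8 ({rec.chirality}, J = {rec.j_hnha:4.1f} Hz) -> "
          f"phi in [{r.lo:6.1f}, {r.hi:6.1f}] deg")

isomer, delta = proline_isomer(PRO7_SHIFTS("AVP"), 7)
print(f"\nAVP Pro7: delta(Cb) - delta(Cg) = {delta:.2f} ppm -> {isomer} peptide bond")

peaks = [
    NOEPeak("2:HN", "2:HA", 1.00),            # reference-strength peak
    NOEPeak("6:HN", "3:HA", 0.18),            # weaker -> longer distance
    NOEPeak("2:HN", "7:QD", 0.05, aromatic=True),
]
rset = build_restraint_set(peaks=peaks, noe_reference_volume=1.0,
                           noe_reference=(("2:HN", "2:HA"), 2.2))
print(f"\n{rset.counts()['distance']} distance restraints "
      f"(calibration: {rset.metadata['calibration']}):")
for d in rset.distances:
    print(f"  {d.atom_pair[0]:6s} {d.atom_pair[1]:6s} upper {d.upper:.2f} A  f={d.force_constant:g}")
print("\nLarger volumes give shorter upper bounds (r^-6 inversion); the")
print("aromatic pair carries a +0.9 A pseudo-atom correction.")
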