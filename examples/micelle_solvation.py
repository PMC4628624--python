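"""Solvation analysis of a peptide on a toy SDS/DPC micelle.

Generates a periodic box with a spherical pseudo-micelle (head-group
sites on a shell, hydrophobic core sites inside, ideal-gas water
outside), adsorbs the peptide on the micelle surface, and computes an
RDF against the head groups, per-residue hydration numbers and the
contact classification.
"""

from pepmicelle.solvation import GroupSpec, contact_profile, hydration_number, rdf
from pepmicelle.synthetic import BoxSpec, BuildSpec, build_peptide, composition_report, make_box

topo, conf = build_peptide(BuildSpec())
spec = BoxSpec(edge=44.0, shell_radius=13.0, n_sds=20, n_dpc=60, n_core=120,
               water_density=0.02, peptide=(topo, conf),
               peptide_placement="surface", n_frames=6, seed=7)
ens = make_box(spec)

rep = composition_report({"SDS": spec.n_sds, "DPC": spec.n_dpc}, spec.edge)
print(f"box: {spec.edge} A, SDS:DPC mole ratio 1:{rep.sds_to_dpc:.0f}")

res = rdf(ens, GroupSpec("sidechain:3"), GroupSpec("headgroups"), r_max=12.0, dr=0.5)
print("\nPhe3 side chain vs head groups, g(r) (first 10 bins):")
for r, g in zip(res.r[:10], res.g[:10]):
    print(f"  r = {r:5.2f} A   g = {g:6.2f}")

print("\nper-residue hydration numbers (waters within 3.8 A of the side chain):")
for i in (2, 3, 8):
    h = hydration_number(ens, GroupSpec(f"sidechain:{i}"), radius=3.8)
    print(f"  residue {i}: {h:.1f}")

p = contact_profile(ens, 3)
print(f"\nresidue 3 contact class: {p.category} "
      f"(first core contact {p.first_peak_core:.1f} A, head {p.first_peak_head:.1f} A)")
print("\ng(r) > 1 near the shell marks head-group contact; low hydration plus")
print("an early core contact would instead indicate burial in the micelle.")
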