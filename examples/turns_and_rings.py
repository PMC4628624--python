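"""Plant a beta-turn in a synthetic nonapeptide ensemble and recover it.

Builds the vasopressin sequence with an ideal type II' turn at residues
6-9 (the geometry favoured when residue 8 is d-configured), jitters it
into a 50-frame ensemble, and runs turn detection, ensemble RMSD and the
Tyr2/Phe3 aromatic-ring descriptors.
"""

from pepmicelle.conformation import backbone_angles, detect_turns, ensemble_rmsd, ring_descriptors
from pepmicelle.core import parse_selection
from pepmicelle.synthetic import BuildSpec, build_peptide, jittered_ensemble

extended = (-120.0, 130.0, 180.0)
angles = [list(extended) for _ in range(9)]
angles[5][1] = 0.0                      # close the 6..9 loop
angles[6] = [60.0, -120.0, 180.0]       # i+1 of the turn
angles[7] = [-80.0, 0.0, 180.0]         # i+2 of the turn

topo, conf = build_peptide(BuildSpec(angles=[tuple(a) for a in angles]))
ens = jittered_ensemble(topo, conf, n_frames=50, sigma=0.05, seed=1)

print("turn assignments (start residue, type, occupancy):")
for t in detect_turns(backbone_angles(ens), ens):
    print(f"  {t.start_residue},{t.start_residue + 1}  beta {t.turn_type:4s} "
          f"occupancy {t.occupancy:.2f}  max dev {t.max_deviation:.1f} deg")

sel = parse_selection(topo, "backbone:1-6")
print(f"\nensemble RMSD (backbone 1-6): {ensemble_rmsd(ens, sel):.3f} A")

rings = ring_descriptors(ens)  # Tyr2 / Phe3
print(f"ring descriptors: Dis = {rings.mean_distance:.2f} A, "
      f"Ang = {rings.circular_mean_angle:.1f} deg (circ. std {rings.circular_std_angle:.1f})")
print("\nThe planted II' turn is reported at position 6 with occupancy ~1;")
print("the RMSD reflects the 0.05 A/coordinate jitter; Dis/Ang summarise")
print("the mutual arrangement of the two aromatic side chains.")
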