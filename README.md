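# pepmicelle

Analysis tools for the conformational study of small chiral peptides —
arginine-vasopressin (AVP, CYFQNCPRG-NH2 with a Cys1–Cys6 disulfide) and
its d-amino-acid analogues — bound to membrane-mimetic SDS/DPC micelles.
The package converts NMR observables into conformational restraints,
analyses conformational ensembles for reverse turns and aromatic-ring
arrangement, and quantifies peptide–micelle–water contacts in periodic
boxes.  It is aimed at structural-NMR and peptide-modelling practitioners
who have ensembles (multi-model PDB) and tabulated observables rather
than raw spectra.

## What it computes

**Restraints from observables** (`pepmicelle.nmr`)

* ³J(HN–Hα) couplings → φ torsion intervals:
  J < 6 Hz → φ ∈ [−90°, −30°]; 6 ≤ J < 8 → [−120°, −60°];
  8 ≤ J < 9 → [−160°, −80°]; J ≥ 9 → [−140°, −100°], with the
  d-amino-acid mirror rule (φ, ψ → −φ, −ψ): the l interval is negated and
  endpoint-swapped for d residues.
* NOE volumes → upper distance bounds via the isolated-spin-pair relation
  d = d_ref (V_ref/V)^(1/6) with class-wise padding and pseudo-atom
  corrections (a documented stand-in for spectrometer-side class
  calibration, flagged in the output metadata).
* Amide-proton temperature coefficients Δδ/ΔT → hydrogen-bond class
  (strong for −3 < Δδ/ΔT ≤ 0 ppb/K, weak for −5 < Δδ/ΔT ≤ −3, none below).
* Proline Δδ(Cβ−Cγ) → cis/trans isomer; indirect ¹³C referencing via
  Ξ = 0.251449530.

**Ensemble conformational analysis** (`pepmicelle.conformation`)

β-turn detection and Lewis typing (I/I′/II/II′/III/III′/VIII/VIII′, VII
kinks, IV fallback) with ensemble occupancies; turn typing commutes with
mirror symmetry, so d-rich peptides land on the primed templates.
Backbone φ/ψ/ω, hydrogen-bond occupancies, radii of gyration, ensemble
RMSD, and the two aromatic-ring descriptors Dis (ring-centroid distance)
and Ang (four-point torsion ring-COM–Cα–Cα–ring-COM) for the Tyr2/Phe3
pair.

**Solvation** (`pepmicelle.solvation`) — minimum-image RDFs g(r) between
peptide groups and micelle head-group/core sites, running coordination
integrals n(r), hydration numbers (waters within 3.8 Å of a group,
union-counted), and per-residue contact classes
(buried_in_core / interfacial / solvent_exposed).

**Synthetic ground truth** (`pepmicelle.synthetic`) — an ideal-geometry
peptide builder (requested torsions are realised exactly; chirality-aware),
toy micelle+water boxes with known densities, and observable tables
back-computed from structures, so every analysis can be validated by
parameter recovery.

## Worked example

```sh
python examples/restraints_from_observables.py
```

prints

```
AVP    Arg8 (L, J =  8.9 Hz) -> phi in [-160.0,  -80.0] deg
iAVP   Arg8 (D, J =  9.8 Hz) -> phi in [ 100.0,  140.0] deg
DAVP   Arg8 (D, J = 10.2 Hz) -> phi in [ 100.0,  140.0] deg
iDAVP  Arg8 (L, J = 11.8 Hz) -> phi in [-140.0, -100.0] deg

AVP Pro7: delta(Cb) - delta(Cg) = 4.29 ppm -> trans peptide bond
```

The high residue-8 couplings of the d-configured analogues map to the
mirrored φ region [100°, 140°], while the same-magnitude coupling on an
l residue maps to [−140°, −100°] — the chirality-aware conversion at the
heart of restraint generation for d-peptides.  The 4.29 ppm Pro7 shift
difference sits in the trans range, confirming the trans Cys6–Pro7 bond.
The other examples (`turns_and_rings.py`, `micelle_solvation.py`,
`closed_loop_observables.py`) demonstrate turn/ring analysis on planted
ensembles and RDF/hydration analysis on toy micelle boxes.

A thin CLI wraps the same functions:
`pepmicelle synth --kind box --out box.pdb`, then
`pepmicelle rdf --a sidechain:3 --b headgroups box.pdb`, etc.

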