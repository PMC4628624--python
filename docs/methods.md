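# Methods

This note documents the models, rules and numerical choices behind
`pepmicelle`, in the spirit of the methods documentation of mature
simulation-analysis packages.

## Scope and data model

The package analyses conformational ensembles of small chiral peptides;
it does not propagate dynamics.  The central objects are a
`PeptideTopology` (ordered residues with per-residue l/d chirality,
atoms, an optional Cys–Cys disulfide and a C-terminal amide flag), a
`Conformation` (Å coordinates, optional cubic box edge) and an `Ensemble`
(frames sharing one topology).  Residue numbering is 1-based
(Cys1…Gly9 for the vasopressin scaffold); angles are degrees on
(−180°, 180°]; the torsion sign follows the IUPAC convention, so mirror
reflection negates every torsion.  Because the PDB format cannot express
chirality, ensembles with d-residues carry a two-column sidecar file
(residue index, L|D).

## Coupling-to-torsion conversion

³J(HN–Hα) → φ uses an interval rule table for l-residues
(J < 6 Hz → [−90, −30]; 6 ≤ J < 8 → [−120, −60]; 8 ≤ J < 9 → [−160, −80];
J ≥ 9 → [−140, −100] degrees, force constant 2 kcal mol⁻¹ rad⁻²).  The
published rules use strict inequalities on both sides, which leaves the
boundary couplings 6, 8 and 9 Hz unassigned; this package resolves the
ambiguity with left-closed bins (a boundary J goes to the higher-J rule).
d-residues occupy the mirror image of the l Ramachandran region, so the
l interval is negated and endpoint-swapped.  Glycine couplings are
excluded by default: with two degenerate HN–Hα couplings the φ sign is
ambiguous.

## NOE calibration

Cross-peak volumes are inverted with the isolated-spin-pair
approximation d = d_ref (V_ref/V)^(1/6).  The reference pair defaults to
a geminal Hβ pair at 1.78 Å and is user-overridable.  Upper bounds add a
distance-class padding (0.2 Å below 2.7 Å, 0.3 Å to 3.5 Å, 0.5 Å above),
pseudo-atom corrections (+1.0 Å methyl, +0.9 Å aromatic equivalent
pairs), and are clipped to [1.8, 6.0] Å (van-der-Waals floor, spin-
diffusion ceiling); force constant 20 kcal mol⁻¹ rad⁻².  This is a
deliberate, documented stand-in for spectrometer-software class
calibration, whose internal calibration curves are not public; every
restraint set carries `calibration: ispa-standin` in its metadata so
downstream users know the provenance of the bounds.  Duplicate restraints
on one pair keep the tighter bound.  The inversion is scale-invariant in
the volumes and strictly monotone (larger volume, shorter distance).

## Temperature coefficients, proline isomers, referencing

Δδ/ΔT is the ordinary-least-squares slope of the amide shift (ppb)
against temperature.  Classes: (−3, 0] ppb/K strong intramolecular
hydrogen bond, (−5, −3] weak/solvent-shared, ≤ −5 none; boundaries go to
the weaker class; positive coefficients — outside the published rules —
are reported as strong/shielded with a warning.  Proline cis/trans uses
Δδ(Cβ−Cγ) with a 7.0 ppm threshold, the midpoint of the literature
anchors (≈4.5 ppm trans, ≈9.6 ppm cis); a missing shift yields
`undetermined`, never a silent guess.  Indirect ¹³C referencing
multiplies the ¹H zero frequency by Ξ = 0.251449530 exactly.

## Turn detection and typing

A four-residue fragment at i is a turn candidate in a frame when
Cα(i)–Cα(i+3) < 7.0 Å.  Ideal templates (φ(i+1), ψ(i+1), φ(i+2), ψ(i+2)):
I (−60, −30, −90, 0), II (−60, 120, 80, 0), III (−60, −30, −60, −30),
VIII (−60, −30, −120, 120); each primed type is the sign-negated
template, which makes typing commute with mirror symmetry by
construction.  A template matches when all four circular deviations are
≤ 45° with at most one above 30°; the smallest worst-deviation template
wins.  The 30°/45°/7 Å defaults follow the classical turn-classification
convention (the study itself states none) and are exposed as flags.
Type VII is handled as a kink — |ψ(i+1)| ≈ 180° with |φ(i+2)| < 60°, or
the converse — with the deviation measured on the near-180° torsion only,
since no four-angle ideal exists.  Distance-qualified fragments matching
no template are type IV (the literature's miscellaneous class).
Occupancy is the fraction of frames carrying a given (position, type)
assignment.

## Hydrogen bonds, RMSD, ring descriptors

Backbone HN(i)→CO(j) bonds are counted per frame when N⋯O ≤ 3.5 Å and
the N–H⋯O angle ≥ 120°; missing amide hydrogens are rebuilt 1.01 Å from
N along the external bisector of the C′(i−1)–N and Cα–N directions
(prolines and the N-terminus excluded).  "Most populated" bonds are those
ranked by occupancy (≥ 0.3 by convention in reports).

Ensemble RMSD defaults to the mean frame-to-mean-structure RMSD after
per-frame least-squares superposition on the analysis selection (two
refinement passes); the alternative pairwise-mean statistic is one
argument away (`method="pairwise"`), since ensemble-spread conventions
differ between analysis programs.  Superposition is Kabsch via SVD with
a proper-rotation determinant correction; degenerate (collinear)
selections raise instead of returning a spurious fit.

The aromatic descriptors for a residue pair (default Tyr2/Phe3) are
Dis, the distance between ring centers, and Ang, the torsion over (ring
center a, Cα a, Cα b, ring center b).  Ring centers use the IUPAC
C1/C3/C5 carbons — PDB names CG, CE1, CE2 — whose equal masses make the
centroid and center of mass coincide.  Ensemble summaries use the
arithmetic mean for Dis and the circular mean/std for Ang.

## Solvation analysis

RDFs use minimum-image distances in a cubic box (non-cubic boxes are
rejected), bins of width dr = 0.1 Å by default to r_max ≤ edge/2, and the
standard normalisation by shell volume 4πr²dr, B-site density N_B/V and
frame × A-site count; self-pairs are excluded when groups overlap.  The
running integral n(r) is the cumulative mean neighbour count per A site
and is internally consistent with the density-weighted quadrature of
g(r).  Hydration numbers count water *oxygens* within 3.8 Å of any atom
of a group, union-counted so a water bridging two solute atoms counts
once, averaged over frames — molecule-level counting that avoids triple
counting hydrogens.  Two standard report sets are side-chain heavy atoms
and backbone carbonyl oxygens per residue.

Contact classification combines the first contact radius of the
side-chain RDF against micelle core sites and against head-group sites
(first bin with g ≥ 1) with the side-chain hydration number: core
contact within 6 Å and closer than the head contact → buried_in_core
(overruled to interfacial if more than 6 waters are present); head
contact within 6 Å → interfacial; otherwise solvent_exposed.  These
thresholds are package defaults in `ContactConfig` — the study defines
no such selections — and the "core" and "head group" selections
(detergent terminal/tail carbons vs SDS sulfur + DPC phosphorus) are
likewise documented conventions.

## Synthetic generators

The peptide builder chains ideal internal coordinates (N–Cα 1.458,
Cα–C′ 1.525, C′–N 1.329 Å; standard angles) by natural-extension
placement, so requested φ/ψ/ω are realised essentially exactly (round
trip < 0.01°).  The Cβ branch uses the improper torsion
dihedral(C′, N, Cα, Cβ) = −120° for l, +120° for d (frozen from ideal
residue templates), and side-chain torsions flip sign with chirality, so
an all-d build with negated torsions is the exact mirror image of the l
build.  No sterics are checked — generation is geometry-only, by design:
the analysis layer, not a force field, is under test, and analytic
ground truth must be exact.

Toy boxes place head-group sites on a sphere (radius 22 Å by default),
core sites uniformly inside 0.75 × that radius, and ideal-gas water
outside the sphere, redrawn each frame; the default water density is
chosen so the expected count in the emulated 85 Å study box is ~13,500
molecules.  The peptide is placed at the micelle center (buried), on the
shell (surface) or at the box corner (bulk — maximally distant from the
micelle under minimum image).  All generators are deterministic under a
fixed seed.  Synthetic observables use a Karplus curve
J = 6.51 cos²(φ−60°) − 1.76 cos(φ−60°) + 1.60 for couplings and ⟨r⁻⁶⟩
for NOE volumes; these synthesis models are deliberately distinct from
the interval rules used for inversion, keeping the two directions of the
round trip independent.

What the toy boxes do *not* emulate: detergent chain conformations,
water structure (the solvent is an ideal gas), electrostatics, and
micelle shape fluctuations.  Passing the solvation suite therefore
validates the estimators (normalisation, counting, classification
logic), not any physical prediction about real micelles.

## Problem sizes and tolerances

Test and validation runs use ensembles of 20–250 frames, boxes of
24–44 Å with a few thousand water sites, and Monte-Carlo tolerances of
3σ around analytic expectations — sizes chosen so the whole suite
completes in seconds while keeping counting statistics meaningful.  The
full-scale 85 Å / 13,500-water geometry is exercised once for its
composition statistics.  Stochastic assertions use fixed seeds
throughout.

## Known limitations

* NOE bounds are ISPA-calibrated, not class-calibrated against a
  spectrometer fit; absolute upper bounds beyond ~4 Å are conservative.
* Turn-occupancy percentages depend on the (documented) tolerance
  defaults; published per-ensemble occupancies from restrained-MD
  trajectories are not reproducible without those trajectories and are
  treated as qualitative.
* Amide-H rebuilding assumes planar trans amides; side-chain donors and
  acceptors are not scanned by the backbone H-bond routine.
* Only cubic periodic boxes are supported; binary trajectory formats
  (DCD/XTC) are out of scope (the PDB/XYZ readers are the extension
  point).
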