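"""Synthetic inputs with exact ground truth.

Everything the pipeline consumes can be generated here: ideal-geometry
nonapeptides built from requested backbone torsions (with per-residue l/d
chirality and an optional 1-6 disulfide), jittered conformational
ensembles, toy micelle+water periodic boxes with known composition and
densities, and NMR observable tables back-computed from a structure.

Generation is geometry-only -- no force field, no sterics -- so that every
planted parameter (turn torsions, ring descriptors, hydrogen-bond
occupancy, hydration environment, densities) is analytically known and
the analysis modules can be tested for exact recovery.  All generators
are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import (
    Atom,
    Conformation,
    Ensemble,
    PeptideTopology,
    Residue,
)
from .conformation import rebuild_amide_hydrogens
from .nmr import CouplingRecord, NOEPeak, TempSeries

__all__ = [
    "BuildSpec",
    "BoxSpec",
    "NoiseModel",
    "SynthObservables",
    "CompositionReport",
    "build_peptide",
    "jittered_ensemble",
    "make_box",
    "study_box_spec",
    "composition_report",
    "synth_observables",
    "karplus_j",
    "AVP_SEQUENCE",
]

AVOGADRO = 6.02214076e23

#: Arginine-vasopressin sequence CYFQNCPRG with a C-terminal amide; the
#: all-l parent.  d-analogues are produced by flipping per-residue
#: chirality (e.g. d-Arg8 for the [d-Arg8] analogue).
AVP_SEQUENCE: tuple[tuple[str, str], ...] = (
    ("CYS", "L"), ("TYR", "L"), ("PHE", "L"), ("GLN", "L"), ("ASN", "L"),
    ("CYS", "L"), ("PRO", "L"), ("ARG", "L"), ("GLY", "achiral"),
)

# ideal backbone internal coordinates, angstrom / degrees
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.6, 121.9
_B_C_O, _A_CA_C_O = 1.231, 120.5
_B_C_NT, _A_CA_C_NT = 1.335, 116.6

#: Cbeta improper torsion dihedral(C', N, CA, CB); -120 deg for l-residues
#: (frozen from ideal residue geometry), sign-flipped for d.
_CB_IMPROPER = -120.0
_B_CA_CB, _A_N_CA_CB = 1.529, 109.47

# side-chain placement recipes: atom -> (refA, refB, refC, bond, angle, torsion,
# chiral) where torsion is multiplied by the residue chirality sign when
# ``chiral`` is true.  References may name backbone or earlier side-chain atoms.
_SIDE_CHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [],
    "CYS": [("SG", "N", "CA", "CB", 1.81, 114.0, -60.0, True)],
    "TYR": [
        ("CG", "N", "CA", "CB", 1.506, 114.0, -60.0, True),
        ("CD1", "CA", "CB", "CG", 1.39, 120.0, 90.0, True),
        ("CD2", "CA", "CB", "CG", 1.39, 120.0, -90.0, True),
        ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0, False),
        ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0, False),
        ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0, False),
        ("OH", "CD1", "CE1", "CZ", 1.36, 120.0, 180.0, False),
    ],
    "PHE": [
        ("CG", "N", "CA", "CB", 1.506, 114.0, -60.0, True),
        ("CD1", "CA", "CB", "CG", 1.39, 120.0, 90.0, True),
        ("CD2", "CA", "CB", "CG", 1.39, 120.0, -90.0, True),
        ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0, False),
        ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0, False),
        ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0, False),
    ],
    "GLN": [
        ("CG", "N", "CA", "CB", 1.52, 111.0, -60.0, True),
        ("CD", "CA", "CB", "CG", 1.52, 111.0, 180.0, False),
        ("OE1", "CB", "CG", "CD", 1.23, 120.0, 0.0, True),
        ("NE2", "CB", "CG", "CD", 1.33, 116.0, 180.0, True),
    ],
    "ASN": [
        ("CG", "N", "CA", "CB", 1.52, 111.0, -60.0, True),
        ("OD1", "CA", "CB", "CG", 1.23, 120.0, 0.0, True),
        ("ND2", "CA", "CB", "CG", 1.33, 116.0, 180.0, True),
    ],
    "PRO": [
        ("CG", "N", "CA", "CB", 1.50, 104.0, 30.0, True),
        ("CD", "CA", "CB", "CG", 1.51, 104.0, -35.0, True),
    ],
    "ARG": [
        ("CG", "N", "CA", "CB", 1.52, 111.0, -60.0, True),
        ("CD", "CA", "CB", "CG", 1.52, 111.0, 180.0, False),
        ("NE", "CB", "CG", "CD", 1.46, 112.0, 180.0, False),
        ("CZ", "CG", "CD", "NE", 1.33, 124.0, 180.0, False),
        ("NH1", "CD", "NE", "CZ", 1.33, 120.0, 0.0, False),
        ("NH2", "CD", "NE", "CZ", 1.33, 120.0, 180.0, False),
    ],
}

_ELEMENT = {"S": "S", "O": "O", "N": "N"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT.get(atom_name[0], "C") if atom_name[0] != "H" else "H"


def nerf_place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from references A, B, C: |CD| = bond, angle(B,C,D),
    torsion dihedral(A,B,C,D) -- natural-extension reference frame."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = math.radians(angle)
    chi = math.radians(torsion)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m = np.cross(n_hat, bc_hat)
    d_local = np.array(
        [-bond * math.cos(theta), bond * math.sin(theta) * math.cos(chi),
         -bond * math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m + d_local[2] * n_hat


@dataclass
class BuildSpec:
    """Recipe for one ideal-geometry peptide conformation.

    ``angles`` lists (phi, psi, omega) per residue in degrees; phi and
    omega of residue 1 are ignored, psi of the last residue orients the
    terminal carbonyl/amide.  Omega defaults to 180 (trans) when None.
    """

    sequence: Sequence[tuple[str, str]] = AVP_SEQUENCE
    angles: Sequence[tuple[float | None, float | None, float | None]] | None = None
    disulfide: tuple[int, int] | None = (1, 6)
    c_terminal_amide: bool = True
    build_sidechains: bool = True

    def __post_init__(self):
        if self.angles is None:
            self.angles = [(-120.0, 130.0, 180.0)] * len(self.sequence)
        if len(self.angles) != len(self.sequence):
            raise ValueError("angle list length must match sequence length")


def build_peptide(spec: BuildSpec) -> tuple[PeptideTopology, Conformation]:
    """Construct an ideal-geometry peptide realising the requested torsions.

    Backbone bond lengths/angles are fixed at ideal values so that
    :func:`~pepmicelle.conformation.backbone_angles` round-trips the
    requested phi/psi/omega essentially exactly.  d-residues get the
    mirror-image Cbeta branch and side-chain torsions.  No steric check is
    performed (geometry only); sterically impossible requests build fine.
    """
    seq = list(spec.sequence)
    n = len(seq)
    angles = [
        (phi if phi is not None else -120.0,
         psi if psi is not None else 130.0,
         om if om is not None else 180.0)
        for (phi, psi, om) in spec.angles
    ]
    # backbone trace
    bbN = [np.array([0.0, 0.0, 0.0])]
    bbCA = [np.array([_B_N_CA, 0.0, 0.0])]
    th = math.radians(_A_N_CA_C)
    bbC = [bbCA[0] + _B_CA_C * np.array([-math.cos(th), math.sin(th), 0.0])]
    for i in range(n - 1):
        psi_i = angles[i][1]
        omega_next = angles[i + 1][2]
        phi_next = angles[i + 1][0]
        Nn = nerf_place(bbN[i], bbCA[i], bbC[i], _B_C_N, _A_CA_C_N, psi_i)
        CAn = nerf_place(bbCA[i], bbC[i], Nn, _B_N_CA, _A_C_N_CA, omega_next)
        Cn = nerf_place(bbC[i], Nn, CAn, _B_CA_C, _A_N_CA_C, phi_next)
        bbN.append(Nn)
        bbCA.append(CAn)
        bbC.append(Cn)

    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    offset = 0
    prev_c_index: int | None = None
    for i, (resname, chirality) in enumerate(seq):
        sign = -1.0 if chirality == "D" else 1.0
        pos: dict[str, np.ndarray] = {"N": bbN[i], "CA": bbCA[i], "C": bbC[i]}
        psi_i = angles[i][1]
        pos["O"] = nerf_place(pos["N"], pos["CA"], pos["C"], _B_C_O, _A_CA_C_O, psi_i + 180.0)
        names = ["N", "CA", "C", "O"]
        if spec.build_sidechains and resname != "GLY":
            pos["CB"] = nerf_place(pos["C"], pos["N"], pos["CA"], _B_CA_CB, _A_N_CA_CB,
                                   sign * _CB_IMPROPER)
            names.append("CB")
            for (nm, ra, rb, rc, bond, ang, tor, chiral) in _SIDE_CHAINS.get(resname, []):
                t = sign * tor if chiral else tor
                pos[nm] = nerf_place(pos[ra], pos[rb], pos[rc], bond, ang, t)
                names.append(nm)
        if i == n - 1 and spec.c_terminal_amide:
            pos["NT"] = nerf_place(pos["N"], pos["CA"], pos["C"], _B_C_NT, _A_CA_C_NT, psi_i)
            pos["HT1"] = nerf_place(pos["CA"], pos["C"], pos["NT"], 1.01, 120.0, 0.0)
            pos["HT2"] = nerf_place(pos["CA"], pos["C"], pos["NT"], 1.01, 120.0, 180.0)
            names += ["NT", "HT1", "HT2"]
        atoms = [Atom(nm, _element_of(nm)) for nm in names]
        residues.append(Residue(resname, chirality, atoms))
        local = {nm: offset + k for k, nm in enumerate(names)}
        bonds += [(local["N"], local["CA"]), (local["CA"], local["C"]), (local["C"], local["O"])]
        if prev_c_index is not None:
            bonds.append((prev_c_index, local["N"]))
        prev_c_index = local["C"]
        coords += [pos[nm] for nm in names]
        offset += len(names)

    topo = PeptideTopology(
        residues=residues,
        bonds=bonds,
        disulfides=[spec.disulfide] if spec.disulfide else [],
        c_terminal_amide=spec.c_terminal_amide,
    )
    xyz = np.array(coords)
    # amide hydrogens at the ideal bisector positions, inserted after N
    hpos = rebuild_amide_hydrogens(topo, xyz)
    if hpos:
        new_res: list[Residue] = []
        new_xyz: list[np.ndarray] = []
        off = 0
        for r_i, res in enumerate(topo.residues, start=1):
            atoms = list(res.atoms)
            block = [xyz[off + k] for k in range(len(atoms))]
            if r_i in hpos:
                atoms.insert(1, Atom("H", "H"))
                block.insert(1, hpos[r_i])
            new_res.append(Residue(res.name, res.chirality, atoms))
            new_xyz += block
            off += len(res.atoms)
        topo = PeptideTopology(new_res, bonds=[], disulfides=topo.disulfides,
                               c_terminal_amide=topo.c_terminal_amide)
        xyz = np.array(new_xyz)
    return topo, Conformation(xyz)


def jittered_ensemble(
    topology: PeptideTopology,
    frame: Conformation,
    n_frames: int,
    sigma: float = 0.1,
    seed: int = 0,
) -> Ensemble:
    """Reference structure plus isotropic Gaussian coordinate jitter per frame."""
    rng = np.random.default_rng(seed)
    frames = [
        Conformation(frame.coordinates + rng.normal(0.0, sigma, frame.coordinates.shape),
                     box_edge=frame.box_edge)
        for _ in range(n_frames)
    ]
    return Ensemble(topology, frames)


# ---------------------------------------------------------------------------
# toy micelle + water boxes
# ---------------------------------------------------------------------------

@dataclass
class BoxSpec:
    """Cubic periodic box with an optional spherical pseudo-micelle.

    The micelle is a shell of detergent head-group sites (SDS sulfur and
    DPC phosphorus) at ``shell_radius`` around the box centre with
    hydrophobic core sites uniformly inside ``0.75 * shell_radius``;
    water oxygens are uniform outside the micelle sphere at
    ``water_density``.  ``peptide_placement`` puts the peptide centre of
    mass at the micelle centre (``buried``), on the shell (``surface``) or
    in bulk water (``bulk``).
    """

    edge: float = 85.0
    water_density: float = 0.0237          # A^-3, see study_box_spec()
    shell_radius: float = 22.0
    n_sds: int = 10
    n_dpc: int = 50
    n_core: int = 150
    peptide: tuple[PeptideTopology, Conformation] | None = None
    peptide_placement: Literal["surface", "buried", "bulk"] = "surface"
    peptide_jitter: float = 0.0
    n_frames: int = 1
    seed: int = 0
    exact_water_count: int | None = None   # override the Poisson draw

    def __post_init__(self):
        if self.water_density < 0:
            raise ValueError("water density must be >= 0")
        if self.micelle_enabled and not self.shell_radius < self.edge / 2:
            raise ValueError("micelle shell radius must be below half the box edge")

    @property
    def micelle_enabled(self) -> bool:
        return (self.n_sds + self.n_dpc + self.n_core) > 0 and self.shell_radius > 0

    @property
    def free_volume(self) -> float:
        v = self.edge**3
        if self.micelle_enabled:
            v -= 4.0 / 3.0 * math.pi * self.shell_radius**3
        return v


def study_box_spec(**overrides) -> BoxSpec:
    """Box emulating the study system: 85 A cubic box, 10 SDS + 50 DPC
    head sites on a 22 A shell, water density tuned so the expected water
    count outside the micelle is ~13,500 molecules."""
    spec = BoxSpec(**overrides)
    if "water_density" not in overrides:
        spec.water_density = 13500.0 / spec.free_volume
    return spec


def _uniform_in_sphere(rng, n, radius, center):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return center + v * r[:, None]


def _on_sphere(rng, n, radius, center):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return center + radius * v


def make_box(spec: BoxSpec) -> Ensemble:
    """Generate a peptide/pseudo-micelle/water ensemble in a cubic box.

    Water positions are redrawn independently every frame (an ideal-gas
    solvent); micelle sites are fixed; the peptide is optionally jittered.
    The water count is one Poisson draw at ``water_density * free_volume``
    (or ``exact_water_count``), held fixed across frames so all frames
    share one topology.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.full(3, spec.edge / 2.0)

    residues: list[Residue] = []
    static: list[np.ndarray] = []   # micelle sites, fixed across frames
    pep_coords = None
    pep_n = 0
    if spec.peptide is not None:
        topo_p, conf_p = spec.peptide
        xyz = conf_p.coordinates.copy()
        com = xyz.mean(axis=0)
        if spec.peptide_placement == "buried":
            target = center
        elif spec.peptide_placement == "surface":
            target = center + np.array([spec.shell_radius, 0.0, 0.0])
        else:  # bulk: the box corner is maximally distant from the micelle
            # under the minimum-image convention ((edge/2)*sqrt(3) away)
            target = center + np.full(3, spec.edge / 2.0) if spec.micelle_enabled \
                else center
        xyz += target - com
        residues += topo_p.residues
        pep_coords = xyz
        pep_n = xyz.shape[0]

    if spec.micelle_enabled:
        heads = _on_sphere(rng, spec.n_sds + spec.n_dpc, spec.shell_radius, center)
        for k in range(spec.n_sds):
            residues.append(Residue("SDS", "achiral", [Atom("S", "S")]))
            static.append(heads[k])
        for k in range(spec.n_sds, spec.n_sds + spec.n_dpc):
            residues.append(Residue("DPC", "achiral", [Atom("P", "P")]))
            static.append(heads[k])
        cores = _uniform_in_sphere(rng, spec.n_core, 0.75 * spec.shell_radius, center)
        for k in range(spec.n_core):
            residues.append(Residue("COR", "achiral", [Atom("C", "C")]))
            static.append(cores[k])

    if spec.exact_water_count is not None:
        n_water = spec.exact_water_count
    else:
        n_water = int(rng.poisson(spec.water_density * spec.free_volume))
    residues += [Residue("HOH", "achiral", [Atom("O", "O")]) for _ in range(n_water)]

    def draw_water():
        out = np.empty((0, 3))
        while out.shape[0] < n_water:
            pts = rng.random((max(n_water - out.shape[0], 16), 3)) * spec.edge
            if spec.micelle_enabled:
                d = pts - center
                d -= spec.edge * np.round(d / spec.edge)
                pts = pts[np.linalg.norm(d, axis=1) > spec.shell_radius]
            out = np.vstack([out, pts])
        return out[:n_water]

    topo = PeptideTopology(residues)
    frames = []
    static_arr = np.array(static).reshape(-1, 3)
    for _ in range(spec.n_frames):
        parts = []
        if pep_coords is not None:
            p = pep_coords
            if spec.peptide_jitter > 0:
                p = p + rng.normal(0.0, spec.peptide_jitter, p.shape)
            parts.append(p)
        if static_arr.size:
            parts.append(static_arr)
        if n_water:
            parts.append(draw_water())
        frames.append(Conformation(np.vstack(parts) if parts else np.empty((0, 3)),
                                   box_edge=spec.edge))
    if pep_n + static_arr.shape[0] + n_water == 0:
        raise ValueError("empty box: no peptide, micelle sites or water requested")
    return Ensemble(topo, frames)


# ---------------------------------------------------------------------------
# composition bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class CompositionReport:
    millimolar: dict[str, float]
    detergent_to_peptide: float | None
    sds_to_dpc: float | None


def composition_report(
    counts: dict[str, int],
    box_edge: float,
    concentrations_mM: dict[str, float] | None = None,
) -> CompositionReport:
    """Molarities and mole ratios from box composition.

    ``counts`` maps species (``peptide``, ``SDS``, ``DPC``, ``water``) to
    molecule counts; molarity = count / (N_A * edge^3).  The
    detergent:peptide ratio uses the given ``concentrations_mM`` when
    supplied (e.g. the experimental sample composition) and the counts
    otherwise; SDS:DPC likewise.
    """
    if not box_edge > 0:
        raise ValueError("box edge must be positive")
    vol_l = box_edge**3 * 1e-27
    mM = {k: 1e3 * v / (AVOGADRO * vol_l) for k, v in counts.items()}

    src = concentrations_mM if concentrations_mM is not None else {
        k: float(v) for k, v in counts.items()
    }
    det = sum(src.get(k, 0.0) for k in ("SDS", "DPC"))
    pep = src.get("peptide", 0.0)
    ratio_dp = det / pep if pep > 0 else None
    sds, dpc = src.get("SDS", 0.0), src.get("DPC", 0.0)
    ratio_sd = dpc / sds if sds > 0 else None
    return CompositionReport(millimolar=mM, detergent_to_peptide=ratio_dp, sds_to_dpc=ratio_sd)


# ---------------------------------------------------------------------------
# synthetic NMR observables
# ---------------------------------------------------------------------------

#: Karplus coefficients (A, B, C) for 3J(HN-Halpha), used for synthesis
#: only; restraint *inversion* uses the interval rule table in
#: :mod:`pepmicelle.nmr`, keeping the two directions independent.
KARPLUS = (6.51, -1.76, 1.60)


def karplus_j(phi_deg: float) -> float:
    """3J(HN-Halpha) in Hz from phi via J = A cos^2(phi-60) + B cos(phi-60) + C."""
    a, b, c = KARPLUS
    ct = math.cos(math.radians(phi_deg - 60.0))
    return a * ct * ct + b * ct + c


@dataclass
class NoiseModel:
    sigma_j: float = 0.0          # Hz
    sigma_volume_frac: float = 0.0
    sigma_shift: float = 0.0      # ppm, on temperature-series points


@dataclass
class SynthObservables:
    couplings: list[CouplingRecord]
    peaks: list[NOEPeak]
    temp_series: list[TempSeries]
    ground_truth: dict


def synth_observables(
    ens: Ensemble,
    noe_pairs: Sequence[tuple[int, str, int, str]] = (),
    temp_slopes: dict[int, float] | None = None,
    noise: NoiseModel = NoiseModel(),
    temperatures: Sequence[float] = (5.0, 10.0, 20.0, 32.0, 40.0, 50.0),
    seed: int = 0,
) -> SynthObservables:
    """Observable tables consistent with an ensemble, with known ground truth.

    Couplings come from the Karplus curve on the per-residue circular-mean
    phi; NOE volumes are proportional to the ensemble <r^-6> of each
    requested proton/atom pair (so the effective distance is
    <r^-6>^(-1/6)); temperature series are linear with the requested
    slopes (ppb/K).  Gaussian noise per :class:`NoiseModel`.
    """
    from .conformation import backbone_angles
    from scipy.stats import circmean

    rng = np.random.default_rng(seed)
    topo = ens.topology
    ang = backbone_angles(ens)

    couplings = []
    phis: dict[int, float] = {}
    for i in range(2, ang.n_residues + 1):
        col = ang.phi[:, i - 1]
        if np.all(np.isnan(col)):
            continue
        phi = float(circmean(col[~np.isnan(col)], high=180.0, low=-180.0))
        phis[i] = phi
        j = karplus_j(phi) + rng.normal(0.0, noise.sigma_j)
        chir = topo.residues[i - 1].chirality
        couplings.append(
            CouplingRecord(i, max(j, 0.0), "D" if chir == "D" else "L")
        )

    peaks = []
    distances: dict[tuple[str, str], float] = {}
    coords = ens.coordinates()
    for (ri, ai, rj, aj) in noe_pairs:
        ia, ib = topo.atom_index(ri, ai), topo.atom_index(rj, aj)
        r = np.linalg.norm(coords[:, ia] - coords[:, ib], axis=1)
        inv6 = float(np.mean(r**-6.0))
        v = inv6 * (1.0 + rng.normal(0.0, noise.sigma_volume_frac)) \
            if noise.sigma_volume_frac else inv6
        la, lb = f"{ri}:{ai}", f"{rj}:{aj}"
        peaks.append(NOEPeak(la, lb, max(v, 1e-12)))
        distances[(la, lb)] = inv6 ** (-1.0 / 6.0)

    series = []
    slopes = dict(temp_slopes or {})
    for res, slope in slopes.items():
        base = 8.0 + 0.05 * res
        pts = [
            (t, base + slope * t / 1000.0 + rng.normal(0.0, noise.sigma_shift))
            for t in temperatures
        ]
        series.append(TempSeries(res, pts))

    return SynthObservables(
        couplings=couplings,
        peaks=peaks,
        temp_series=series,
        ground_truth={"phi": phis, "distances": distances, "temp_slopes": slopes},
    )
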