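"""Domain types and geometric primitives shared by all analysis stages.

The central objects are :class:`PeptideTopology` (residues with l/d
chirality, atoms, bonds, an optional 1-6 disulfide), :class:`Conformation`
(one coordinate set, optionally in a cubic periodic box) and
:class:`Ensemble` (an ordered series of conformations sharing one
topology).  Residue indices are 1-based in every public interface,
matching the Cys1...Gly9 numbering conventional for neurohypophyseal
nonapeptides; coordinates are in angstroms and angles in degrees on the
canonical interval (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "PeptideTopology",
    "Conformation",
    "Ensemble",
    "AtomSelection",
    "GeometryError",
    "SelectionError",
    "dihedral_angle",
    "center_of_mass",
    "superpose",
    "kabsch",
    "apply_transform",
    "wrap_angle",
    "parse_selection",
]

#: Standard atomic masses (u) for the elements this package handles.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.973762,
    "NA": 22.98976928,
}

#: Atom names treated as backbone for selection purposes.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "H", "HA", "HA2", "HA3", "OXT", "NT", "HT1", "HT2"})


class GeometryError(ValueError):
    """Degenerate geometry (coincident or collinear points) where an angle is undefined."""


class SelectionError(ValueError):
    """An atom selection that is empty, out of range, or cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    mass: float | None = None

    def __post_init__(self):
        if self.mass is None:
            el = self.element.upper()
            if el not in ATOMIC_MASSES:
                raise ValueError(f"unknown element {self.element!r}; give an explicit mass")
            object.__setattr__(self, "mass", ATOMIC_MASSES[el])


Chirality = Literal["L", "D", "achiral"]


@dataclass
class Residue:
    name: str
    chirality: Chirality
    atoms: list[Atom]

    def __post_init__(self):
        if self.name == "GLY" and self.chirality != "achiral":
            raise ValueError("Gly is achiral")
        if self.chirality not in ("L", "D", "achiral"):
            raise ValueError(f"chirality must be L, D or achiral, got {self.chirality!r}")


@dataclass
class PeptideTopology:
    """Residue/atom/bond description of one molecular system.

    ``disulfides`` holds 1-based residue-index pairs; each member must be a
    Cys.  Non-peptide constituents of a simulation box (detergent head or
    core sites, water) are ordinary residues here (``SDS``, ``DPC``,
    ``COR``, ``HOH``) with ``achiral`` chirality.
    """

    residues: list[Residue]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    disulfides: list[tuple[int, int]] = field(default_factory=list)
    c_terminal_amide: bool = False

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("topology needs at least one residue")
        n = self.n_atoms
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a},{b}) references non-existent atoms (n={n})")
        for i, j in self.disulfides:
            for r in (i, j):
                if not (1 <= r <= len(self.residues)):
                    raise ValueError(f"disulfide residue index {r} out of range")
                if not self.residues[r - 1].name.startswith("CY"):
                    raise ValueError(f"disulfide partner residue {r} is not a cysteine")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def residue_offsets(self) -> np.ndarray:
        """Index of the first atom of each residue."""
        return np.concatenate([[0], np.cumsum([len(r.atoms) for r in self.residues])[:-1]])

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Global index of ``atom_name`` in 1-based residue ``residue_index``."""
        res = self.residues[residue_index - 1]
        off = int(self.residue_offsets[residue_index - 1])
        for k, a in enumerate(res.atoms):
            if a.name == atom_name:
                return off + k
        raise SelectionError(f"residue {residue_index} ({res.name}) has no atom {atom_name!r}")

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        return any(a.name == atom_name for a in self.residues[residue_index - 1].atoms)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for r in self.residues for a in r.atoms], float)

    def atom_names(self) -> list[str]:
        return [a.name for r in self.residues for a in r.atoms]

    def atom_residue_indices(self) -> np.ndarray:
        """1-based residue index of every atom."""
        return np.concatenate(
            [np.full(len(r.atoms), i + 1, int) for i, r in enumerate(self.residues)]
        )


@dataclass
class Conformation:
    """One frame: per-atom coordinates in angstroms, optional cubic box edge."""

    coordinates: np.ndarray
    box_edge: float | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if self.box_edge is not None and not self.box_edge > 0:
            raise ValueError("box_edge must be positive")


@dataclass
class Ensemble:
    topology: PeptideTopology
    frames: list[Conformation]
    frame_times: list[float] | None = None  # ps

    def __post_init__(self):
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {k} has {f.coordinates.shape[0]} atoms, topology has {n}"
                )
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, float)
            if len(t) != len(self.frames):
                raise ValueError("frame_times length mismatch")
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class AtomSelection:
    indices: tuple[int, ...]
    tag: str = ""

    def __post_init__(self):
        if len(set(self.indices)) != len(self.indices):
            raise SelectionError(f"duplicate indices in selection {self.tag!r}")

    def __len__(self):
        return len(self.indices)

    def array(self) -> np.ndarray:
        return np.asarray(self.indices, int)

    def validate(self, n_atoms: int) -> "AtomSelection":
        for i in self.indices:
            if not 0 <= i < n_atoms:
                raise SelectionError(f"index {i} out of range for {n_atoms} atoms")
        return self


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def wrap_angle(deg):
    """Wrap angle(s) to the canonical interval (-180, 180]."""
    a = np.asarray(deg, float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0  # maps to (-180, 180]
    return float(wrapped) if np.isscalar(deg) or wrapped.ndim == 0 else wrapped


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, degrees in (-180, 180].

    IUPAC sign convention: looking from p2 to p3, a clockwise rotation of
    the far bond relative to the near bond is positive.  Mirror reflection
    of all four points negates the result.  Raises :class:`GeometryError`
    on coincident consecutive points or three collinear points rather than
    returning NaN.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p2 - p1
    b1 = p3 - p2
    b2 = p4 - p3
    for b, lab in ((b0, "p1-p2"), (b1, "p2-p3"), (b2, "p3-p4")):
        if np.linalg.norm(b) < 1e-9:
            raise GeometryError(f"coincident points on segment {lab}")
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 * np.linalg.norm(b0) * np.linalg.norm(b1):
        raise GeometryError("p1, p2, p3 are collinear; torsion undefined")
    if np.linalg.norm(n2) < 1e-9 * np.linalg.norm(b1) * np.linalg.norm(b2):
        raise GeometryError("p2, p3, p4 are collinear; torsion undefined")
    b1u = b1 / np.linalg.norm(b1)
    m1 = np.cross(n1, b1u)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


def center_of_mass(
    topology: PeptideTopology,
    frame: Conformation,
    sel: AtomSelection,
    weighting: Literal["mass", "geometric"] = "mass",
) -> np.ndarray:
    """Mass-weighted or geometric center of the selected atoms (angstrom 3-vector)."""
    if len(sel) == 0:
        raise SelectionError("empty selection")
    idx = sel.array()
    xyz = frame.coordinates[idx]
    if weighting == "geometric":
        return xyz.mean(axis=0)
    w = topology.masses()[idx]
    return (xyz * w[:, None]).sum(axis=0) / w.sum()


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (proper rotation only).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise GeometryError("superposition needs >=3 paired atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(P, tol=1e-8 * max(1.0, np.abs(P).max())) < 2:
        raise GeometryError("selected atoms are collinear; rotation is underdetermined")
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    diff = (P @ R.T) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def superpose(
    mobile: Conformation,
    reference: Conformation,
    sel: AtomSelection,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose ``mobile`` on ``reference`` using the selected atoms.

    Returns the rotation matrix, translation vector and the minimised RMSD
    over the selection.  Apply with :func:`apply_transform`.
    """
    idx = sel.array()
    return kabsch(mobile.coordinates[idx], reference.coordinates[idx])


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ rotation.T + translation


# ---------------------------------------------------------------------------
# selection strings
# ---------------------------------------------------------------------------

def _residue_range(topology: PeptideTopology, spec: str | None) -> list[int]:
    if spec is None or spec == "":
        return list(range(1, len(topology.residues) + 1))
    out: list[int] = []
    for part in spec.split(","):
        if "-" in part:
            a, b = part.split("-")
            out.extend(range(int(a), int(b) + 1))
        else:
            out.append(int(part))
    for r in out:
        if not 1 <= r <= len(topology.residues):
            raise SelectionError(f"residue index {r} out of range")
    return out


def parse_selection(topology: PeptideTopology, text: str) -> AtomSelection:
    """Resolve a selection string against a topology.

    Grammar (residue ranges are 1-based, e.g. ``backbone:1-6``)::

        all | heavy[:RANGE] | backbone[:RANGE] | sidechain[:RANGE]
        ring:RES | name:ATOMNAME | resname:NAME | water | headgroups | core

    ``heavy`` means every non-hydrogen atom; ``sidechain`` excludes
    backbone and amide-cap atoms; ``ring`` is the three IUPAC C1/C3/C5
    ring carbons (PDB names CG, CE1, CE2) used for aromatic ring centers.
    """
    text = text.strip()
    kind, _, arg = text.partition(":")
    kind = kind.lower()
    offs = topology.residue_offsets
    idx: list[int] = []

    def residue_atoms(r: int):
        res = topology.residues[r - 1]
        off = int(offs[r - 1])
        return [(off + k, a) for k, a in enumerate(res.atoms)]

    if kind == "all":
        idx = list(range(topology.n_atoms))
    elif kind == "heavy":
        for r in _residue_range(topology, arg or None):
            idx += [i for i, a in residue_atoms(r) if a.element.upper() != "H"]
    elif kind == "backbone":
        for r in _residue_range(topology, arg or None):
            idx += [i for i, a in residue_atoms(r) if a.name in ("N", "CA", "C", "O")]
    elif kind == "sidechain":
        for r in _residue_range(topology, arg or None):
            idx += [
                i
                for i, a in residue_atoms(r)
                if a.name not in BACKBONE_ATOMS and a.element.upper() != "H"
            ]
    elif kind == "ring":
        if not arg:
            raise SelectionError("ring selection needs a residue index, e.g. ring:2")
        r = int(arg)
        idx = [topology.atom_index(r, nm) for nm in ("CG", "CE1", "CE2")]
    elif kind == "name":
        names = set(arg.split(","))
        idx = [i for i, nm in enumerate(topology.atom_names()) if nm in names]
    elif kind == "resname":
        names = set(arg.upper().split(","))
        for r in range(1, len(topology.residues) + 1):
            if topology.residues[r - 1].name.upper() in names:
                idx += [i for i, _ in residue_atoms(r)]
    elif kind == "water":
        for r in range(1, len(topology.residues) + 1):
            if topology.residues[r - 1].name in ("HOH", "WAT"):
                idx += [i for i, a in residue_atoms(r) if a.element.upper() == "O"]
    elif kind == "headgroups":
        for r in range(1, len(topology.residues) + 1):
            if topology.residues[r - 1].name in ("SDS", "DPC"):
                idx += [i for i, a in residue_atoms(r) if a.element.upper() in ("S", "P", "N")]
    elif kind == "core":
        for r in range(1, len(topology.residues) + 1):
            if topology.residues[r - 1].name == "COR":
                idx += [i for i, _ in residue_atoms(r)]
    else:
        raise SelectionError(f"cannot parse selection {text!r}")

    if not idx:
        raise SelectionError(f"selection {text!r} matched no atoms")
    return AtomSelection(tuple(idx), tag=text).validate(topology.n_atoms)
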