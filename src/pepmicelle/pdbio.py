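"""File formats: multi-model PDB ensembles, XYZ with a box comment,
tabular observable inputs, and restraint writers.

PDB cannot express l/d chirality, so ensembles with d-residues carry a
chirality sidecar: a two-column text file (1-based residue index, L|D)
read alongside the coordinates.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import (
    Atom,
    Conformation,
    Ensemble,
    PeptideTopology,
    Residue,
)
from .nmr import (
    CouplingRecord,
    DihedralRestraint,
    DistanceRestraint,
    NOEPeak,
    RestraintSet,
    ShiftTable,
    TempSeries,
)

__all__ = [
    "PDBFormatError",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_xyz",
    "write_xyz",
    "read_chirality",
    "write_chirality",
    "read_couplings",
    "read_peaks",
    "read_temp_series",
    "read_shift_table",
    "write_restraints_tsv",
    "write_restraints_amber",
    "frame_bookkeeping",
]

_ACHIRAL_RESNAMES = {"GLY", "HOH", "WAT", "SDS", "DPC", "COR"}


class PDBFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# chirality sidecar
# ---------------------------------------------------------------------------

def write_chirality(topology: PeptideTopology, path) -> None:
    """Two-column sidecar (1-based residue index, L|D) for chiral residues."""
    lines = [
        f"{i}\t{res.chirality}"
        for i, res in enumerate(topology.residues, start=1)
        if res.chirality in ("L", "D")
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_chirality(path) -> dict[int, str]:
    out: dict[int, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or parts[1] not in ("L", "D"):
            raise PDBFormatError(f"{path}:{ln}: expected '<residue_index> L|D', got {line!r}")
        out[int(parts[0])] = parts[1]
    return out


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

def _validate_models(path) -> None:
    n_model = n_end = 0
    last_model = 0
    for line in Path(path).read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            n_model += 1
        elif rec == "ENDMDL":
            n_end += 1
            last_model = n_end
    if n_model != n_end:
        raise PDBFormatError(
            f"{path}: truncated multi-model file -- {n_model} MODEL vs {n_end} ENDMDL "
            f"records; last complete model is {last_model}"
        )


def read_pdb_ensemble(path, chirality_path=None) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    MODEL/ENDMDL blocks become frames; a CRYST1 cubic cell becomes the box
    edge.  Chirality comes from the sidecar file (see
    :func:`read_chirality`); without one every chiral residue defaults to
    l.  Round-tripping through :func:`write_pdb_ensemble` preserves
    coordinates to PDB precision (1e-3 angstrom).
    """
    _validate_models(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as err:  # biotite raises on inconsistent models
        raise PDBFormatError(f"{path}: {err}") from err

    box_edge = None
    box = stack.box
    if box is not None:
        b = np.asarray(box)
        b0 = b[0] if b.ndim == 3 else b
        diag = np.diag(b0)
        if np.allclose(b0, np.diag(diag)) and np.allclose(diag, diag[0]) and diag[0] > 0:
            box_edge = float(diag[0])

    chir = read_chirality(chirality_path) if chirality_path else {}
    residues: list[Residue] = []
    # group atoms by (chain, res_id) in file order
    arr0 = stack[0]
    keys = list(zip(arr0.chain_id, arr0.res_id))
    seen: dict[tuple, int] = {}
    groups: list[list[int]] = []
    for k, key in enumerate(keys):
        if key not in seen:
            seen[key] = len(groups)
            groups.append([])
        groups[seen[key]].append(k)
    order = [i for grp in groups for i in grp]
    for r_i, grp in enumerate(groups, start=1):
        resname = str(arr0.res_name[grp[0]]).strip()
        atoms = []
        for k in grp:
            el = str(arr0.element[k]).strip().capitalize() or "C"
            atoms.append(Atom(str(arr0.atom_name[k]).strip(), el))
        if resname in _ACHIRAL_RESNAMES:
            chirality = "achiral"
        else:
            chirality = chir.get(r_i, "L")
        residues.append(Residue(resname, chirality, atoms))
    topo = PeptideTopology(residues)
    coords = np.asarray(stack.coord)[:, order, :]
    frames = [Conformation(coords[f], box_edge=box_edge) for f in range(coords.shape[0])]
    return Ensemble(topo, frames)


def write_pdb_ensemble(ens: Ensemble, path, chirality_path=None) -> None:
    """Write an ensemble as a multi-model PDB (CRYST1 records the cubic box).

    Writes a chirality sidecar when a path is given (required for
    round-tripping d-residues)."""
    topo = ens.topology
    n = topo.n_atoms
    arr = struc.AtomArray(n)
    res_idx = topo.atom_residue_indices()
    arr.chain_id = np.full(n, "A")
    arr.res_id = res_idx
    arr.res_name = np.array(
        [topo.residues[r - 1].name for r in res_idx], dtype="U5"
    )
    arr.atom_name = np.array(topo.atom_names(), dtype="U6")
    arr.element = np.array(
        [a.element.upper() for r in topo.residues for a in r.atoms], dtype="U2"
    )
    arr.hetero = np.array(
        [topo.residues[r - 1].name in ("HOH", "WAT", "SDS", "DPC", "COR") for r in res_idx]
    )
    stack = struc.from_template(arr, ens.coordinates())
    edge = ens.frames[0].box_edge
    if edge is not None:
        stack.box = np.repeat(np.diag([edge, edge, edge])[None], ens.n_frames, axis=0)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    if chirality_path:
        write_chirality(topo, chirality_path)


# ---------------------------------------------------------------------------
# XYZ with a comment-line box record
# ---------------------------------------------------------------------------

def write_xyz(ens: Ensemble, path) -> None:
    """Concatenated-frame XYZ; the comment line carries ``box_edge=<A>``."""
    names = ens.topology.atom_names()
    elements = [a.element for r in ens.topology.residues for a in r.atoms]
    with open(path, "w") as fh:
        for f, frame in enumerate(ens.frames):
            fh.write(f"{len(names)}\n")
            box = f" box_edge={frame.box_edge:.6f}" if frame.box_edge else ""
            fh.write(f"frame={f}{box}\n")
            for el, xyz in zip(elements, frame.coordinates):
                fh.write(f"{el:<2s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")


def read_xyz(path, topology: PeptideTopology | None = None) -> Ensemble:
    """Read concatenated-frame XYZ (box edge from the comment line).

    Without a topology, a flat one-residue topology is synthesised from
    the element column."""
    lines = Path(path).read_text().splitlines()
    frames = []
    elements0: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].split()[0])
        except ValueError as err:
            raise PDBFormatError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from err
        comment = lines[i + 1]
        box_edge = None
        for tok in comment.split():
            if tok.startswith("box_edge="):
                box_edge = float(tok.split("=", 1)[1])
        xyz = np.empty((nat, 3))
        els = []
        for k in range(nat):
            parts = lines[i + 2 + k].split()
            els.append(parts[0])
            xyz[k] = [float(p) for p in parts[1:4]]
        if not elements0:
            elements0 = els
        frames.append(Conformation(xyz, box_edge=box_edge))
        i += 2 + nat
    if topology is None:
        topology = PeptideTopology(
            [Residue("UNK", "achiral", [Atom(el.upper(), el) for el in elements0])]
        )
    return Ensemble(topology, frames)


# ---------------------------------------------------------------------------
# observable tables
# ---------------------------------------------------------------------------

def _read_table(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PDBFormatError(f"{path}: missing column(s) {missing}; have {list(df.columns)}")
    return df


def read_couplings(path) -> list[CouplingRecord]:
    """Columns: residue, j_hz, chirality (L|D)."""
    df = _read_table(path, ["residue", "j_hz", "chirality"])
    return [
        CouplingRecord(int(r.residue), float(r.j_hz), str(r.chirality).upper())
        for r in df.itertuples()
    ]


def read_peaks(path) -> list[NOEPeak]:
    """Columns: atom1, atom2, volume; optional methyl/aromatic flags (0/1)."""
    df = _read_table(path, ["atom1", "atom2", "volume"])
    return [
        NOEPeak(
            str(r.atom1), str(r.atom2), float(r.volume),
            methyl=bool(getattr(r, "methyl", 0)), aromatic=bool(getattr(r, "aromatic", 0)),
        )
        for r in df.itertuples()
    ]


def read_temp_series(path) -> list[TempSeries]:
    """Columns: residue, temperature_C, shift_ppm."""
    df = _read_table(path, ["residue", "temperature_C", "shift_ppm"])
    return [
        TempSeries(int(res), [(float(t), float(s)) for t, s in
                              zip(grp.temperature_C, grp.shift_ppm)])
        for res, grp in df.groupby("residue")
    ]


def read_shift_table(path) -> ShiftTable:
    """Columns: residue, atom, shift_ppm; optional resname."""
    df = _read_table(path, ["residue", "atom", "shift_ppm"])
    shifts = {(int(r.residue), str(r.atom)): float(r.shift_ppm) for r in df.itertuples()}
    names = {}
    if "resname" in df.columns:
        names = {int(r.residue): str(r.resname) for r in df.itertuples()}
    return ShiftTable(shifts, residue_names=names)


# ---------------------------------------------------------------------------
# restraint writers
# ---------------------------------------------------------------------------

def write_restraints_tsv(rset: RestraintSet, path) -> None:
    """Neutral tabular format of record: one row per restraint.

    Columns: kind, atoms (comma-joined indices or pair labels), lo, hi,
    force_constant, label.  Distances use lo/hi as the bounds in angstrom;
    dihedrals in degrees."""
    rows = []
    for d in rset.distances:
        rows.append(("distance", f"{d.atom_pair[0]},{d.atom_pair[1]}",
                     f"{d.lower:.3f}", f"{d.upper:.3f}", f"{d.force_constant:g}", d.label))
    for t in rset.dihedrals:
        atoms = ",".join(map(str, t.atom_indices)) if t.atom_indices else "-"
        rows.append(("dihedral", atoms, f"{t.lo:.2f}", f"{t.hi:.2f}",
                     f"{t.force_constant:g}", t.label))
    with open(path, "w") as fh:
        fh.write(f"# calibration: {rset.metadata.get('calibration', 'none')}\n")
        fh.write("kind\tatoms\tlo\thi\tforce_constant\tlabel\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_restraints_amber(rset: RestraintSet, path) -> None:
    """AMBER-flavoured &rst namelist blocks (flat-bottom wells r1<r2<r3<r4)."""
    with open(path, "w") as fh:
        for d in rset.distances:
            fh.write(
                "&rst iat=0,0,\n"
                f"  ! pair {d.atom_pair[0]} {d.atom_pair[1]} ({d.label})\n"
                f"  r1={d.lower - 0.5:.2f}, r2={d.lower:.2f}, r3={d.upper:.2f}, "
                f"r4={d.upper + 0.5:.2f},\n"
                f"  rk2={d.force_constant:.1f}, rk3={d.force_constant:.1f},\n"
                "&end\n"
            )
        for t in rset.dihedrals:
            iat = ",".join(map(str, t.atom_indices)) if t.atom_indices else "0,0,0,0"
            fh.write(
                f"&rst iat={iat},\n"
                f"  ! {t.label}\n"
                f"  r1={t.lo - 10:.1f}, r2={t.lo:.1f}, r3={t.hi:.1f}, r4={t.hi + 10:.1f},\n"
                f"  rk2={t.force_constant:.1f}, rk3={t.force_constant:.1f},\n"
                "&end\n"
            )


# ---------------------------------------------------------------------------
# trajectory bookkeeping
# ---------------------------------------------------------------------------

def frame_bookkeeping(total_ns: float, dt_fs: float, save_every: int,
                      analyze_last_ns: float) -> int:
    """Number of saved frames in the analysis window.

    ``floor(analyze_last_ns * 1e6 / (dt_fs * save_every))`` -- e.g. an
    8 ns run at a 2 fs step saving every 2000th step yields 250 frames in
    the final 1 ns."""
    if dt_fs <= 0 or save_every <= 0:
        raise ValueError("time step and save interval must be positive")
    if total_ns <= 0:
        raise ValueError("total simulation length must be positive")
    if analyze_last_ns < 0 or analyze_last_ns > total_ns:
        raise ValueError("analysis window must lie within the run")
    return math.floor(analyze_last_ns * 1e6 / (dt_fs * save_every))
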