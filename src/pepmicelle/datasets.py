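"""Published measured values for arginine-vasopressin (AVP), its
[d-Arg8] analogue (DAVP) and their all-residue chirality-inverted
(inverso) counterparts in mixed SDS/DPC micelles, typed in from the
study's tables so analyses can be reproduced without spectrometer data.

Residue numbering is 1-based over CYFQNC PRG-NH2 (tocin ring Cys1-Cys6).
"""

from .nmr import CouplingRecord, ShiftTable

__all__ = [
    "PEPTIDES",
    "ARG8_COUPLINGS",
    "GLN4_COUPLINGS",
    "PRO7_SHIFTS",
    "NOE_COUNTS",
    "NMR_SAMPLE_MM",
    "BOX_COMPOSITION",
    "MD_SCHEDULE",
    "AVP_CYS6_TEMP_COEFF",
]

#: Per-analogue residue-8 chirality (the only position differing between
#: AVP and DAVP; inverso analogues flip every chiral residue).
PEPTIDES = ("AVP", "iAVP", "DAVP", "iDAVP")

#: Measured 3J(HN-Halpha) of residue 8 (Hz) and its chirality.
ARG8_COUPLINGS = {
    "AVP": CouplingRecord(8, 8.9, "L"),
    "iAVP": CouplingRecord(8, 9.8, "D"),
    "DAVP": CouplingRecord(8, 10.2, "D"),
    "iDAVP": CouplingRecord(8, 11.8, "L"),
}

#: Measured 3J(HN-Halpha) of Gln4 (Hz).
GLN4_COUPLINGS = {
    "AVP": CouplingRecord(4, 9.1, "L"),
    "iAVP": CouplingRecord(4, 9.9, "D"),
    "DAVP": CouplingRecord(4, 6.8, "L"),
    "iDAVP": CouplingRecord(4, 6.5, "D"),
}

#: 13C shifts (ppm) of Pro7; Cgamma was not assigned for DAVP/iDAVP.
_PRO7 = {
    "AVP": {"CA": 61.46, "CB": 29.46, "CG": 25.17},
    "iAVP": {"CB": 29.50, "CG": 25.22},
    "DAVP": {"CB": 29.38},
    "iDAVP": {"CB": 29.20},
}


def PRO7_SHIFTS(peptide: str) -> ShiftTable:
    """Shift table holding the Pro7 13C assignments of one analogue."""
    vals = _PRO7[peptide]
    return ShiftTable({(7, atom): ppm for atom, ppm in vals.items()},
                      residue_names={7: "PRO"})


#: Assigned NOESY cross peaks per analogue.
NOE_COUNTS = {"AVP": 75, "iAVP": 73, "DAVP": 69, "iDAVP": 92}

#: NMR sample composition, mM.
NMR_SAMPLE_MM = {"peptide": 4.5, "SDS": 26.0, "DPC": 130.0}

#: Simulation-box composition: detergent monomer counts, cubic edge (A),
#: approximate water count.
BOX_COMPOSITION = {"n_sds": 10, "n_dpc": 50, "edge": 85.0, "n_water": 13500}

#: Restrained-MD schedule: total length (ns), time step (fs), coordinate
#: save interval (steps), analysis window (final ns).
MD_SCHEDULE = {"total_ns": 8.0, "dt_fs": 2.0, "save_every": 2000, "analyze_last_ns": 1.0}

#: Amide-proton temperature coefficient of Cys6 in AVP, ppb/K (strong
#: intramolecular hydrogen bond).
AVP_CYS6_TEMP_COEFF = -2.7
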