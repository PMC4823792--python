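"""Atom role classification for ion-interaction analysis.

Roles name the candidate Ca2+ coordination partners on a protein: the
carboxylate carbons of Asp/Glu and the C-terminus, backbone carbonyl
oxygens, the Gln side-chain carbonyl oxygen, Ser/Thr hydroxyl oxygens, and
side-chain amino/guanidinium nitrogens — plus the monatomic ion species.
Role assignment is a pure function of (residue_name, atom_name, c-terminal
flag), so it applies uniformly to structures from any source.
"""

from __future__ import annotations

from enum import Enum


class AtomRole(str, Enum):
    CARBOXYLATE_CARBON = "carboxylate_carbon"
    BACKBONE_OXYGEN = "backbone_oxygen"
    GLN_CARBONYL_OXYGEN = "gln_carbonyl_oxygen"
    HYDROXYL_OXYGEN = "hydroxyl_oxygen"
    AMINO_NITROGEN = "amino_nitrogen"
    CALCIUM = "calcium"
    SODIUM = "sodium"
    CHLORIDE = "chloride"
    OTHER = "other"


_ION_RESNAMES = {
    "CA": AtomRole.CALCIUM,
    "CAL": AtomRole.CALCIUM,
    "CA2": AtomRole.CALCIUM,
    "CA2+": AtomRole.CALCIUM,
    "NA": AtomRole.SODIUM,
    "SOD": AtomRole.SODIUM,
    "NA+": AtomRole.SODIUM,
    "CL": AtomRole.CHLORIDE,
    "CLA": AtomRole.CHLORIDE,
    "CL-": AtomRole.CHLORIDE,
}

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_SIDECHAIN_ROLES = {
    ("ASP", "CG"): AtomRole.CARBOXYLATE_CARBON,
    ("GLU", "CD"): AtomRole.CARBOXYLATE_CARBON,
    ("GLN", "OE1"): AtomRole.GLN_CARBONYL_OXYGEN,
    ("SER", "OG"): AtomRole.HYDROXYL_OXYGEN,
    ("THR", "OG1"): AtomRole.HYDROXYL_OXYGEN,
    ("GLN", "NE2"): AtomRole.AMINO_NITROGEN,
    ("ARG", "NE"): AtomRole.AMINO_NITROGEN,
    ("ARG", "NH1"): AtomRole.AMINO_NITROGEN,
    ("ARG", "NH2"): AtomRole.AMINO_NITROGEN,
    ("LYS", "NZ"): AtomRole.AMINO_NITROGEN,
}


def assign_role(residue_name: str, atom_name: str, c_terminal: bool = False) -> AtomRole:
    """Classify one atom. ``c_terminal`` marks the terminal residue whose
    backbone carboxyl carbon (atom C) counts as a carboxylate carbon."""
    res = residue_name.strip().upper()
    atom = atom_name.strip().upper()
    # "CA" names the calcium ion residue, never the alpha carbon: amino-acid
    # residues use their three-letter codes, so the residue name disambiguates
    if res in _ION_RESNAMES and res not in _AMINO_ACIDS:
        return _ION_RESNAMES[res]
    if (res, atom) in _SIDECHAIN_ROLES:
        return _SIDECHAIN_ROLES[(res, atom)]
    if res in _AMINO_ACIDS:
        if c_terminal and atom == "C":
            return AtomRole.CARBOXYLATE_CARBON
        if atom == "O":
            return AtomRole.BACKBONE_OXYGEN
    return AtomRole.OTHER


#: Contact thresholds (nm) per coordinating role, anchored by first-shell
#: RDF minima: 0.4 nm for carboxylates is the certain value; the others span
#: the 0.25–0.5 nm first-shell range typical for Ca2+ partners.
DEFAULT_THRESHOLDS_NM: dict[AtomRole, float] = {
    AtomRole.CARBOXYLATE_CARBON: 0.40,
    AtomRole.BACKBONE_OXYGEN: 0.32,
    AtomRole.GLN_CARBONYL_OXYGEN: 0.32,
    AtomRole.HYDROXYL_OXYGEN: 0.35,
    AtomRole.AMINO_NITROGEN: 0.50,
}
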