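"""Embedded constant tables: elements, amino-acid topology, energy scales.

All distances in Å, masses in Da, energies in kcal/mol.
"""

from __future__ import annotations

# Atomic masses (Da) and van der Waals radii (Å) for elements occurring in
# standard amino acids plus selenium (MSE is remapped to MET but SE atoms may
# still appear in raw coordinate files).
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "SE": 78.971,
    "P": 30.974,
}

VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = tuple(sorted(THREE_TO_ONE))

# Nonstandard residue remapping (others are excluded and reported).
NONSTANDARD_MAP: dict[str, str] = {"MSE": "MET"}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Last heavy atom (LHA) of the side chain, per residue type.  GLY has no side
# chain so its anchor falls back to CA; ALA's is CB.  Symmetric termini
# (ASP OD1/OD2, GLU OE1/OE2, ...) are broken toward the lower branch number.
LHA_ATOM: dict[str, str] = {
    "ALA": "CB", "ARG": "NH1", "ASN": "OD1", "ASP": "OD1", "CYS": "SG",
    "GLN": "OE1", "GLU": "OE1", "GLY": "CA", "HIS": "NE2", "ILE": "CD1",
    "LEU": "CD1", "LYS": "NZ", "MET": "CE", "PHE": "CZ", "PRO": "CG",
    "SER": "OG", "THR": "OG1", "TRP": "CH2", "TYR": "OH", "VAL": "CG1",
}

# Side-chain torsion (chi) atom tetrads, in order CHI1..CHI4.
_CHI1 = ("N", "CA", "CB", "CG")
CHI_ATOMS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "ALA": (),
    "GLY": (),
    "ARG": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "NE"),
            ("CG", "CD", "NE", "CZ")),
    "ASN": (_CHI1, ("CA", "CB", "CG", "OD1")),
    "ASP": (_CHI1, ("CA", "CB", "CG", "OD1")),
    "CYS": (("N", "CA", "CB", "SG"),),
    "GLN": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")),
    "GLU": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")),
    "HIS": (_CHI1, ("CA", "CB", "CG", "ND1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "LEU": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "LYS": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "CE"),
            ("CG", "CD", "CE", "NZ")),
    "MET": (_CHI1, ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")),
    "PHE": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "PRO": (_CHI1, ("CA", "CB", "CG", "CD")),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "TRP": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "TYR": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "VAL": (("N", "CA", "CB", "CG1"),),
}

# Radzicka & Wolfenden (1988) hydrophobicity scale (cyclohexane -> water
# transfer free energies, kcal/mol, positive = hydrophobic).  Proline was not
# measured in the original scale; it is assigned 0.0 by convention here.
RADZICKA_SCALE: dict[str, float] = {
    "ALA": 1.81, "ARG": -14.92, "ASN": -6.64, "ASP": -8.72, "CYS": 1.28,
    "GLN": -5.54, "GLU": -6.81, "GLY": 0.94, "HIS": -4.66, "ILE": 4.92,
    "LEU": 4.92, "LYS": -5.55, "MET": 2.35, "PHE": 2.98, "PRO": 0.0,
    "SER": -3.40, "THR": -2.57, "TRP": 2.33, "TYR": -0.14, "VAL": 4.04,
}

# Theoretical maximum solvent accessibility per residue type (Å², extended
# Gly-X-Gly tripeptide reference, Tien et al. 2013).  Used to normalize
# per-residue accessibility into relative accessibility.
MAX_ACC: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# Contact energy scale (kcal/mol).  All hydrogen-bond flavours (direct and
# water-mediated) carry the hydrogen-bond energy; charged pairs carry the
# salt-bridge magnitude whether attractive or repulsive.
E_HYDROPHOBIC = 0.6
E_AROMATIC = 1.5
E_HBOND = 2.6
E_CHARGED = 10.0
E_DISULFIDE = 85.0

CONTACT_TYPES: tuple[str, ...] = (
    "HYDROPHOBIC", "AROMATIC",
    "HB_MM", "HB_MS", "HB_SS",
    "HB_MWM", "HB_MWS", "HB_SWS",
    "HB_MWWM", "HB_MWWS", "HB_SWWS",
    "CHARGED_ATTRACTIVE", "CHARGED_REPULSIVE", "DISULFIDE",
)

CONTACT_ENERGY: dict[str, float] = {
    "HYDROPHOBIC": E_HYDROPHOBIC,
    "AROMATIC": E_AROMATIC,
    "HB_MM": E_HBOND, "HB_MS": E_HBOND, "HB_SS": E_HBOND,
    "HB_MWM": E_HBOND, "HB_MWS": E_HBOND, "HB_SWS": E_HBOND,
    "HB_MWWM": E_HBOND, "HB_MWWS": E_HBOND, "HB_SWWS": E_HBOND,
    "CHARGED_ATTRACTIVE": E_CHARGED,
    "CHARGED_REPULSIVE": E_CHARGED,
    "DISULFIDE": E_DISULFIDE,
}

# Formally charged side-chain groups: residue -> (sign, atom names whose
# centroid locates the charge).
CHARGED_GROUPS: dict[str, tuple[int, tuple[str, ...]]] = {
    "ASP": (-1, ("OD1", "OD2")),
    "GLU": (-1, ("OE1", "OE2")),
    "LYS": (+1, ("NZ",)),
    "ARG": (+1, ("NE", "NH1", "NH2")),
    "HIS": (+1, ("ND1", "NE2")),
}

# Atom names participating in charged groups, for suppressing double counting
# of charged pairs as hydrogen bonds.
CHARGED_GROUP_ATOMS: dict[str, frozenset[str]] = {
    res: frozenset(atoms) for res, (_, atoms) in CHARGED_GROUPS.items()
}

# Aromatic ring atoms (six-membered ring used for the centroid in TRP).
AROMATIC_RING: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

# Apolar (hydrophobic-contact capable) carbon atoms per residue type:
# side-chain carbons not covalently bonded to N or O in the standard topology.
APOLAR_CARBONS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG"),
    "ASN": ("CB",),
    "ASP": ("CB",),
    "CYS": ("CB",),
    "GLN": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "GLY": (),
    "HIS": ("CB",),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD"),
    "MET": ("CB", "CG", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG"),
    "SER": (),
    "THR": ("CG2",),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "VAL": ("CB", "CG1", "CG2"),
}


def element_of(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name (heavy atoms only)."""
    name = atom_name.strip()
    if name.startswith(("SE",)) and len(name) <= 3:
        return "SE"
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")
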