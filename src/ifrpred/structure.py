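"""Typed atomic model for protein complexes and geometric primitives.

Reads the fixed-column PDB dialect (ATOM/HETATM/TER), resolves alternate
locations to the highest-occupancy conformer, routes waters (HOH) to a
separate pool, and exposes backbone/side-chain torsion computations.

Internal residue indexing is 0-based; original PDB residue numbers and
insertion codes are preserved for output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ATOMIC_MASS,
    BACKBONE_ATOMS,
    CHI_ATOMS,
    LHA_ATOM,
    NONSTANDARD_MAP,
    STANDARD_AA,
    THREE_TO_ONE,
    VDW_RADIUS,
    element_of,
)


class PDBParseError(ValueError):
    """Raised for malformed coordinate records (carries the line number)."""


class EmptyStructureError(ValueError):
    """Raised when a coordinate file contains no protein atoms."""


@dataclass
class AtomRecord:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    mass: float           # Da
    vdw_radius: float     # Å
    is_water: bool = False
    chain_id: str = ""
    residue_seq: int = 0
    insertion_code: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if self.mass <= 0 or self.vdw_radius <= 0:
            raise ValueError(f"non-physical mass/radius for atom {self.name}")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    amino_acid_type: str       # three-letter code, one of the 20 standard
    seq_index: int             # 0-based position within its chain
    atoms: list[AtomRecord] = field(default_factory=list)
    chain_id: str = ""
    residue_seq: int = 0       # original PDB residue number
    insertion_code: str = ""

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def c_alpha(self) -> AtomRecord | None:
        return self.atom("CA")

    @property
    def c_beta(self) -> AtomRecord | None:
        return self.atom("CB")

    @property
    def lha(self) -> AtomRecord | None:
        """Last heavy atom of the side chain (CA for GLY, CB for ALA)."""
        return self.atom(LHA_ATOM[self.amino_acid_type])

    @property
    def locator(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclass
class ChainStructure:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE[r.amino_acid_type] for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ComplexStructure:
    pdb_id: str = ""
    resolution: float | None = None
    chains: list[ChainStructure] = field(default_factory=list)
    waters: list[AtomRecord] = field(default_factory=list)
    oligomeric_state_consistent: bool = True
    is_fragment: bool = False
    has_nonprotein_polymer: bool = False
    excluded_residues: list[tuple[str, int, str]] = field(default_factory=list)

    def chain(self, chain_id: str) -> ChainStructure:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.pdb_id or 'complex'}")

    def iter_residues(self):
        for c in self.chains:
            yield from c.residues

    def protein_atoms(self) -> list[AtomRecord]:
        return [a for r in self.iter_residues() for a in r.atoms]

    def subcomplex(self, chain_id: str, with_waters: bool = True) -> "ComplexStructure":
        """A single-chain view (chain in isolation), sharing atom objects."""
        return ComplexStructure(
            pdb_id=self.pdb_id,
            resolution=self.resolution,
            chains=[self.chain(chain_id)],
            waters=list(self.waters) if with_waters else [],
            oligomeric_state_consistent=self.oligomeric_state_consistent,
            is_fragment=self.is_fragment,
        )


# Residue names treated as water.
_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})
# Nucleic-acid residue names: their presence flags a non-protein polymer.
_NUCLEIC_NAMES = frozenset(
    {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U", "T"}
)


def _parse_float(line_no: int, text: str, what: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise PDBParseError(
            f"line {line_no}: malformed {what} field {text.strip()!r}"
        ) from exc


def parse_pdb(text: str, pdb_id: str = "") -> ComplexStructure:
    """Parse PDB-format text into a :class:`ComplexStructure`.

    Chains are split by chain identifier, HOH/WAT residues are routed to the
    water pool, nucleic-acid chains set ``has_nonprotein_polymer``, alternate
    locations are resolved to the highest occupancy (ties keep the first
    conformer encountered), and unmappable nonstandard residues are excluded
    and reported in ``excluded_residues``.
    """
    resolution: float | None = None
    waters: list[AtomRecord] = []
    has_nonprotein = False
    excluded: list[tuple[str, int, str]] = []
    # (chain, resseq, icode, resname) -> {atom name -> AtomRecord}
    residues: dict[tuple, dict[str, AtomRecord]] = {}
    order: list[tuple] = []

    for line_no, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if line.startswith("REMARK   2") and "RESOLUTION" in line:
            tail = line.split("RESOLUTION", 1)[1].lstrip(". ")
            for tok in tail.split():
                try:
                    resolution = float(tok)
                    break
                except ValueError:
                    continue
        if not (rec.startswith("ATOM") or rec.startswith("HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {line_no}: truncated coordinate record")
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or "_"
        try:
            resseq = int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(
                f"line {line_no}: malformed residue number {line[22:26]!r}"
            ) from exc
        icode = line[26].strip()
        x = _parse_float(line_no, line[30:38], "x coordinate")
        y = _parse_float(line_no, line[38:46], "y coordinate")
        z = _parse_float(line_no, line[46:54], "z coordinate")
        occ_text = line[54:60].strip()
        occupancy = _parse_float(line_no, occ_text, "occupancy") if occ_text else 1.0
        elem = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not elem:
            elem = element_of(name)
        if elem == "H" or elem == "D":
            continue  # hydrogens never contribute to the descriptors

        if resname in _WATER_NAMES:
            waters.append(AtomRecord(
                name=name, element=elem, position=(x, y, z),
                mass=ATOMIC_MASS.get(elem, 15.999),
                vdw_radius=VDW_RADIUS.get(elem, 1.52),
                is_water=True, chain_id=chain_id, residue_seq=resseq,
                insertion_code=icode, occupancy=occupancy))
            continue
        if resname in _NUCLEIC_NAMES:
            has_nonprotein = True
            continue

        mapped = NONSTANDARD_MAP.get(resname, resname)
        if mapped not in STANDARD_AA:
            key = (chain_id, resseq, icode)
            if key not in excluded:
                excluded.append(key)
            continue
        if mapped != resname and name == "SE":
            name = "SD"  # MSE selenium takes the MET sulfur position
            elem = "S"

        key = (chain_id, resseq, icode, mapped)
        if key not in residues:
            residues[key] = {}
            order.append(key)
        atom = AtomRecord(
            name=name, element=elem, position=(x, y, z),
            mass=ATOMIC_MASS.get(elem, 12.011),
            vdw_radius=VDW_RADIUS.get(elem, 1.70),
            is_water=False, chain_id=chain_id, residue_seq=resseq,
            insertion_code=icode, occupancy=occupancy)
        prev = residues[key].get(name)
        if prev is None or (altloc and atom.occupancy > prev.occupancy):
            residues[key][name] = atom

    if not residues:
        raise EmptyStructureError("no protein atoms found")

    chains: dict[str, ChainStructure] = {}
    for key in order:
        chain_id, resseq, icode, resname = key
        chain = chains.setdefault(chain_id, ChainStructure(chain_id=chain_id))
        chain.residues.append(Residue(
            amino_acid_type=resname,
            seq_index=len(chain.residues),
            atoms=list(residues[key].values()),
            chain_id=chain_id,
            residue_seq=resseq,
            insertion_code=icode,
        ))

    return ComplexStructure(
        pdb_id=pdb_id,
        resolution=resolution,
        chains=list(chains.values()),
        waters=waters,
        has_nonprotein_polymer=has_nonprotein,
        excluded_residues=excluded,
    )


def write_pdb(complex_: ComplexStructure) -> str:
    """Serialize a complex back to fixed-column PDB text."""
    lines: list[str] = []
    if complex_.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {complex_.resolution:8.2f} ANGSTROMS."
        )
    serial = 1
    for chain in complex_.chains:
        for res in chain.residues:
            for atom in res.atoms:
                x, y, z = atom.position
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.amino_acid_type:>3s} "
                    f"{chain.chain_id:1s}{res.residue_seq:4d}"
                    f"{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.chain_id}")
        serial += 1
    for atom in complex_.waters:
        x, y, z = atom.position
        lines.append(
            f"HETATM{serial:5d} {atom.name:<4s} HOH "
            f"{atom.chain_id or 'W':1s}{atom.residue_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is requested for (near-)collinear points."""


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle about the p2-p3 axis, in degrees in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or norm_b2 < 1e-9:
        raise DegenerateGeometryError("collinear or coincident points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _safe_dihedral(*atoms: AtomRecord | None) -> float | None:
    if any(a is None for a in atoms):
        return None
    try:
        return dihedral(*(a.position for a in atoms))
    except DegenerateGeometryError:
        return None


def phi_psi(chain: ChainStructure, i: int) -> tuple[float | None, float | None]:
    """Backbone (phi, psi) of residue *i*; either is None at chain termini or
    where a backbone atom is missing."""
    res = chain.residues[i]
    prev_res = chain.residues[i - 1] if i > 0 else None
    next_res = chain.residues[i + 1] if i + 1 < len(chain.residues) else None
    phi = None
    psi = None
    if prev_res is not None:
        phi = _safe_dihedral(prev_res.atom("C"), res.atom("N"),
                             res.atom("CA"), res.atom("C"))
    if next_res is not None:
        psi = _safe_dihedral(res.atom("N"), res.atom("CA"),
                             res.atom("C"), next_res.atom("N"))
    return phi, psi


def chi_angles(residue: Residue) -> list[float | None]:
    """Side-chain torsions CHI1..CHI4 where defined for the residue type.

    Returns one entry per chi defined for the type; a missing side-chain atom
    marks that chi and all deeper ones as None.
    """
    tetrads = CHI_ATOMS[residue.amino_acid_type]
    out: list[float | None] = []
    broken = False
    for tetrad in tetrads:
        if broken:
            out.append(None)
            continue
        val = _safe_dihedral(*(residue.atom(n) for n in tetrad))
        if val is None:
            broken = True
        out.append(val)
    return out
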