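"""Solvent accessibility, interface labeling, and dataset filtering.

Accessibility uses rolling-probe point sampling (Shrake-Rupley style): each
atom's solvent-extended sphere is covered with quasi-uniform points and the
fraction not occluded by any neighboring atom's extended sphere gives the
exposed area.  A residue is an interface-forming residue (IFR) when its
accessibility drops upon complexation; exposed non-interface residues are
free surface residues (FSR); the rest are buried.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import MAX_ACC
from .structure import AtomRecord, ChainStructure, ComplexStructure

DEFAULT_PROBE_RADIUS = 1.4   # Å, water probe
DEFAULT_N_POINTS = 960       # sampling points per atom
DELTA_AREA = 0.1             # Å², minimum accessibility loss that marks an IFR
EXPOSURE_MIN = 0.05          # relative accessibility defining "surface"


class ResidueClass(str, enum.Enum):
    IFR = "IFR"
    FSR = "FSR"
    BURIED = "BURIED"


class SizeClass(str, enum.Enum):
    SMALL = "SMALL"
    MEDIUM = "MEDIUM"
    LARGE = "LARGE"


@dataclass
class SurfaceLabel:
    chain_id: str
    residue_seq: int
    insertion_code: str
    amino_acid_type: str
    acc_isolation: float   # Å²
    acc_complex: float     # Å²
    relative_acc: float    # fraction of the type-specific maximum
    cls: ResidueClass


@dataclass
class InterfaceSummary:
    chain_id: str
    interface_area: float  # Å²
    size_class: SizeClass
    n_ifr: int


@dataclass
class FilterCriteria:
    max_resolution: float = 3.0      # Å
    min_chain_length: int = 50       # residues
    min_interface_area: float = 200.0  # Å²
    identity_cutoff: float = 0.30    # pairwise sequence identity

    def __post_init__(self) -> None:
        for name in ("max_resolution", "min_chain_length",
                     "min_interface_area", "identity_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(atoms: list[AtomRecord],
         probe_radius: float = DEFAULT_PROBE_RADIUS,
         n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å²).

    ``n_points`` below 12 is refused: the sampling would be too coarse to
    say anything about occlusion.
    """
    if not atoms:
        raise ValueError("need at least one atom")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 12:
        raise ValueError("n_points < 12: sampling resolution too low")

    centers = np.array([a.position for a in atoms])
    radii = np.array([a.vdw_radius + probe_radius for a in atoms])
    unit = _sphere_points(n_points)
    tree = cKDTree(centers)
    max_r = radii.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = centers[i] + radii[i] * unit
        neighbors = tree.query_ball_point(centers[i], radii[i] + max_r)
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - centers[j], pts - centers[j])
            exposed &= d2 > radii[j] ** 2
        areas[i] = exposed.mean() * 4.0 * math.pi * radii[i] ** 2
    return areas


def _residue_areas(complex_: ComplexStructure, probe_radius: float,
                   n_points: int) -> dict[tuple, float]:
    """Per-residue SASA over the protein atoms of the given structure."""
    atoms: list[AtomRecord] = []
    owners: list[tuple] = []
    for res in complex_.iter_residues():
        for a in res.atoms:
            atoms.append(a)
            owners.append(res.locator)
    per_atom = sasa(atoms, probe_radius, n_points)
    out: dict[tuple, float] = {}
    for loc, area in zip(owners, per_atom):
        out[loc] = out.get(loc, 0.0) + float(area)
    return out


def label_residues(complex_: ComplexStructure,
                   probe_radius: float = DEFAULT_PROBE_RADIUS,
                   n_points: int = DEFAULT_N_POINTS,
                   delta_area: float = DELTA_AREA,
                   exposure_min: float = EXPOSURE_MIN) -> list[SurfaceLabel]:
    """Label every residue IFR / FSR / BURIED.

    Accessibility in isolation is computed per chain alone; accessibility in
    complex over all chains together.  A residue losing more than
    ``delta_area`` Å² upon complexation is an IFR; otherwise it is an FSR if
    its relative accessibility reaches ``exposure_min``, else buried.  For a
    single-chain structure no residue can be an IFR.
    """
    acc_complex = _residue_areas(complex_, probe_radius, n_points)
    labels: list[SurfaceLabel] = []
    multi = len(complex_.chains) >= 2
    for chain in complex_.chains:
        iso = _residue_areas(
            ComplexStructure(chains=[chain]), probe_radius, n_points)
        for res in chain.residues:
            a_iso = iso[res.locator]
            a_cpx = acc_complex[res.locator]
            rel = a_iso / MAX_ACC[res.amino_acid_type]
            if multi and (a_iso - a_cpx) > delta_area:
                cls = ResidueClass.IFR
            elif rel >= exposure_min:
                cls = ResidueClass.FSR
            else:
                cls = ResidueClass.BURIED
            labels.append(SurfaceLabel(
                chain_id=chain.chain_id,
                residue_seq=res.residue_seq,
                insertion_code=res.insertion_code,
                amino_acid_type=res.amino_acid_type,
                acc_isolation=a_iso,
                acc_complex=a_cpx,
                relative_acc=rel,
                cls=cls,
            ))
    return labels


def interface_area(labels: list[SurfaceLabel], chain_id: str) -> float:
    """Chain interface area (Å²): accessibility lost upon complexation,
    summed over the chain's residues (per-residue loss clipped at 0)."""
    found = False
    total = 0.0
    for lab in labels:
        if lab.chain_id == chain_id:
            found = True
            total += max(0.0, lab.acc_isolation - lab.acc_complex)
    if not found:
        raise KeyError(f"no labels for chain {chain_id!r}")
    return total


def size_class(area: float) -> SizeClass:
    """Interface size class: ≤800 Å² small, ≤3000 Å² medium, else large."""
    if area < 0:
        raise ValueError("interface area cannot be negative")
    if area <= 800.0:
        return SizeClass.SMALL
    if area <= 3000.0:
        return SizeClass.MEDIUM
    return SizeClass.LARGE


def summarize_interfaces(labels: list[SurfaceLabel]) -> list[InterfaceSummary]:
    out = []
    for cid in sorted({lab.chain_id for lab in labels}):
        area = interface_area(labels, cid)
        n_ifr = sum(1 for lab in labels
                    if lab.chain_id == cid and lab.cls is ResidueClass.IFR)
        out.append(InterfaceSummary(cid, area, size_class(area), n_ifr))
    return out


@dataclass
class FilterLogEntry:
    pdb_id: str
    kept: bool
    rejected_by: str | None = None


def filter_dataset(entries: list[ComplexStructure],
                   criteria: FilterCriteria | None = None,
                   probe_radius: float = DEFAULT_PROBE_RADIUS,
                   n_points: int = DEFAULT_N_POINTS,
                   ) -> tuple[list[ComplexStructure], list[FilterLogEntry]]:
    """Sequentially apply the corpus filter chain.

    Order: resolution ≤ max; no non-protein polymer; oligomeric state
    consistent; ≥2 chains; every chain ≥ min length; interface area ≥ min;
    not a fragment.  The log records which filter rejected each entry.
    """
    criteria = criteria or FilterCriteria()
    kept: list[ComplexStructure] = []
    log: list[FilterLogEntry] = []

    def reject(entry: ComplexStructure, why: str) -> None:
        log.append(FilterLogEntry(entry.pdb_id, False, why))

    for entry in entries:
        if entry.resolution is not None and entry.resolution > criteria.max_resolution:
            reject(entry, "resolution")
            continue
        if entry.has_nonprotein_polymer:
            reject(entry, "nonprotein_polymer")
            continue
        if not entry.oligomeric_state_consistent:
            reject(entry, "oligomeric_state")
            continue
        if len(entry.chains) < 2:
            reject(entry, "n_chains")
            continue
        if any(len(c) < criteria.min_chain_length for c in entry.chains):
            reject(entry, "chain_length")
            continue
        labels = label_residues(entry, probe_radius, n_points)
        max_area = max(interface_area(labels, c.chain_id)
                       for c in entry.chains)
        if max_area < criteria.min_interface_area:
            reject(entry, "interface_area")
            continue
        if entry.is_fragment:
            reject(entry, "fragment")
            continue
        kept.append(entry)
        log.append(FilterLogEntry(entry.pdb_id, True))
    return kept, log


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity = matches / alignment length.

    Needleman-Wunsch with match +1, mismatch 0, gap open -10, extend -0.5.
    """
    from Bio import Align

    if not seq_a or not seq_b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


def redundancy_reduce(chains: list[ChainStructure],
                      identity_cutoff: float = 0.30
                      ) -> list[ChainStructure]:
    """Greedy redundancy reduction at the given identity cutoff.

    Chains sorted by length descending; each joins the first cluster whose
    representative it matches above the cutoff, else founds a new one.  The
    returned representatives are mutually below the cutoff.
    """
    import warnings

    usable = []
    for c in chains:
        if len(c) == 0:
            warnings.warn(f"chain {c.chain_id!r} has empty sequence; skipped")
            continue
        usable.append(c)
    reps: list[ChainStructure] = []
    for c in sorted(usable, key=lambda ch: (-len(ch), ch.chain_id)):
        if not any(pairwise_identity(c.sequence, r.sequence) > identity_cutoff
                   for r in reps):
            reps.append(c)
    return reps


def labels_to_tsv(labels: list[SurfaceLabel], pdb_id: str = "") -> str:
    """Per-residue label table (TSV)."""
    lines = ["pdb_id\tchain\tresidue\ticode\taa\tacc_isolation\tacc_complex"
             "\trelative_acc\tclass"]
    for lab in labels:
        lines.append(
            f"{pdb_id}\t{lab.chain_id}\t{lab.residue_seq}\t"
            f"{lab.insertion_code}\t{lab.amino_acid_type}\t"
            f"{lab.acc_isolation:.3f}\t{lab.acc_complex:.3f}\t"
            f"{lab.relative_acc:.4f}\t{lab.cls.value}")
    return "\n".join(lines) + "\n"
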