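"""Typed inter-residue contact detection and contact energies.

The energy scale is fixed (hydrophobic 0.6, aromatic 1.5, hydrogen bond 2.6,
charged pair 10.0, disulfide 85.0 kcal/mol); the geometric criteria are
package conventions exposed through :class:`ContactCriteria`.

Rules worth knowing:

* at most one contact record per (residue pair, contact type); its distance
  is the closest qualifying atom pair;
* residue pairs adjacent in sequence (|Δindex| ≤ 1, same chain) are skipped
  entirely so peptide-bond geometry does not masquerade as a hydrogen bond;
* an N/O atom pair in which both atoms belong to formally charged groups is
  a charged contact, never additionally a hydrogen bond;
* water-mediated hydrogen bonds require one (W) or two mutually hydrogen-
  bonded (WW) bridging waters within hydrogen-bond distance of both partners.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    APOLAR_CARBONS,
    AROMATIC_RING,
    CHARGED_GROUP_ATOMS,
    CHARGED_GROUPS,
    CONTACT_ENERGY,
    CONTACT_TYPES,
)
from .structure import ComplexStructure, Residue


@dataclass(frozen=True)
class ContactCriteria:
    hydrophobic_cutoff: float = 3.9   # apolar C - apolar C
    aromatic_cutoff: float = 5.0      # ring centroid - ring centroid
    hbond_cutoff: float = 3.2         # N/O - N/O
    charged_cutoff: float = 6.0       # charged-group N/O pair
    disulfide_cutoff: float = 2.5     # SG - SG


@dataclass
class ContactRecord:
    locator_a: tuple[str, int, str]
    locator_b: tuple[str, int, str]
    contact_type: str
    energy: float      # kcal/mol
    distance: float    # Å, closest qualifying atom pair (centroid for AROMATIC)
    midpoint: np.ndarray  # location used by contact-energy-density descriptors

    def involves(self, locator: tuple[str, int, str]) -> bool:
        return locator == self.locator_a or locator == self.locator_b


def _mainside(atom_name: str) -> str:
    from .constants import BACKBONE_ATOMS
    return "M" if atom_name in BACKBONE_ATOMS else "S"


def _hb_type(tag_a: str, tag_b: str, n_waters: int) -> str:
    pair = "".join(sorted(tag_a + tag_b))  # MM, MS, SS
    if n_waters == 0:
        return f"HB_{pair}"
    bridge = "W" * n_waters
    if pair == "MM":
        return f"HB_M{bridge}M"
    if pair == "MS":
        return f"HB_M{bridge}S"
    return f"HB_S{bridge}S"


def detect_contacts(complex_: ComplexStructure,
                    intra_only: bool = False,
                    criteria: ContactCriteria | None = None
                    ) -> list[ContactRecord]:
    """Detect all typed contacts in a structure.

    ``intra_only`` restricts the output to same-chain pairs (the "internal"
    contacts used by CED and CLO).
    """
    crit = criteria or ContactCriteria()
    residues: list[Residue] = list(complex_.iter_residues())
    if not residues:
        return []

    # Flat heavy-atom table for neighbor search.
    positions, atom_res, atom_names = [], [], []
    for ri, res in enumerate(residues):
        for atom in res.atoms:
            positions.append(atom.position)
            atom_res.append(ri)
            atom_names.append(atom.name)
    positions = np.asarray(positions)
    tree = cKDTree(positions)
    max_cut = max(crit.hydrophobic_cutoff, crit.aromatic_cutoff,
                  crit.hbond_cutoff, crit.charged_cutoff,
                  crit.disulfide_cutoff)

    # Candidate residue pairs: any heavy-atom pair within the largest cutoff.
    cand: set[tuple[int, int]] = set()
    for ia, ib in tree.query_pairs(max_cut):
        ra, rb = atom_res[ia], atom_res[ib]
        if ra == rb:
            continue
        cand.add((min(ra, rb), max(ra, rb)))

    # best[(ra, rb, type)] = (distance, midpoint)
    best: dict[tuple[int, int, str], tuple[float, np.ndarray]] = {}

    def consider(ra: int, rb: int, ctype: str, dist: float,
                 mid: np.ndarray) -> None:
        key = (ra, rb, ctype)
        cur = best.get(key)
        if cur is None or dist < cur[0]:
            best[key] = (dist, mid)

    def charge_sign(res: Residue, atom_name: str) -> int:
        grp = CHARGED_GROUP_ATOMS.get(res.amino_acid_type)
        if grp and atom_name in grp:
            return CHARGED_GROUPS[res.amino_acid_type][0]
        return 0

    for ra, rb in sorted(cand):
        res_a, res_b = residues[ra], residues[rb]
        same_chain = res_a.chain_id == res_b.chain_id
        if same_chain and abs(res_a.seq_index - res_b.seq_index) <= 1:
            continue
        if intra_only and not same_chain:
            continue

        for atom_a, atom_b in itertools.product(res_a.atoms, res_b.atoms):
            d = float(np.linalg.norm(atom_a.position - atom_b.position))
            if d > max_cut:
                continue
            mid = 0.5 * (atom_a.position + atom_b.position)
            # disulfide
            if (atom_a.name == "SG" and atom_b.name == "SG"
                    and d <= crit.disulfide_cutoff):
                consider(ra, rb, "DISULFIDE", d, mid)
                continue
            sign_a = charge_sign(res_a, atom_a.name)
            sign_b = charge_sign(res_b, atom_b.name)
            if sign_a and sign_b and d <= crit.charged_cutoff:
                ctype = ("CHARGED_ATTRACTIVE" if sign_a * sign_b < 0
                         else "CHARGED_REPULSIVE")
                consider(ra, rb, ctype, d, mid)
                continue  # charged pairs are never also H-bonds
            if (atom_a.element in "NO" and atom_b.element in "NO"
                    and d <= crit.hbond_cutoff
                    and not (sign_a and sign_b)):
                ctype = _hb_type(_mainside(atom_a.name),
                                 _mainside(atom_b.name), 0)
                consider(ra, rb, ctype, d, mid)
            if (atom_a.element == "C" and atom_b.element == "C"
                    and d <= crit.hydrophobic_cutoff
                    and atom_a.name in APOLAR_CARBONS[res_a.amino_acid_type]
                    and atom_b.name in APOLAR_CARBONS[res_b.amino_acid_type]):
                consider(ra, rb, "HYDROPHOBIC", d, mid)

        # aromatic stacking: ring-centroid distance
        ring_a = AROMATIC_RING.get(res_a.amino_acid_type)
        ring_b = AROMATIC_RING.get(res_b.amino_acid_type)
        if ring_a and ring_b:
            pts_a = [res_a.atom(n) for n in ring_a]
            pts_b = [res_b.atom(n) for n in ring_b]
            if all(pts_a) and all(pts_b):
                cen_a = np.mean([a.position for a in pts_a], axis=0)
                cen_b = np.mean([a.position for a in pts_b], axis=0)
                d = float(np.linalg.norm(cen_a - cen_b))
                if d <= crit.aromatic_cutoff:
                    consider(ra, rb, "AROMATIC", d, 0.5 * (cen_a + cen_b))

    records = [
        ContactRecord(
            locator_a=residues[ra].locator,
            locator_b=residues[rb].locator,
            contact_type=ctype,
            energy=CONTACT_ENERGY[ctype],
            distance=dist,
            midpoint=mid,
        )
        for (ra, rb, ctype), (dist, mid) in sorted(
            best.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    ]
    records.extend(_water_mediated(complex_, residues, crit, intra_only))
    return records


def _water_mediated(complex_: ComplexStructure, residues: list[Residue],
                    crit: ContactCriteria, intra_only: bool
                    ) -> list[ContactRecord]:
    waters = [w for w in complex_.waters if w.element == "O"]
    if not waters:
        return []
    wpos = np.asarray([w.position for w in waters])
    wtree = cKDTree(wpos)

    # polar protein atoms near each water
    polar_pos, polar_res, polar_tag = [], [], []
    for ri, res in enumerate(residues):
        for atom in res.atoms:
            if atom.element in "NO":
                polar_pos.append(atom.position)
                polar_res.append(ri)
                polar_tag.append(_mainside(atom.name))
    if not polar_pos:
        return []
    ptree = cKDTree(np.asarray(polar_pos))

    # water w -> {(residue index, M/S tag) -> distance} of H-bonded atoms
    near: list[dict[tuple[int, str], float]] = []
    for wi in range(len(waters)):
        found: dict[tuple[int, str], float] = {}
        for pi in ptree.query_ball_point(wpos[wi], crit.hbond_cutoff):
            d = float(np.linalg.norm(np.asarray(polar_pos[pi]) - wpos[wi]))
            key = (polar_res[pi], polar_tag[pi])
            if key not in found or d < found[key]:
                found[key] = d
        near.append(found)

    best: dict[tuple[int, int, str], tuple[float, np.ndarray]] = {}

    def consider(ra: int, rb: int, ctype: str, dist: float,
                 mid: np.ndarray) -> None:
        res_a, res_b = residues[ra], residues[rb]
        same_chain = res_a.chain_id == res_b.chain_id
        if same_chain and abs(res_a.seq_index - res_b.seq_index) <= 1:
            return
        if intra_only and not same_chain:
            return
        key = (ra, rb, ctype)
        cur = best.get(key)
        if cur is None or dist < cur[0]:
            best[key] = (dist, mid)

    # single-water bridges
    for wi, found in enumerate(near):
        for (ra, tag_a), (rb, tag_b) in itertools.combinations(
                sorted(found), 2):
            if ra == rb:
                continue
            da, db = found[(ra, tag_a)], found[(rb, tag_b)]
            consider(ra, rb, _hb_type(tag_a, tag_b, 1), da + db, wpos[wi])

    # double-water bridges: waters H-bonded to each other
    for wi, wj in wtree.query_pairs(crit.hbond_cutoff):
        mid = 0.5 * (wpos[wi] + wpos[wj])
        for (ra, tag_a), da in near[wi].items():
            for (rb, tag_b), db in near[wj].items():
                if ra == rb:
                    continue
                lo, hi = min(ra, rb), max(ra, rb)
                t = (_hb_type(tag_a, tag_b, 2) if ra <= rb
                     else _hb_type(tag_b, tag_a, 2))
                consider(lo, hi, t, da + db, mid)

    return [
        ContactRecord(
            locator_a=residues[ra].locator,
            locator_b=residues[rb].locator,
            contact_type=ctype,
            energy=CONTACT_ENERGY[ctype],
            distance=dist,
            midpoint=mid,
        )
        for (ra, rb, ctype), (dist, mid) in sorted(
            best.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    ]


def contact_energy(locator: tuple[str, int, str],
                   contacts: list[ContactRecord]) -> dict[str, float]:
    """Per-type and total contact energy (kcal/mol) for one residue."""
    out = {t: 0.0 for t in CONTACT_TYPES}
    for rec in contacts:
        if rec.involves(locator):
            out[rec.contact_type] += rec.energy
    out["TOTAL"] = sum(out[t] for t in CONTACT_TYPES)
    return out


def unused_contact_energy(amino_acid_type: str,
                          observed: dict[str, float],
                          max_table: dict[str, dict[str, float]]
                          ) -> dict[str, float]:
    """Unexploited contact potential: corpus maximum minus observed, per type
    and total, floored at zero."""
    if amino_acid_type not in max_table:
        raise KeyError(f"no contact-energy maxima for type {amino_acid_type}")
    maxima = max_table[amino_acid_type]
    return {key: max(0.0, maxima.get(key, 0.0) - observed.get(key, 0.0))
            for key in list(CONTACT_TYPES) + ["TOTAL"]}


def build_max_table(per_residue_energies: list[tuple[str, dict[str, float]]]
                    ) -> dict[str, dict[str, float]]:
    """Per-amino-acid-type maxima of contact energies over a corpus.

    Input: (amino_acid_type, per-type energy dict) per residue.
    """
    table: dict[str, dict[str, float]] = {}
    for aa, energies in per_residue_energies:
        row = table.setdefault(
            aa, {key: 0.0 for key in list(CONTACT_TYPES) + ["TOTAL"]})
        for key, val in energies.items():
            if val > row.get(key, 0.0):
                row[key] = val
    return table
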