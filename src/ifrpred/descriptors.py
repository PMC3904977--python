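"""Per-residue physicochemical and structural descriptors.

The descriptor suite characterizes each residue's nano-environment:

* contact energies per interaction type and their "unused" complement
  (distance to the corpus maximum for that amino-acid type);
* contact energy density (CED) inside probe spheres of 3-7 Å at the
  C-alpha and last-heavy-atom (LHA) anchors, internal contacts only;
* cross-link order (CLO) and cross-presence order (CPO): long-range
  (≥30 positions apart) structural neighbors, contact-based and
  sphere-based respectively;
* local packing: mass density and sponge (void fraction) in 3-7 Å spheres;
* backbone (phi/psi) and side-chain (chi1-4) torsions;
* hydrophobicity (Radzicka scale × relative accessibility);
* electrostatic potential from a screened-Coulomb sum over formal charges
  (a pluggable stand-in for a Poisson-Boltzmann solver);
* weighted neighbor averages (WNA) of every non-angular descriptor over
  residues within 15 Å, weighted by inverse distance (WNADist) or by the
  neighbor's relative accessibility (WNASurf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    CHARGED_GROUPS,
    CONTACT_TYPES,
    MAX_ACC,
    RADZICKA_SCALE,
)
from .contacts import (
    ContactCriteria,
    ContactRecord,
    contact_energy,
    detect_contacts,
    unused_contact_energy,
)
from .structure import ChainStructure, ComplexStructure, Residue, chi_angles, phi_psi
from .surface import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, sasa


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunables of the descriptor suite (defaults are the package's
    standard operating point)."""
    probe_radii: tuple[int, ...] = (3, 4, 5, 6, 7)  # Å, density/sponge/CED
    cpo_radius: float = 8.0          # Å
    min_seq_separation: int = 30     # CLO/CPO long-range threshold
    wna_cutoff: float = 15.0         # Å, neighbor-average horizon
    ep_lambda: float = 8.0           # Å, Debye-like screening length
    ep_epsilon: float = 80.0         # relative dielectric
    sasa_probe: float = DEFAULT_PROBE_RADIUS
    sasa_points: int = DEFAULT_N_POINTS
    contact_criteria: ContactCriteria = field(default_factory=ContactCriteria)


# ---------------------------------------------------------------------------
# individual descriptor operations
# ---------------------------------------------------------------------------

def clo(residue: Residue, contacts: list[ContactRecord],
        min_sep: int = 30,
        seq_index_of: dict[tuple, int] | None = None) -> int:
    """Cross-link order: distinct same-chain contact partners at sequence
    separation ≥ ``min_sep``.

    ``seq_index_of`` maps residue locators to 0-based chain positions; when
    omitted, PDB residue numbers are used as the sequence coordinate.
    """
    def seq_of(loc: tuple) -> int:
        if seq_index_of is not None:
            return seq_index_of[loc]
        return loc[1]

    partners = set()
    my = residue.locator
    for rec in contacts:
        if not rec.involves(my):
            continue
        other = rec.locator_b if rec.locator_a == my else rec.locator_a
        if other[0] != my[0]:
            continue
        if abs(seq_of(other) - seq_of(my)) >= min_sep:
            partners.add(other)
    return len(partners)


def cpo(residue: Residue, chain: ChainStructure, anchor: str,
        radius: float = 8.0, min_sep: int = 30) -> int | None:
    """Cross-presence order: residues whose matching anchor atom lies within
    ``radius`` of this residue's anchor, at sequence separation ≥ ``min_sep``.

    ``anchor`` is one of ``CA``, ``CB``, ``LHA``.  Returns None when the
    residue itself lacks the anchor atom (e.g. CB for glycine).
    """
    my_atom = _anchor_atom(residue, anchor)
    if my_atom is None:
        return None
    count = 0
    for other in chain.residues:
        if abs(other.seq_index - residue.seq_index) < min_sep:
            continue
        a = _anchor_atom(other, anchor)
        if a is None:
            continue
        if np.linalg.norm(a.position - my_atom.position) <= radius:
            count += 1
    return count


def _anchor_atom(residue: Residue, anchor: str):
    if anchor == "CA":
        return residue.c_alpha
    if anchor == "CB":
        return residue.c_beta
    if anchor == "LHA":
        return residue.lha
    raise ValueError(f"unknown anchor {anchor!r}")


def _sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * radius ** 3


def density(residue: Residue, complex_: ComplexStructure, center: str,
            radius: float) -> float | None:
    """Local mass density (Da/Å³): masses of protein atoms (any chain,
    waters excluded) whose centers fall within ``radius`` of the anchor,
    divided by the sphere volume."""
    atom = _anchor_atom(residue, center)
    if atom is None:
        return None
    total = 0.0
    for a in complex_.protein_atoms():
        if np.linalg.norm(a.position - atom.position) <= radius:
            total += a.mass
    return total / _sphere_volume(radius)


def sponge(residue: Residue, complex_: ComplexStructure, center: str,
           radius: float) -> float | None:
    """Void fraction in [0, 1] of the probe sphere after subtracting the van
    der Waals volumes of enclosed atoms (overfilled spheres clip to 0)."""
    atom = _anchor_atom(residue, center)
    if atom is None:
        return None
    vol = _sphere_volume(radius)
    occupied = 0.0
    for a in complex_.protein_atoms():
        if np.linalg.norm(a.position - atom.position) <= radius:
            occupied += _sphere_volume(a.vdw_radius)
    return max(0.0, vol - occupied) / vol


def hydrophobicity(amino_acid_type: str, relative_acc: float) -> float:
    """Radzicka-scale hydrophobicity weighted by relative accessibility."""
    return RADZICKA_SCALE[amino_acid_type] * relative_acc


def _charge_sites(complex_: ComplexStructure) -> list[tuple[float, np.ndarray]]:
    """Formal charge sites: charged side-chain group centroids plus the
    chain termini (+1 at the first N, -1 at the terminal carboxyl)."""
    sites: list[tuple[float, np.ndarray]] = []
    for chain in complex_.chains:
        for res in chain.residues:
            entry = CHARGED_GROUPS.get(res.amino_acid_type)
            if entry is None:
                continue
            sign, names = entry
            pts = [res.atom(n).position for n in names if res.atom(n)]
            if pts:
                sites.append((float(sign), np.mean(pts, axis=0)))
        if chain.residues:
            first_n = chain.residues[0].atom("N")
            if first_n is not None:
                sites.append((1.0, first_n.position))
            last = chain.residues[-1]
            cterm = last.atom("OXT") or last.atom("C")
            if cterm is not None:
                sites.append((-1.0, cterm.position))
    return sites


def screened_coulomb(point: np.ndarray,
                     sites: list[tuple[float, np.ndarray]],
                     lam: float = 8.0, eps: float = 80.0) -> float:
    """Screened-Coulomb potential Σ q·exp(-d/λ)/(ε·d) at a point; sites at
    zero distance are skipped."""
    total = 0.0
    for q, pos in sites:
        d = float(np.linalg.norm(point - pos))
        if d < 1e-9:
            continue
        total += q * math.exp(-d / lam) / (eps * d)
    return total


def electrostatic_potential(residue: Residue, complex_: ComplexStructure,
                            at: str = "CA",
                            lam: float = 8.0, eps: float = 80.0,
                            atom_exposure: dict[int, float] | None = None,
                            sites: list[tuple[float, np.ndarray]] | None = None
                            ) -> float | None:
    """Electrostatic potential at an anchor of the residue.

    ``at`` is ``CA``, ``LHA``, ``AVERAGE`` (mean over the residue's heavy
    atoms) or ``SURFACE`` (at the residue's most solvent-exposed atom;
    requires ``atom_exposure`` keyed by ``id(atom)``).
    """
    if sites is None:
        sites = _charge_sites(complex_)
    if at in ("CA", "LHA"):
        atom = _anchor_atom(residue, at)
        if atom is None:
            return None
        return screened_coulomb(atom.position, sites, lam, eps)
    if at == "AVERAGE":
        if not residue.atoms:
            return None
        vals = [screened_coulomb(a.position, sites, lam, eps)
                for a in residue.atoms]
        return float(np.mean(vals))
    if at == "SURFACE":
        if not residue.atoms:
            return None
        if atom_exposure is None:
            raise ValueError("SURFACE anchor requires per-atom exposure")
        atom = max(residue.atoms, key=lambda a: atom_exposure.get(id(a), 0.0))
        return screened_coulomb(atom.position, sites, lam, eps)
    raise ValueError(f"unknown anchor {at!r}")


def ced(residue: Residue, contacts: list[ContactRecord], anchor: str,
        radius: float) -> float | None:
    """Contact energy density (kcal/mol per Å³): energies of contacts whose
    midpoint lies within ``radius`` of the anchor, over the sphere volume."""
    atom = _anchor_atom(residue, anchor)
    if atom is None:
        return None
    total = 0.0
    for rec in contacts:
        if np.linalg.norm(rec.midpoint - atom.position) <= radius:
            total += rec.energy
    return total / _sphere_volume(radius)


def wna(values, positions, rel_acc, mode: str, cutoff: float = 15.0
        ) -> np.ndarray:
    """Weighted neighbor average of a per-residue descriptor.

    For residue i, averages the descriptor over the N neighbors j within
    ``cutoff`` Å (positions are the residues' anchor coordinates, the
    residue itself excluded): weights are 1/d_ij in ``DIST`` mode and the
    neighbor's relative accessibility in ``SURF`` mode.  A residue with no
    neighbors (or all-zero weights, or only missing neighbor values) keeps
    its own value.  Missing (NaN) neighbor values are skipped; the result
    for a residue whose own value is NaN is NaN only if it also has no
    usable neighbors.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if mode not in ("DIST", "SURF"):
        raise ValueError(f"unknown WNA mode {mode!r}")
    vals = np.asarray(values, dtype=float)
    pos = np.asarray(positions, dtype=float)
    acc = np.asarray(rel_acc, dtype=float)
    n = len(vals)
    out = np.empty(n)
    tree = cKDTree(pos)
    for i in range(n):
        num = 0.0
        den = 0.0
        for j in tree.query_ball_point(pos[i], cutoff):
            if j == i or not np.isfinite(vals[j]):
                continue
            if mode == "DIST":
                d = float(np.linalg.norm(pos[i] - pos[j]))
                w = 1.0 / d if d > 0 else 0.0
            else:
                w = acc[j] if np.isfinite(acc[j]) else 0.0
            num += w * vals[j]
            den += w
        out[i] = num / den if den > 0 else vals[i]
    return out


# ---------------------------------------------------------------------------
# descriptor-table assembly
# ---------------------------------------------------------------------------

ANGLE_COLUMNS = ("PHI", "PSI", "CHI1", "CHI2", "CHI3", "CHI4")


def base_descriptor_columns(config: DescriptorConfig | None = None
                            ) -> list[str]:
    cfg = config or DescriptorConfig()
    cols = ["Hydrophobicity", "EP@Ca", "EP@LHA", "EP_Average", "EP@Surface"]
    for anchor in ("Ca", "LHA"):
        cols += [f"CED@{anchor}_INT_{r}" for r in cfg.probe_radii]
    cols += ["CLO", "CPO@Ca", "CPO@Cb", "CPO@LHA"]
    cols += list(ANGLE_COLUMNS)
    for anchor in ("Ca", "LHA"):
        cols += [f"Density@{anchor}_{r}" for r in cfg.probe_radii]
    for anchor in ("Ca", "LHA"):
        cols += [f"Sponge@{anchor}_{r}" for r in cfg.probe_radii]
    cols += [f"Energy_{t}" for t in CONTACT_TYPES] + ["Energy_TOTAL"]
    return cols


def compute_descriptors(complex_: ComplexStructure,
                        config: DescriptorConfig | None = None
                        ) -> pd.DataFrame:
    """Full per-residue descriptor table for a structure.

    One row per residue (index: chain, residue number, insertion code), one
    column per descriptor variant, NaN for missing values.  WNA columns are
    appended for every non-angular descriptor.  Relative accessibility is
    computed per chain in isolation, so the table is identical whether the
    chain is passed alone or inside a complex *only* for single-chain
    inputs; the training pipeline always passes single chains.
    """
    cfg = config or DescriptorConfig()
    contacts_all = detect_contacts(complex_, criteria=cfg.contact_criteria)
    contacts_int = [r for r in contacts_all
                    if r.locator_a[0] == r.locator_b[0]]
    sites = _charge_sites(complex_)
    seq_index_of = {res.locator: res.seq_index
                    for res in complex_.iter_residues()}

    # per-atom exposure and per-residue relative accessibility, per chain in
    # isolation
    atom_exposure: dict[int, float] = {}
    rel_acc: dict[tuple, float] = {}
    for chain in complex_.chains:
        atoms = [a for res in chain.residues for a in res.atoms]
        areas = sasa(atoms, cfg.sasa_probe, cfg.sasa_points)
        for a, area in zip(atoms, areas):
            atom_exposure[id(a)] = float(area)
        for res in chain.residues:
            tot = sum(atom_exposure[id(a)] for a in res.atoms)
            rel_acc[res.locator] = tot / MAX_ACC[res.amino_acid_type]

    rows = []
    index = []
    for chain in complex_.chains:
        for i, res in enumerate(chain.residues):
            row: dict[str, float | None] = {}
            loc = res.locator
            row["Hydrophobicity"] = hydrophobicity(
                res.amino_acid_type, rel_acc[loc])
            for at, col in (("CA", "EP@Ca"), ("LHA", "EP@LHA"),
                            ("AVERAGE", "EP_Average"),
                            ("SURFACE", "EP@Surface")):
                row[col] = electrostatic_potential(
                    res, complex_, at, cfg.ep_lambda, cfg.ep_epsilon,
                    atom_exposure=atom_exposure, sites=sites)
            for anchor, tag in (("CA", "Ca"), ("LHA", "LHA")):
                for r in cfg.probe_radii:
                    row[f"CED@{tag}_INT_{r}"] = ced(
                        res, contacts_int, anchor, float(r))
            row["CLO"] = clo(res, contacts_int, cfg.min_seq_separation,
                             seq_index_of)
            for anchor, tag in (("CA", "Ca"), ("CB", "Cb"), ("LHA", "LHA")):
                row[f"CPO@{tag}"] = cpo(res, chain, anchor, cfg.cpo_radius,
                                        cfg.min_seq_separation)
            phi, psi = phi_psi(chain, i)
            row["PHI"] = phi
            row["PSI"] = psi
            chis = chi_angles(res)
            for k in range(4):
                row[f"CHI{k + 1}"] = chis[k] if k < len(chis) else None
            for anchor, tag in (("CA", "Ca"), ("LHA", "LHA")):
                for r in cfg.probe_radii:
                    row[f"Density@{tag}_{r}"] = density(
                        res, complex_, anchor, float(r))
                    row[f"Sponge@{tag}_{r}"] = sponge(
                        res, complex_, anchor, float(r))
            energies = contact_energy(loc, contacts_all)
            for t in CONTACT_TYPES:
                row[f"Energy_{t}"] = energies[t]
            row["Energy_TOTAL"] = energies["TOTAL"]
            row["_rel_acc"] = rel_acc[loc]
            row["_aa"] = res.amino_acid_type
            rows.append(row)
            index.append(loc)

    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["chain", "residue", "icode"]))
    df = add_wna_columns(df, complex_, cfg)
    return df


def add_wna_columns(df: pd.DataFrame, complex_: ComplexStructure,
                    config: DescriptorConfig | None = None) -> pd.DataFrame:
    """Append _WNADist and _WNASurf variants for every non-angular
    descriptor column, using C-alpha positions as neighbor coordinates."""
    cfg = config or DescriptorConfig()
    positions = []
    for res in complex_.iter_residues():
        ca = res.c_alpha
        positions.append(ca.position if ca is not None
                         else res.atoms[0].position)
    positions = np.asarray(positions)
    rel = df["_rel_acc"].to_numpy(dtype=float)
    new_cols = {}
    for col in df.columns:
        if col.startswith("_") or col in ANGLE_COLUMNS:
            continue
        vals = df[col].to_numpy(dtype=float)
        new_cols[f"{col}_WNADist"] = wna(vals, positions, rel, "DIST",
                                         cfg.wna_cutoff)
        new_cols[f"{col}_WNASurf"] = wna(vals, positions, rel, "SURF",
                                         cfg.wna_cutoff)
    return pd.concat([df, pd.DataFrame(new_cols, index=df.index)], axis=1)


def add_unused_columns(df: pd.DataFrame,
                       max_table: dict[str, dict[str, float]],
                       with_wna: bool = True,
                       complex_: ComplexStructure | None = None,
                       config: DescriptorConfig | None = None
                       ) -> pd.DataFrame:
    """Append Unused_* contact-energy columns given per-type corpus maxima.

    Maxima are a training-corpus property, so this step is separate from
    :func:`compute_descriptors` (it must be re-done per training fold).
    When ``with_wna`` is set and a structure is supplied, WNA variants of
    the unused columns are appended as well.
    """
    cfg = config or DescriptorConfig()
    keys = list(CONTACT_TYPES) + ["TOTAL"]
    unused_rows = []
    for loc, row in df.iterrows():
        aa = row["_aa"]
        observed = {t: row[f"Energy_{t}"] for t in CONTACT_TYPES}
        observed["TOTAL"] = row["Energy_TOTAL"]
        unused_rows.append(unused_contact_energy(aa, observed, max_table))
    unused_df = pd.DataFrame(
        [{f"Unused_{k}": v[k] for k in keys} for v in unused_rows],
        index=df.index)
    out = pd.concat([df, unused_df], axis=1)
    if with_wna and complex_ is not None:
        positions = []
        for res in complex_.iter_residues():
            ca = res.c_alpha
            positions.append(ca.position if ca is not None
                             else res.atoms[0].position)
        positions = np.asarray(positions)
        rel = out["_rel_acc"].to_numpy(dtype=float)
        new_cols = {}
        for k in keys:
            vals = out[f"Unused_{k}"].to_numpy(dtype=float)
            new_cols[f"Unused_{k}_WNADist"] = wna(
                vals, positions, rel, "DIST", cfg.wna_cutoff)
            new_cols[f"Unused_{k}_WNASurf"] = wna(
                vals, positions, rel, "SURF", cfg.wna_cutoff)
        out = pd.concat([out, pd.DataFrame(new_cols, index=out.index)],
                        axis=1)
    return out


def descriptors_to_tsv(df: pd.DataFrame) -> str:
    """Wide per-residue descriptor table as TSV (NA for missing)."""
    out = df.drop(columns=[c for c in df.columns if c.startswith("_")])
    out = out.copy()
    out.insert(0, "aa", df["_aa"])
    return out.to_csv(sep="\t", na_rep="NA")
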