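"""Synthetic test inputs: toy two-chain complexes with planted contacts and
known interface residues, and labeled Gaussian feature sets with known
Bayes-optimal separability.

The toy complexes are geometric test vectors, not realistic folds: each
chain is an ideal extended backbone (N-CA 1.46 Å, CA-C 1.52 Å, C-N 1.33 Å)
laid along x, the partner chain offset in z, and planted contacts place the
relevant side-chain atoms at exactly the requested distance between the
chains.  Every generator is seed-deterministic and ships its ground truth
alongside, so tests never re-derive truth from the code under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import Datamart
from .structure import ComplexStructure, parse_pdb

# residue types used to realize each planted contact type, and the
# side-chain atoms placed at the contact distance
_CONTACT_RESIDUES: dict[str, tuple[str, str, str, str]] = {
    # type: (aa_a, atom_a, aa_b, atom_b)
    "HYDROPHOBIC": ("LEU", "CD1", "LEU", "CD1"),
    "DISULFIDE": ("CYS", "SG", "CYS", "SG"),
    "CHARGED_ATTRACTIVE": ("LYS", "NZ", "ASP", "OD1"),
    "CHARGED_REPULSIVE": ("LYS", "NZ", "LYS", "NZ"),
    "HB_SS": ("SER", "OG", "SER", "OG"),
}


@dataclass
class ToyComplexSpec:
    n_residues: int = 12
    planted_contacts: list[tuple[str, tuple[int, int], float]] = field(
        default_factory=list)  # (contact type, (res_a, res_b), distance Å)
    chain_separation: float = 100.0  # Å between the two backbones
    contact_patch: list[int] = field(default_factory=list)
    patch_distance: float = 3.6      # Å between facing patch atoms
    fsr_decoys: list[int] = field(default_factory=list)
    seed: int = 0
    include_waters: bool = False


class GenerationError(ValueError):
    """Raised for infeasible fixture geometry."""


_SPACING = 3.88  # Å between consecutive residue frames along x


def _backbone(i: int, z: float) -> dict[str, tuple[float, float, float]]:
    x0 = _SPACING * i
    return {
        "N": (x0, 0.0, z),
        "CA": (x0 + 1.23, 0.78, z),
        "C": (x0 + 2.55, 0.0, z),
        "O": (x0 + 2.95, -1.16, z),
    }


def make_toy_complex(spec: ToyComplexSpec) -> tuple[str, dict]:
    """Build a two-chain toy complex as PDB text plus its ground truth.

    Ground truth: the planted contacts (with the residue locators they
    join) and the residues that are interface-forming by construction (the
    contact-patch residues, whose facing side-chain atoms occlude each
    other across the chains).
    """
    n = spec.n_residues
    for _, (ia, ib), dist in spec.planted_contacts:
        if not (0 <= ia < n and 0 <= ib < n):
            raise GenerationError("planted contact index out of range")
        if dist <= 0:
            raise GenerationError("planted contact distance must be positive")
    sep = spec.chain_separation
    # residue types: default GLY everywhere, overridden where planted
    types_a = ["GLY"] * n
    types_b = ["GLY"] * n
    extra_a: dict[int, list[tuple[str, tuple[float, float, float]]]] = {}
    extra_b: dict[int, list[tuple[str, tuple[float, float, float]]]] = {}

    truth_contacts = []
    for ctype, (ia, ib), dist in spec.planted_contacts:
        if ctype not in _CONTACT_RESIDUES:
            raise GenerationError(f"unsupported planted contact {ctype!r}")
        aa_a, atom_a, aa_b, atom_b = _CONTACT_RESIDUES[ctype]
        types_a[ia] = aa_a
        types_b[ib] = aa_b
        xa = _SPACING * ia + 1.23
        za = (sep - dist) / 2.0
        zb = (sep + dist) / 2.0
        pa = (xa, 0.78, za)
        pb = (xa, 0.78, zb)
        extra_a.setdefault(ia, []).append((atom_a, pa))
        extra_b.setdefault(ib, []).append((atom_b, pb))
        if ctype == "CHARGED_ATTRACTIVE":
            # ASP needs the full carboxylate pair for its charged group
            extra_b[ib].append(("OD2", (xa + 1.1, 0.78, zb)))
        if dist > 2.0 * (1.7 + 1.4):
            raise GenerationError(
                "planted contact distance exceeds occlusion range; "
                "the contact criteria table caps at 6 Å")
        truth_contacts.append({
            "type": ctype,
            "chain_a": "A", "residue_a": ia + 1,
            "chain_b": "B", "residue_b": ib + 1,
            "distance": dist,
        })

    patch_ifr = []
    for idx in spec.contact_patch:
        if not (0 <= idx < n):
            raise GenerationError("contact patch index out of range")
        types_a[idx] = "LEU"
        types_b[idx] = "LEU"
        x = _SPACING * idx + 1.23
        za = (sep - spec.patch_distance) / 2.0
        zb = (sep + spec.patch_distance) / 2.0
        extra_a.setdefault(idx, []).append(("CD1", (x, 0.78, za)))
        extra_b.setdefault(idx, []).append(("CD1", (x, 0.78, zb)))
        patch_ifr.append(("A", idx + 1))
        patch_ifr.append(("B", idx + 1))

    # free-surface decoys: same residue type as the patch but with the side
    # chain pointing away from the interface, so the type's datamart gets
    # both classes
    for idx in spec.fsr_decoys:
        if not (0 <= idx < n):
            raise GenerationError("decoy index out of range")
        if idx in spec.contact_patch:
            raise GenerationError("decoy overlaps contact patch")
        types_a[idx] = "LEU"
        types_b[idx] = "LEU"
        x = _SPACING * idx + 1.23
        extra_a.setdefault(idx, []).append(("CD1", (x, 0.78, -2.5)))
        extra_b.setdefault(idx, []).append(("CD1", (x, 0.78, sep + 2.5)))

    lines = []
    serial = 1

    def emit(chain_id, i, resname, atoms):
        nonlocal serial
        for name, (x, y, z) in atoms:
            elem = name[0] if not name.startswith("SE") else "SE"
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} {chain_id}"
                f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {elem:>2s}")
            serial += 1

    for i in range(n):
        atoms = list(_backbone(i, 0.0).items()) + extra_a.get(i, [])
        emit("A", i, types_a[i], atoms)
    lines.append("TER")
    for i in range(n):
        atoms = list(_backbone(i, sep).items()) + extra_b.get(i, [])
        emit("B", i, types_b[i], atoms)
    lines.append("TER")
    if spec.include_waters:
        rng = np.random.default_rng(spec.seed)
        for w in range(3):
            x = float(rng.uniform(0, _SPACING * n))
            y = float(rng.uniform(10, 20))
            lines.append(
                f"HETATM{serial:5d}  O   HOH W{w + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{-30.0:8.3f}  1.00  0.00           O")
            serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    planted_pair_ifr = []
    for ctype, (ia, ib), dist in spec.planted_contacts:
        # side chains occlude each other when inside SASA occlusion range
        if dist <= 2 * 1.7 + 2 * 1.4:
            planted_pair_ifr += [("A", ia + 1), ("B", ib + 1)]
    truth = {
        "contacts": truth_contacts,
        "ifr_residues": sorted(set(patch_ifr + planted_pair_ifr)),
        "n_residues": n,
        "chain_separation": sep,
    }
    return pdb_text, truth


def make_toy_structure(spec: ToyComplexSpec,
                       pdb_id: str = "TOY1") -> tuple[ComplexStructure, dict]:
    text, truth = make_toy_complex(spec)
    return parse_pdb(text, pdb_id=pdb_id), truth


@dataclass
class GaussianMartSpec:
    n_per_class: int = 500
    n_features: int = 10
    separation: float = 2.0          # Δ, class-mean distance in pooled SDs
    covariance: str = "identity"     # or "planted-correlation"
    amino_acid_type: str = "LEU"
    n_duplicate: int = 2             # extra duplicated columns (planted mode)
    n_combination: int = 2           # extra linear-combination columns
    direction_seed: int | None = None  # fixes the shift direction separately
    seed: int = 0


def make_gaussian_mart(spec: GaussianMartSpec) -> tuple[Datamart, dict]:
    """Two multivariate-Gaussian classes with identity covariance and class
    means Δ apart, giving an analytic Bayes AUC of Φ(Δ/√2).

    ``planted-correlation`` mode appends duplicated and linear-combination
    columns to exercise correlation pruning and PCA.  Returns the datamart
    and its ground truth (Bayes AUC, shift direction, planted columns).
    """
    if spec.separation < 0:
        raise ValueError("separation must be non-negative")
    if spec.n_per_class < 2:
        raise ValueError("need at least 2 rows per class")
    rng = np.random.default_rng(spec.seed)
    d = spec.n_features
    dir_rng = (np.random.default_rng(spec.direction_seed)
               if spec.direction_seed is not None else rng)
    u = dir_rng.standard_normal(d)
    u /= np.linalg.norm(u)
    shift = spec.separation * u
    X0 = rng.standard_normal((spec.n_per_class, d))
    X1 = rng.standard_normal((spec.n_per_class, d)) + shift
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(spec.n_per_class, dtype=int),
                        np.ones(spec.n_per_class, dtype=int)])
    cols = [f"f{i}" for i in range(d)]
    planted: list[str] = []
    if spec.covariance == "planted-correlation":
        blocks = [X]
        for j in range(spec.n_duplicate):
            src = j % d
            blocks.append(X[:, [src]])
            planted.append(f"dup{j}_of_f{src}")
            cols.append(planted[-1])
        for j in range(spec.n_combination):
            w = rng.standard_normal(d)
            blocks.append((X[:, :d] @ w)[:, None])
            planted.append(f"combo{j}")
            cols.append(planted[-1])
        X = np.hstack(blocks)
    elif spec.covariance != "identity":
        raise ValueError(f"unknown covariance structure {spec.covariance!r}")

    perm = rng.permutation(len(y))
    X, y = X[perm], y[perm]
    frame = pd.DataFrame(X, columns=cols)
    n_entries = max(10, len(y) // 50)
    entry_ids = np.array([f"SYN{i % n_entries:03d}" for i in range(len(y))],
                         dtype=object)
    mart = Datamart(amino_acid_type=spec.amino_acid_type, X=frame, y=y,
                    entry_ids=entry_ids)
    from scipy.stats import norm

    truth = {
        "bayes_auc": float(norm.cdf(spec.separation / math.sqrt(2.0))),
        "shift_direction": u,
        "planted_columns": planted,
    }
    return mart, truth
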