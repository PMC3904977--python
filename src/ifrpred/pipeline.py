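"""End-to-end training and prediction workflows.

Training: label every residue of every corpus entry (IFR / FSR / buried by
accessibility change), compute each chain's descriptors in isolation, split
the corpus into entry-level folds, and — per fold, on training entries only
— derive the contact-energy maxima, prune correlated descriptors, fit the
per-type PCA and LDA, and score the held-out entries.  The shipped bundle
is refit on the full corpus.

Features are computed on chains in isolation while labels come from the
isolation-vs-complex accessibility change; computing features on the
assembled complex would leak the label through interface packing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .contacts import CONTACT_TYPES, build_max_table
from .descriptors import add_unused_columns, compute_descriptors
from .evaluation import (
    EvalReport,
    FoldAssignment,
    UndefinedMetricError,
    kfold_split,
    roc_auc,
)
from .features import (
    Datamart,
    build_datamart,
    drop_correlated,
    fit_pca,
    project,
)
from .lda import (
    ClassifierBundle,
    TrainingError,
    TypeClassifier,
    aggregate,
    fit_lda,
    predict_table,
)
from .structure import ComplexStructure
from .surface import ResidueClass, label_residues


@dataclass
class EntryData:
    """Labeled, per-chain descriptor tables for one corpus entry."""
    pdb_id: str
    chains: dict[str, object]      # chain_id -> single-chain ComplexStructure
    tables: dict[str, pd.DataFrame]  # chain_id -> base descriptor table
    labels: pd.Series              # per-residue class, indexed like tables
    ifr: pd.Series                 # binary label for surface residues


def prepare_entry(complex_: ComplexStructure, config: RunConfig) -> EntryData:
    """Label a complex and compute per-chain isolation descriptors."""
    dcfg = config.descriptor_config()
    labels = label_residues(
        complex_, config.probe_radius, config.n_points,
        config.delta_area, config.exposure_min)
    label_map = {(l.chain_id, l.residue_seq, l.insertion_code): l.cls.value
                 for l in labels}
    chains: dict[str, object] = {}
    tables: dict[str, pd.DataFrame] = {}
    for chain in complex_.chains:
        sub = complex_.subcomplex(chain.chain_id)
        chains[chain.chain_id] = sub
        tables[chain.chain_id] = compute_descriptors(sub, dcfg)
    all_idx = pd.concat(list(tables.values())).index
    cls = pd.Series([label_map[i] for i in all_idx], index=all_idx)
    ifr = (cls == ResidueClass.IFR.value).astype(int)
    return EntryData(pdb_id=complex_.pdb_id, chains=chains, tables=tables,
                     labels=cls, ifr=ifr)


def _entry_full_table(entry: EntryData,
                      max_table: dict, config: RunConfig) -> pd.DataFrame:
    dcfg = config.descriptor_config()
    parts = [
        add_unused_columns(entry.tables[cid], max_table,
                           complex_=entry.chains[cid], config=dcfg)
        for cid in entry.tables
    ]
    return pd.concat(parts)


def _max_table_from_entries(entries: list[EntryData]) -> dict:
    rows = []
    for e in entries:
        for table in e.tables.values():
            for _, row in table.iterrows():
                energies = {t: float(row[f"Energy_{t}"])
                            for t in CONTACT_TYPES}
                energies["TOTAL"] = float(row["Energy_TOTAL"])
                rows.append((row["_aa"], energies))
    return build_max_table(rows)


def build_marts(entries: list[EntryData], max_table: dict,
                config: RunConfig) -> dict[str, Datamart]:
    """Per-amino-acid-type datamarts over the surface residues (IFR=1,
    FSR=0; buried residues excluded) of the given entries."""
    frames = []
    for e in entries:
        full = _entry_full_table(e, max_table, config)
        full = full.loc[e.labels.loc[full.index] != ResidueClass.BURIED.value]
        full = full.assign(
            _label=e.ifr.loc[full.index].to_numpy(),
            _entry=e.pdb_id)
        frames.append(full)
    corpus = pd.concat(frames)
    marts: dict[str, Datamart] = {}
    feature_cols = [c for c in corpus.columns if not c.startswith("_")]
    for aa, group in corpus.groupby("_aa"):
        mart = build_datamart(
            aa, group[feature_cols],
            group["_label"].to_numpy(),
            group["_entry"].to_numpy())
        if len(mart.y) >= 4 and len(set(mart.y)) == 2:
            marts[aa] = mart
        else:
            warnings.warn(
                f"type {aa}: insufficient or single-class data; skipped")
    return marts


def fit_type_classifiers(marts: dict[str, Datamart], config: RunConfig,
                         frozen_k: dict[str, int] | None = None
                         ) -> tuple[dict[str, TypeClassifier], dict[str, int]]:
    """Fit correlation pruning + PCA + LDA per amino-acid type.

    Returns the classifiers and the per-type retained-component counts
    (which callers may freeze across cross-validation folds).
    """
    classifiers: dict[str, TypeClassifier] = {}
    k_used: dict[str, int] = {}
    for aa, mart in marts.items():
        reduced, _removed = drop_correlated(
            mart.X, config.correlation_threshold)
        k = frozen_k.get(aa) if frozen_k else None
        if k is not None:
            k = min(k, reduced.shape[1])
        proj = fit_pca(reduced, config.variance_target, k=k)
        scores = project(proj, reduced)
        try:
            model = fit_lda(scores, mart.y, amino_acid_type=aa)
        except TrainingError as exc:
            warnings.warn(str(exc))
            continue
        classifiers[aa] = TypeClassifier(
            columns=list(reduced.columns), projection=proj, model=model)
        k_used[aa] = proj.k
    return classifiers, k_used


@dataclass
class CVReport:
    fold_assignment: FoldAssignment
    per_fold_auc: list[float] = field(default_factory=list)
    per_fold_max_mcc: list[float] = field(default_factory=list)
    per_type_auc: dict[str, list[float]] = field(default_factory=dict)
    skipped_folds: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_fold_auc))


def train_corpus(complexes: list[ComplexStructure], config: RunConfig
                 ) -> tuple[ClassifierBundle, CVReport]:
    """Full training workflow on a corpus of parsed complexes.

    Per-type retained-component counts are frozen from the first fold's
    training set and reused in all folds, keeping the projections
    comparable across folds.  All fitted quantities (energy maxima,
    pruning, PCA, LDA) derive from training folds only.
    """
    entries = [prepare_entry(c, config) for c in complexes]
    by_id = {e.pdb_id: e for e in entries}
    if len(by_id) != len(entries):
        raise ValueError("duplicate pdb_ids in corpus")
    assignment = kfold_split(sorted(by_id), config.k_folds, config.seed)

    report = CVReport(fold_assignment=assignment)
    frozen_k: dict[str, int] | None = None
    for fold in range(assignment.k):
        train = [by_id[i] for i in assignment.train_ids(fold)]
        test = [by_id[i] for i in assignment.test_ids(fold)]
        max_table = _max_table_from_entries(train)
        marts = build_marts(train, max_table, config)
        classifiers, k_used = fit_type_classifiers(marts, config, frozen_k)
        if frozen_k is None:
            frozen_k = k_used
        bundle = ClassifierBundle(
            classifiers=classifiers, max_table=max_table,
            cutoff=config.decision_cutoff, seed=config.seed)
        scores, labels, types = [], [], []
        for e in test:
            full = _entry_full_table(e, max_table, config)
            surf = e.labels.loc[full.index] != ResidueClass.BURIED.value
            full = full.loc[surf.to_numpy()]
            preds = predict_table(bundle, full)
            ok = preds["predicted"].to_numpy()
            scores.append(preds["P_IFR"].to_numpy()[ok])
            labels.append(e.ifr.loc[full.index].to_numpy()[ok])
            types.append(full["_aa"].to_numpy()[ok])
        s = np.concatenate(scores) if scores else np.array([])
        y = np.concatenate(labels) if labels else np.array([])
        t = np.concatenate(types) if types else np.array([])
        try:
            rep = roc_auc(s, y, seed=config.seed)
        except UndefinedMetricError:
            report.skipped_folds += 1
            continue
        report.per_fold_auc.append(rep.auc)
        report.per_fold_max_mcc.append(rep.max_mcc)
        for aa in np.unique(t):
            mask = t == aa
            if len(set(y[mask])) == 2:
                aa_rep = roc_auc(s[mask], y[mask])
                report.per_type_auc.setdefault(aa, []).append(aa_rep.auc)

    # final bundle refit on the whole corpus
    max_table = _max_table_from_entries(entries)
    marts = build_marts(entries, max_table, config)
    classifiers, _ = fit_type_classifiers(marts, config, frozen_k)
    bundle = ClassifierBundle(
        classifiers=classifiers, max_table=max_table,
        cutoff=config.decision_cutoff, seed=config.seed,
        provenance={"n_entries": len(entries),
                    "k_folds": config.k_folds,
                    "config": config.to_dict()})
    return bundle, report


def predict_structure(bundle: ClassifierBundle, complex_: ComplexStructure,
                      config: RunConfig | None = None,
                      cutoff: float | None = None) -> pd.DataFrame:
    """Per-residue IFR posterior and class for a structure.

    Each chain is scored from its isolation descriptors.  Buried residues
    (relative accessibility below the surface threshold) are reported
    without a prediction; so are residue types without a model.
    """
    config = config or RunConfig()
    dcfg = config.descriptor_config()
    parts = []
    for chain in complex_.chains:
        sub = complex_.subcomplex(chain.chain_id)
        table = compute_descriptors(sub, dcfg)
        full = add_unused_columns(table, bundle.max_table,
                                  complex_=sub, config=dcfg)
        surface = full["_rel_acc"] >= config.exposure_min
        preds = predict_table(bundle, full.loc[surface.to_numpy()], cutoff)
        buried = full.loc[(~surface).to_numpy()]
        if len(buried):
            b = pd.DataFrame(index=buried.index)
            b["aa"] = buried["_aa"]
            b["P_IFR"] = np.nan
            b["predicted"] = False
            b["predicted_class"] = "BURIED"
            b["cutoff"] = cutoff if cutoff is not None else bundle.cutoff
            preds = pd.concat([preds, b])
        parts.append(preds)
    return aggregate(parts)


def predictions_to_tsv(preds: pd.DataFrame, pdb_id: str = "") -> str:
    lines = ["pdb_id\tchain\tresidue\ticode\taa\tP_IFR\tclass\tcutoff"]
    for (chain, resnum, icode), row in preds.iterrows():
        p = "NA" if not np.isfinite(row["P_IFR"]) else f"{row['P_IFR']:.6f}"
        lines.append(f"{pdb_id}\t{chain}\t{resnum}\t{icode}\t{row['aa']}"
                     f"\t{p}\t{row['predicted_class']}\t{row['cutoff']}")
    return "\n".join(lines) + "\n"
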