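"""Datamart assembly, correlated-descriptor pruning, and PCA projection.

Each amino-acid type gets its own "datamart": a matrix of descriptor values
for that type's surface residues with a binary interface label (IFR=1,
FSR=0).  Training preprocessing is strictly fit-on-train: correlation
pruning and the PCA standardization/rotation are learned from training rows
only and then applied unchanged to test rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Datamart:
    amino_acid_type: str
    X: pd.DataFrame          # rows = residues, columns = descriptors
    y: np.ndarray            # binary labels, IFR = 1, FSR = 0
    entry_ids: np.ndarray    # parent structure id per row (for entry-level CV)
    dropped_rows: int = 0    # rows removed for missing values
    dropped_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.entry_ids = np.asarray(self.entry_ids, dtype=object)
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be binary (IFR=1, FSR=0)")

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, mask: np.ndarray) -> "Datamart":
        return Datamart(self.amino_acid_type, self.X.iloc[mask].copy(),
                        self.y[mask], self.entry_ids[mask])


def build_datamart(amino_acid_type: str, table: pd.DataFrame,
                   labels: np.ndarray, entry_ids: np.ndarray) -> Datamart:
    """Assemble one type's datamart from a raw descriptor table.

    Columns that are entirely missing for the type (e.g. chi angles for
    glycine) or have zero variance are dropped first; remaining rows with
    any missing value are then discarded, mirroring the exclusion of chains
    with missing attributes from training.
    """
    dropped_cols = [c for c in table.columns
                    if table[c].isna().all()
                    or table[c].nunique(dropna=True) <= 1]
    X = table.drop(columns=dropped_cols)
    keep = ~X.isna().any(axis=1).to_numpy()
    return Datamart(
        amino_acid_type=amino_acid_type,
        X=X.loc[keep].reset_index(drop=True),
        y=np.asarray(labels)[keep],
        entry_ids=np.asarray(entry_ids, dtype=object)[keep],
        dropped_rows=int((~keep).sum()),
        dropped_columns=dropped_cols,
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def drop_correlated(X: pd.DataFrame, threshold: float = 0.85
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively remove the column most correlated with others until no
    pair exceeds ``threshold`` in |r|.

    The column participating in the most over-threshold pairs is removed at
    each step (ties broken by larger mean |r| over those pairs, then by
    column order).  Returns the reduced frame and the removal log.
    """
    cols = list(X.columns)
    corr = np.abs(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 0.0)
    removed: list[str] = []
    active = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(active, active)]
        over = sub > threshold
        if not over.any():
            break
        counts = over.sum(axis=1)
        mean_r = np.where(counts > 0,
                          (sub * over).sum(axis=1) / np.maximum(counts, 1),
                          0.0)
        # most pairs first, then larger mean |r|, then earliest column
        order = sorted(range(len(active)),
                       key=lambda i: (-counts[i], -mean_r[i], i))
        victim = order[0]
        removed.append(cols[active[victim]])
        del active[victim]
    keep = [cols[i] for i in active]
    return X[keep], removed


@dataclass
class PCAProjection:
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    eigenvectors: np.ndarray  # (n_features, n_features), columns = components
    eigenvalues: np.ndarray   # non-increasing
    k: int                    # retained component count
    variance_target: float = 0.95

    @property
    def cumulative_variance(self) -> float:
        """Fraction of total variance captured by the k retained components."""
        total = float(self.eigenvalues.sum())
        return float(self.eigenvalues[:self.k].sum() / total)

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "k": self.k,
            "variance_target": self.variance_target,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAProjection":
        return cls(
            columns=list(d["columns"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            eigenvectors=np.asarray(d["eigenvectors"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            k=int(d["k"]),
            variance_target=float(d["variance_target"]),
        )


def fit_pca(X: pd.DataFrame, variance_target: float = 0.95,
            k: int | None = None) -> PCAProjection:
    """Correlation-matrix PCA fit on training rows.

    Columns are standardized by their training mean and SD; the retained
    component count is the smallest k whose cumulative eigenvalue fraction
    reaches ``variance_target`` (or the explicitly frozen ``k``).
    Rank-deficient inputs proceed with zero eigenvalues and a warning.
    """
    data = X.to_numpy(dtype=float)
    means = data.mean(axis=0)
    sds = data.std(axis=0, ddof=1)
    if np.any(sds == 0):
        warnings.warn("zero-variance column in PCA input; left unscaled")
        sds = np.where(sds == 0, 1.0, sds)
    Z = (data - means) / sds
    corr = (Z.T @ Z) / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    if np.any(eigvals <= 1e-12):
        warnings.warn("rank-deficient correlation matrix; zero eigenvalues")
    if k is None:
        frac = np.cumsum(eigvals) / eigvals.sum()
        k = int(np.searchsorted(frac, variance_target - 1e-12) + 1)
    return PCAProjection(
        columns=list(X.columns), means=means, sds=sds,
        eigenvectors=eigvecs, eigenvalues=eigvals, k=int(k),
        variance_target=variance_target)


def project(projection: PCAProjection, X: pd.DataFrame) -> np.ndarray:
    """Project rows onto the retained components.

    Standardization uses the *training* means/SDs; the projection is never
    re-fit on the rows being projected.  Column mismatches raise with the
    lists of missing/extra names.
    """
    missing = [c for c in projection.columns if c not in X.columns]
    extra = [c for c in X.columns if c not in projection.columns]
    if missing or extra:
        raise ValueError(
            f"column mismatch: missing {missing!r}, unexpected {extra!r}")
    data = X[projection.columns].to_numpy(dtype=float)
    Z = (data - projection.means) / projection.sds
    return Z @ projection.eigenvectors[:, :projection.k]


def save_datamart_tsv(mart: Datamart, path_tsv, path_json) -> None:
    out = mart.X.copy()
    out["label"] = mart.y
    out["entry_id"] = mart.entry_ids
    out.to_csv(path_tsv, sep="\t", index=False)
    with open(path_json, "w") as fh:
        json.dump({
            "amino_acid_type": mart.amino_acid_type,
            "columns": mart.columns,
            "label_column": "label",
            "entry_column": "entry_id",
            "dropped_rows": mart.dropped_rows,
            "dropped_columns": mart.dropped_columns,
        }, fh, indent=1)
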