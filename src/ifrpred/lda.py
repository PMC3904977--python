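"""Gaussian linear discriminant classifiers for interface prediction.

One LDA model per amino-acid type (plus an optional type-unspecific model):
class-conditional Gaussians with a pooled covariance, giving a linear
decision boundary and a calibrated posterior P(IFR | x) via Bayes' rule.
A :class:`ClassifierBundle` packages the 20 per-type models with their
retained-column lists, PCA projections, contact-energy maxima, and the
decision cutoff, and serializes to JSON for exact reload.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import PCAProjection, project

BUNDLE_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Raised when a model cannot be fit (e.g. single-class input)."""


@dataclass
class LDAModel:
    amino_acid_type: str       # three-letter code or "UNSPECIFIC"
    mean_ifr: np.ndarray
    mean_fsr: np.ndarray
    covariance: np.ndarray     # pooled within-class covariance
    prior_ifr: float
    ridge: float = 0.0

    @property
    def discriminant_direction(self) -> np.ndarray:
        """Σ⁻¹(μ_IFR − μ_FSR), the linear discriminant axis."""
        return np.linalg.solve(self.covariance,
                               self.mean_ifr - self.mean_fsr)

    def to_dict(self) -> dict:
        return {
            "amino_acid_type": self.amino_acid_type,
            "mean_ifr": self.mean_ifr.tolist(),
            "mean_fsr": self.mean_fsr.tolist(),
            "covariance": self.covariance.tolist(),
            "prior_ifr": self.prior_ifr,
            "ridge": self.ridge,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            amino_acid_type=d["amino_acid_type"],
            mean_ifr=np.asarray(d["mean_ifr"], dtype=float),
            mean_fsr=np.asarray(d["mean_fsr"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            prior_ifr=float(d["prior_ifr"]),
            ridge=float(d.get("ridge", 0.0)),
        )


def fit_lda(scores: np.ndarray, labels: np.ndarray,
            amino_acid_type: str = "UNSPECIFIC",
            ridge: float = 1e-6) -> LDAModel:
    """Fit a two-class LDA: per-class means, pooled within-class covariance,
    empirical class priors.

    Singular pooled covariance is diagonally regularized by ``ridge`` with
    a warning.  Single-class input raises :class:`TrainingError`.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) != {0, 1}:
        raise TrainingError(
            f"both classes required to fit {amino_acid_type} model")
    X1, X0 = X[y == 1], X[y == 0]
    mu1 = X1.mean(axis=0)
    mu0 = X0.mean(axis=0)
    n1, n0 = len(X1), len(X0)
    # pooled within-class covariance
    d1 = X1 - mu1
    d0 = X0 - mu0
    cov = (d1.T @ d1 + d0.T @ d0) / max(n1 + n0 - 2, 1)
    cov = np.atleast_2d(cov)
    applied_ridge = 0.0
    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        warnings.warn("singular pooled covariance; applying diagonal ridge")
        cov = cov + ridge * np.eye(cov.shape[0])
        applied_ridge = ridge
    return LDAModel(
        amino_acid_type=amino_acid_type,
        mean_ifr=mu1, mean_fsr=mu0, covariance=cov,
        prior_ifr=n1 / (n1 + n0), ridge=applied_ridge)


def posterior(model: LDAModel, x: np.ndarray) -> np.ndarray:
    """P(IFR | x) for one vector or a matrix of row vectors.

    Gaussian class-conditional likelihoods share the pooled covariance, so
    the log-odds are linear in x; the posterior is their logistic transform
    times the class priors.
    """
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    dim = model.mean_ifr.shape[0]
    if X.shape[1] != dim:
        raise ValueError(
            f"dimension mismatch: model expects {dim}, got {X.shape[1]}")
    w = model.discriminant_direction
    mid = 0.5 * (model.mean_ifr + model.mean_fsr)
    log_prior_odds = np.log(model.prior_ifr / (1.0 - model.prior_ifr))
    logit = (X - mid) @ w + log_prior_odds
    p = 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))
    return float(p[0]) if single else p


@dataclass
class TypeClassifier:
    """Everything needed to score one amino-acid type: the retained
    descriptor columns, the PCA projection, and the LDA model."""
    columns: list[str]
    projection: PCAProjection
    model: LDAModel

    def score(self, X: pd.DataFrame) -> np.ndarray:
        return posterior(self.model, project(self.projection, X[self.columns]))

    def to_dict(self) -> dict:
        return {"columns": self.columns,
                "projection": self.projection.to_dict(),
                "model": self.model.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "TypeClassifier":
        return cls(columns=list(d["columns"]),
                   projection=PCAProjection.from_dict(d["projection"]),
                   model=LDAModel.from_dict(d["model"]))


@dataclass
class ClassifierBundle:
    classifiers: dict[str, TypeClassifier]  # keyed by type or "UNSPECIFIC"
    max_table: dict[str, dict[str, float]]  # contact-energy maxima
    cutoff: float = 0.50
    seed: int | None = None
    provenance: dict = field(default_factory=dict)
    format_version: int = BUNDLE_FORMAT_VERSION

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie strictly inside (0, 1)")

    def model_for(self, amino_acid_type: str) -> TypeClassifier | None:
        return (self.classifiers.get(amino_acid_type)
                or self.classifiers.get("UNSPECIFIC"))

    def to_json(self) -> str:
        return json.dumps({
            "format_version": self.format_version,
            "cutoff": self.cutoff,
            "seed": self.seed,
            "provenance": self.provenance,
            "max_table": self.max_table,
            "classifiers": {k: v.to_dict()
                            for k, v in sorted(self.classifiers.items())},
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierBundle":
        d = json.loads(text)
        version = d.get("format_version")
        if version != BUNDLE_FORMAT_VERSION:
            raise ValueError(
                f"incompatible bundle format {version!r}; "
                f"this build reads version {BUNDLE_FORMAT_VERSION}")
        return cls(
            classifiers={k: TypeClassifier.from_dict(v)
                         for k, v in d["classifiers"].items()},
            max_table=d["max_table"],
            cutoff=float(d["cutoff"]),
            seed=d.get("seed"),
            provenance=d.get("provenance", {}),
        )


def predict_table(bundle: ClassifierBundle, rows: pd.DataFrame,
                  cutoff: float | None = None) -> pd.DataFrame:
    """Score a per-residue descriptor table (already including Unused_*
    columns) with the bundle.

    Input must carry ``_aa`` (residue type) and the descriptor columns; the
    output has P_IFR, predicted class, and a ``predicted`` flag (False when
    no model covers the type or a required descriptor is missing).
    """
    cut = bundle.cutoff if cutoff is None else cutoff
    p = np.full(len(rows), np.nan)
    predicted = np.zeros(len(rows), dtype=bool)
    for aa in rows["_aa"].unique():
        clf = bundle.model_for(aa)
        if clf is None:
            continue
        mask = (rows["_aa"] == aa).to_numpy()
        sub = rows.loc[mask, clf.columns]
        ok = ~sub.isna().any(axis=1).to_numpy()
        if not ok.any():
            continue
        scores = clf.score(sub.loc[ok])
        idx = np.flatnonzero(mask)[ok]
        p[idx] = scores
        predicted[idx] = True
    out = pd.DataFrame(index=rows.index)
    out["aa"] = rows["_aa"]
    out["P_IFR"] = p
    out["predicted"] = predicted
    out["predicted_class"] = np.where(
        ~predicted, "UNPREDICTED", np.where(p >= cut, "IFR", "FSR"))
    out["cutoff"] = cut
    return out


def aggregate(per_type_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine disjoint per-type prediction tables into a single table
    ordered by chain and residue number.  Duplicate residues are an
    integrity error; scores are never recalibrated across types."""
    if not per_type_tables:
        return pd.DataFrame()
    merged = pd.concat(per_type_tables, axis=0)
    if merged.index.duplicated().any():
        dupes = merged.index[merged.index.duplicated()].tolist()
        raise ValueError(f"duplicate residues in aggregation: {dupes[:5]!r}")
    return merged.sort_index()
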