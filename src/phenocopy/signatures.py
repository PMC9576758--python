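"""Training, locking, serializing and applying phenocopy signatures.

A phenocopy signature is a gradient-boosted tree classifier (hinge objective)
that predicts driver-gene mutation status from pathway-restricted, normalized
gene expression.  Depth and tree count are tuned by stratified k-fold
cross-validation scored with ROC AUC on pooled out-of-fold margins; the final
model is refit on all training data and locked.  Once locked, a signature is
immutable: prediction never changes its state, and the serialized form can be
hash-compared before and after any validation run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .prep import ExpressionMatrix

#: depth x tree-count grid explored by default
DEFAULT_GRID: tuple[tuple[int, int], ...] = tuple(
    (depth, n_trees) for depth in (2, 3, 4, 6) for n_trees in (50, 100, 200, 400)
)

_BASE_PARAMS = {
    "objective": "binary:hinge",
    "eta": 0.3,
    "tree_method": "hist",
    "nthread": 1,
}


class SignatureLockedError(RuntimeError):
    """Raised on any attempt to modify a locked signature."""


def pooled_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC of a score vector: the probability that a random positive
    outscores a random negative (ties count one half)."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))


@dataclass
class PhenocopySignature:
    pathway_name: str
    feature_genes: list[str]
    normalization_dialect: str
    booster: xgb.Booster
    tuned_depth: int
    tuned_n_trees: int
    cv_auc: float
    training_fingerprint: str
    cv_results: list[dict] = field(default_factory=list)
    objective: str = "binary:hinge"
    cv_score_pooling: str = "pooled_out_of_fold"
    locked: bool = True

    def __setattr__(self, name, value):
        # class-level default of ``locked`` must not trip the guard during init
        if self.__dict__.get("locked", False):
            raise SignatureLockedError(f"signature {self.pathway_name!r} is locked")
        super().__setattr__(name, value)

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        """Serialize as a directory: native model dump + JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(directory / "model.json"))
        meta = {
            "pathway_name": self.pathway_name,
            "feature_genes": self.feature_genes,
            "normalization_dialect": self.normalization_dialect,
            "tuned_depth": self.tuned_depth,
            "tuned_n_trees": self.tuned_n_trees,
            "cv_auc": self.cv_auc,
            "training_fingerprint": self.training_fingerprint,
            "cv_results": self.cv_results,
            "objective": self.objective,
            "cv_score_pooling": self.cv_score_pooling,
            "locked": self.locked,
        }
        (directory / "signature.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "PhenocopySignature":
        directory = Path(directory)
        meta = json.loads((directory / "signature.json").read_text())
        booster = xgb.Booster()
        booster.load_model(str(directory / "model.json"))
        return cls(booster=booster, **meta)


def cross_validated_auc(
    X: np.ndarray,
    y: np.ndarray,
    depth: int,
    n_trees_list: list[int],
    folds: int,
    seed: int,
    extra_params: dict | None = None,
) -> dict[int, float]:
    """Pooled out-of-fold ROC AUC for one tree depth at several tree counts.

    Each fold is trained once to the largest tree count; margins at smaller
    counts reuse the same ensemble's leading trees.
    """
    max_trees = max(n_trees_list)
    margins = {t: np.empty(y.size) for t in n_trees_list}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    params = {**_BASE_PARAMS, "max_depth": depth, "seed": seed, **(extra_params or {})}
    for train_idx, test_idx in skf.split(X, y):
        dtrain = xgb.DMatrix(X[train_idx], label=y[train_idx])
        dtest = xgb.DMatrix(X[test_idx])
        booster = xgb.train(params, dtrain, num_boost_round=max_trees)
        for t in n_trees_list:
            margins[t][test_idx] = booster.predict(
                dtest, output_margin=True, iteration_range=(0, t)
            )
    return {t: pooled_auc(y, margins[t]) for t in n_trees_list}


def train_signature(
    features: ExpressionMatrix,
    labels: pd.Series,
    pathway_name: str | None = None,
    grid: tuple[tuple[int, int], ...] = DEFAULT_GRID,
    folds: int = 10,
    seed: int = 0,
    extra_params: dict | None = None,
) -> PhenocopySignature:
    """Tune, fit and lock one phenocopy signature.

    ``features`` must already be pathway-restricted and normalized; ``labels``
    is the 0/1 mutation-status vector aligned to its samples.  The
    (depth, n_trees) pair with the best pooled out-of-fold AUC wins; ties go
    to fewer trees, then shallower trees.
    """
    labels = labels.reindex(features.samples)
    if labels.isna().any():
        raise ValueError("every sample in the feature matrix needs a label")
    y = labels.to_numpy().astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels are single-class; cannot train a classifier")
    if folds > counts.min():
        raise ValueError(
            f"{folds}-fold CV impossible with minority class of {counts.min()} samples"
        )
    X = features.values.to_numpy().T.astype(np.float32)  # samples x genes
    feature_genes = list(features.genes)

    by_depth: dict[int, list[int]] = {}
    for depth, n_trees in grid:
        by_depth.setdefault(int(depth), []).append(int(n_trees))
    cv_results = []
    for depth in sorted(by_depth):
        aucs = cross_validated_auc(X, y, depth, sorted(set(by_depth[depth])), folds, seed, extra_params)
        for n_trees, auc in aucs.items():
            cv_results.append({"depth": depth, "n_trees": n_trees, "auc": auc})
    # tie-break: smaller n_trees first, then smaller depth; strict improvement wins
    best = None
    for row in sorted(cv_results, key=lambda r: (r["n_trees"], r["depth"])):
        if best is None or row["auc"] > best["auc"]:
            best = row

    params = {**_BASE_PARAMS, "max_depth": best["depth"], "seed": seed, **(extra_params or {})}
    dtrain = xgb.DMatrix(X, label=y, feature_names=feature_genes)
    booster = xgb.train(params, dtrain, num_boost_round=best["n_trees"])

    fingerprint = hashlib.sha256()
    fingerprint.update(features.values.to_csv().encode())
    fingerprint.update(labels.to_csv().encode())
    fingerprint.update(json.dumps({"grid": sorted(grid), "folds": folds, "seed": seed}).encode())

    return PhenocopySignature(
        pathway_name=pathway_name or getattr(features, "pathway_name", "pathway"),
        feature_genes=feature_genes,
        normalization_dialect=features.normalization,
        booster=booster,
        tuned_depth=best["depth"],
        tuned_n_trees=best["n_trees"],
        cv_auc=best["auc"],
        training_fingerprint=fingerprint.hexdigest(),
        cv_results=cv_results,
        objective=params["objective"],
    )


def predict_phenocopy(
    signature: PhenocopySignature,
    matrix: ExpressionMatrix,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Apply a locked signature to new samples.

    Returns a frame indexed by sample with columns ``call`` (0/1, hinge margin
    thresholded at 0) and ``margin``.  The matrix must be normalized with the
    dialect registered in the signature.  Feature genes absent from the matrix
    are imputed at the mid-rank value 0.5 (neutral under rank normalization);
    more than ``max_missing_fraction`` missing is an error.
    """
    if matrix.normalization != signature.normalization_dialect:
        raise ValueError(
            f"matrix normalization {matrix.normalization!r} does not match the "
            f"signature's registered dialect {signature.normalization_dialect!r}"
        )
    present = [g for g in signature.feature_genes if g in set(matrix.genes)]
    missing_frac = 1.0 - len(present) / len(signature.feature_genes)
    if missing_frac > max_missing_fraction:
        raise ValueError(
            f"{missing_frac:.0%} of signature feature genes missing from matrix "
            f"(limit {max_missing_fraction:.0%})"
        )
    X = matrix.values.reindex(signature.feature_genes).T
    X = X.fillna(0.5).to_numpy().astype(np.float32)
    dmat = xgb.DMatrix(X, feature_names=signature.feature_genes)
    margin = signature.booster.predict(dmat, output_margin=True)
    return pd.DataFrame(
        {"call": (margin > 0).astype(int), "margin": margin.astype(float)},
        index=matrix.samples,
    )
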