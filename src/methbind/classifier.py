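"""Random-forest classifier over methylation scores and genomic features.

The class probability of a site is the fraction of trees voting "bound";
feature importance is Gini (mean impurity decrease); the tree count can be
chosen by out-of-bag error stability.  Trained models carry their feature
schema and the fitted methylation models so they can be saved and applied to
a different sample (cross-sample prediction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .meth_model import MethylationModel
from .scan import BOUND, UNBOUND

logger = logging.getLogger(__name__)

MODEL_FILE_VERSION = 1

DEFAULT_N_TREES = 500
DEFAULT_TREE_GRID = (100, 200, 500, 1000)
DEFAULT_STABILITY_TOL = 0.005


class SchemaMismatchError(ValueError):
    """Feature table does not match the schema the model was trained with."""


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    feature_schema: list[str]
    meth_models: dict[str, MethylationModel] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    version: int = MODEL_FILE_VERSION

    def __post_init__(self) -> None:
        if not self.feature_schema:
            raise ValueError("feature_schema must be non-empty")


def _as_binary_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        mapped = np.where(arr == BOUND, 1, np.where(arr == UNBOUND, 0, -1))
        if np.any(mapped < 0):
            bad = sorted(set(arr) - {BOUND, UNBOUND})
            raise ValueError(f"unrecognized labels: {bad}")
        return mapped.astype(int)
    return arr.astype(int)


def _check_schema(model: TrainedModel, features: pd.DataFrame) -> None:
    got = list(features.columns)
    if got != model.feature_schema:
        missing = [c for c in model.feature_schema if c not in got]
        extra = [c for c in got if c not in model.feature_schema]
        raise SchemaMismatchError(
            f"feature schema mismatch: missing {missing}, unexpected {extra}, "
            f"expected order {model.feature_schema}"
        )


def train_rf(
    features: pd.DataFrame,
    labels: Sequence,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    balanced: bool = False,
    meth_models: Mapping[str, MethylationModel] | None = None,
    metadata: Mapping | None = None,
) -> TrainedModel:
    """Fit the random forest; deterministic given (data, seed, n_trees).

    Uses sqrt(#features) candidate features per split and stores the
    out-of-bag error estimate in the metadata.  ``balanced`` switches on
    class-balanced sample weighting within each bootstrap (off by default).
    """
    y = _as_binary_labels(labels)
    if len(y) != len(features):
        raise ValueError("features and labels must be parallel")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        class_weight="balanced_subsample" if balanced else None,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # tiny training sets can leave some rows never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        forest.fit(features.to_numpy(), y)
    meta = dict(metadata or {})
    meta.update(
        seed=seed,
        n_trees=n_trees,
        balanced=balanced,
        max_features="sqrt",
        oob_error=float(1.0 - forest.oob_score_),
        class_counts={"unbound": int((y == 0).sum()), "bound": int((y == 1).sum())},
    )
    return TrainedModel(
        forest=forest,
        feature_schema=list(features.columns),
        meth_models=dict(meth_models or {}),
        metadata=meta,
    )


def select_n_trees(
    features: pd.DataFrame,
    labels: Sequence,
    grid: Sequence[int] = DEFAULT_TREE_GRID,
    stability_tol: float = DEFAULT_STABILITY_TOL,
    seed: int = 0,
) -> int:
    """Choose the tree count by out-of-bag error stability.

    Returns the smallest grid value whose OOB error differs from the next
    grid value's by less than ``stability_tol``; if the curve never
    stabilizes, the grid maximum is returned with a warning.  A length-1
    grid short-circuits to its only value.
    """
    grid = list(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    if len(grid) == 1:
        return grid[0]
    oob = [
        train_rf(features, labels, n_trees=n, seed=seed).metadata["oob_error"]
        for n in grid
    ]
    for i in range(len(grid) - 1):
        if abs(oob[i] - oob[i + 1]) < stability_tol:
            return grid[i]
    warnings.warn(
        f"out-of-bag error did not stabilize within {stability_tol}; "
        f"using the grid maximum {grid[-1]}",
        stacklevel=2,
    )
    return grid[-1]


def predict_proba(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Per-site probability of binding: the fraction of trees voting "bound"."""
    _check_schema(model, features)
    proba = model.forest.predict_proba(features.to_numpy())
    bound_col = list(model.forest.classes_).index(1)
    return proba[:, bound_col]


def gini_importance(model: TrainedModel) -> pd.Series:
    """Gini (mean impurity decrease) importance per feature, summing to 1."""
    return pd.Series(
        model.forest.feature_importances_, index=model.feature_schema, name="gini_importance"
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "version": model.version,
        "feature_schema": model.feature_schema,
        "meth_models": {ctx: mm.to_dict() for ctx, mm in model.meth_models.items()},
        "metadata": model.metadata,
        "forest": model.forest,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("version")
    if version != MODEL_FILE_VERSION:
        raise ValueError(f"unsupported model file version {version!r}")
    return TrainedModel(
        forest=payload["forest"],
        feature_schema=list(payload["feature_schema"]),
        meth_models={
            ctx: MethylationModel.from_dict(d)
            for ctx, d in payload["meth_models"].items()
        },
        metadata=dict(payload["metadata"]),
        version=version,
    )
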