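"""Per-element charge regression: training, prediction, and evaluation.

One regressor is fitted per chemical element, mapping the 61-feature
atom encoding to a partial charge in units of e.  Supported model
families are random forests (500 trees), distance-weighted k-nearest
neighbors (k = 7, Minkowski order 2) and ordinary least squares.
Evaluation reports RMSE, range-normalized RMSE (percent) and R²
(squared Pearson correlation; the coefficient of determination is
exposed alongside).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor

from .atomfeat import FEATURE_SCHEMA, FeatureTable, schema_hash

__all__ = [
    "DEFAULT_HYPERPARAMS",
    "MIN_TRAINING_ROWS",
    "DatasetSplit",
    "ElementModel",
    "EvalMetrics",
    "split_dataset",
    "train_element_model",
    "train_all_elements",
    "predict_charges",
    "rmse",
    "nrmse",
    "r_squared",
    "r_squared_cod",
    "evaluate",
    "save_models",
    "load_models",
]

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "random_forest": {"n_trees": 500},
    "knn": {"k": 7, "minkowski_p": 2},
    "linear": {},
}

#: Fewest labeled atoms an element needs before a model is fitted.
MIN_TRAINING_ROWS = 10


@dataclass(frozen=True)
class DatasetSplit:
    """Reproducible train/test partition of row indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    p_train: float
    seed: int

    def __post_init__(self) -> None:
        train, test = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")


def split_dataset(n: int, p_train: float = 0.2, seed: int = 0) -> DatasetSplit:
    """Uniform random split; the default ``p_train = 0.2`` reads the
    1:4 train:test ratio literally."""
    if n < 5:
        raise ValueError(f"dataset of {n} rows is too small to split (need >= 5)")
    if not 0.0 < p_train < 1.0:
        raise ValueError("p_train must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = math.ceil(n * p_train)
    return DatasetSplit(np.sort(perm[:n_train]), np.sort(perm[n_train:]), p_train, seed)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _make_estimator(algorithm: str, hyperparams: dict, seed: int):
    if algorithm == "random_forest":
        return RandomForestRegressor(
            n_estimators=int(hyperparams.get("n_trees", 500)),
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "knn":
        return KNeighborsRegressor(
            n_neighbors=int(hyperparams.get("k", 7)),
            p=int(hyperparams.get("minkowski_p", 2)),
            weights="distance",
        )
    if algorithm == "linear":
        return LinearRegression()
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class ElementModel:
    """A fitted regressor for one element, pinned to a feature schema."""

    element: str
    algorithm: str
    hyperparams: dict
    estimator: object
    schema_hash: str
    seed: int
    n_training_rows: int = 0

    def predict(self, table: FeatureTable) -> np.ndarray:
        if schema_hash(table.schema) != self.schema_hash:
            raise ValueError(
                f"feature schema mismatch for {self.element} model: "
                f"table hash {schema_hash(table.schema)} != model hash {self.schema_hash}"
            )
        return np.asarray(self.estimator.predict(table.features()), dtype=float)


def train_element_model(table: FeatureTable, element: str,
                        algorithm: str = "random_forest",
                        hyperparams: dict | None = None,
                        seed: int = 0) -> ElementModel:
    """Fit one regressor on the labeled rows of a single element."""
    if not table.has_labels:
        raise ValueError("training requires a labeled feature table")
    sub = table.rows_for(element)
    if sub.n_rows < MIN_TRAINING_ROWS:
        raise ValueError(
            f"element {element}: only {sub.n_rows} labeled rows "
            f"(need >= {MIN_TRAINING_ROWS})"
        )
    params = dict(DEFAULT_HYPERPARAMS.get(algorithm, {}))
    if algorithm not in DEFAULT_HYPERPARAMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if hyperparams:
        params.update(hyperparams)
    est = _make_estimator(algorithm, params, seed)
    est.fit(sub.features(), sub.labels())
    return ElementModel(element, algorithm, params, est,
                        schema_hash(table.schema), seed, sub.n_rows)


def train_all_elements(table: FeatureTable, algorithm: str = "random_forest",
                       hyperparams: dict | None = None, seed: int = 0,
                       min_rows: int = MIN_TRAINING_ROWS) -> dict[str, ElementModel]:
    """Fit a model for every element with at least ``min_rows`` labeled rows."""
    models: dict[str, ElementModel] = {}
    for element in sorted(set(table.elements)):
        if (table.elements == element).sum() >= min_rows:
            models[element] = train_element_model(table, element, algorithm,
                                                  hyperparams, seed)
    if not models:
        raise ValueError("no element has enough labeled rows to train")
    return models


def predict_charges(models: dict[str, ElementModel], table: FeatureTable) -> np.ndarray:
    """Route every row to its element's model; output aligned to row order."""
    elements = table.elements
    missing = sorted(set(elements) - set(models))
    if missing:
        raise ValueError(f"no model for element(s): {', '.join(missing)}")
    out = np.empty(table.n_rows)
    for element, model in models.items():
        mask = elements == element
        if mask.any():
            out[mask] = model.predict(table.subset(np.flatnonzero(mask)))
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    return y_true, y_pred


def rmse(y_true, y_pred) -> float:
    """Root mean square error, in units of e."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def nrmse(y_true, y_pred) -> float:
    """RMSE normalized by the range of the true charges, in percent."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    rng = float(np.max(y_true) - np.min(y_true))
    if rng == 0.0:
        raise ValueError("NRMSE undefined: y_true has zero range")
    return rmse(y_true, y_pred) / rng * 100.0


def r_squared(y_true, y_pred) -> float:
    """Squared Pearson correlation between truth and prediction."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if y_true.size < 2:
        raise ValueError("R^2 requires at least 2 points")
    if np.ptp(y_true) == 0.0 or np.ptp(y_pred) == 0.0:
        raise ValueError("R^2 undefined for constant input")
    r = np.corrcoef(y_true, y_pred)[0, 1]
    return float(r * r)


def r_squared_cod(y_true, y_pred) -> float:
    """Coefficient of determination (1 - SS_res/SS_tot); companion
    definition to the Pearson-based :func:`r_squared`."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    ss_tot = float(np.sum((y_true - np.mean(y_true)) ** 2))
    if ss_tot == 0.0:
        raise ValueError("coefficient of determination undefined for constant y_true")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


@dataclass
class EvalMetrics:
    rmse: float
    nrmse: float
    r2: float
    r2_cod: float = float("nan")
    n: int = 0


def evaluate(models: dict[str, ElementModel], table: FeatureTable,
             split: DatasetSplit) -> dict[str, EvalMetrics]:
    """Held-out metrics per element plus the unweighted cross-element
    mean row (keyed ``"mean"``).  Elements absent from the test rows,
    or degenerate there, are omitted."""
    if not table.has_labels:
        raise ValueError("evaluation requires labels")
    test = table.subset(split.test_indices)
    results: dict[str, EvalMetrics] = {}
    for element in sorted(models):
        mask = test.elements == element
        if not mask.any():
            continue
        sub = test.subset(np.flatnonzero(mask))
        y_true = sub.labels()
        if np.ptp(y_true) == 0.0:
            continue
        y_pred = models[element].predict(sub)
        results[element] = EvalMetrics(
            rmse=rmse(y_true, y_pred),
            nrmse=nrmse(y_true, y_pred),
            r2=r_squared(y_true, y_pred),
            r2_cod=r_squared_cod(y_true, y_pred),
            n=int(mask.sum()),
        )
    if results:
        results["mean"] = EvalMetrics(
            rmse=float(np.mean([m.rmse for m in results.values()])),
            nrmse=float(np.mean([m.nrmse for m in results.values()])),
            r2=float(np.mean([m.r2 for m in results.values()])),
            r2_cod=float(np.mean([m.r2_cod for m in results.values()])),
            n=sum(m.n for m in results.values()),
        )
    return results


# ---------------------------------------------------------------------------
# Persistence: JSON manifest + one joblib payload per element
# ---------------------------------------------------------------------------

def save_models(models: dict[str, ElementModel], directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"models": {}}
    for element, m in sorted(models.items()):
        payload = f"{element}.joblib"
        joblib.dump(m.estimator, directory / payload)
        manifest["models"][element] = {
            "element": m.element,
            "algorithm": m.algorithm,
            "hyperparams": m.hyperparams,
            "schema_hash": m.schema_hash,
            "seed": m.seed,
            "n_training_rows": m.n_training_rows,
            "payload": payload,
        }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def load_models(directory) -> dict[str, ElementModel]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    models: dict[str, ElementModel] = {}
    for element, meta in manifest["models"].items():
        if meta["schema_hash"] != schema_hash(FEATURE_SCHEMA):
            raise ValueError(
                f"model bundle for {element} was trained under a different "
                f"feature schema ({meta['schema_hash']})"
            )
        estimator = joblib.load(directory / meta["payload"])
        models[element] = ElementModel(
            element=meta["element"],
            algorithm=meta["algorithm"],
            hyperparams=meta["hyperparams"],
            estimator=estimator,
            schema_hash=meta["schema_hash"],
            seed=meta["seed"],
            n_training_rows=meta["n_training_rows"],
        )
    return models
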