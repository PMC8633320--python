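"""Ensemble regression of fused fungal severity from sepal spectral features.

Each sepal is a feature vector made of its per-band mean spectrum and per-band
spectral standard deviation; the target is the panel-fused severity grade.
Random Forest and gradient-boosted-tree (XGBoost) regressors are tuned by
exhaustive grid search maximizing mean cross-validated R2 under one of two
schemes — shuffled 10-fold, or group k-fold with tomato batches as groups so
no batch straddles a fold — refit on the full training set and scored on a
held-out test split.  The experiment repeats over several random 80/20
splits.  Sepal predictions are averaged per tomato for fruit-level
correlation.  Interpretation is impurity-based global feature importance plus
exact TreeSHAP attributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold, KFold, GridSearchCV, train_test_split

from ._treeshap import tree_shap_values
from .sepals import SepalRecord

__all__ = [
    "ModelConfig",
    "ModelReport",
    "FeatureMatrix",
    "split_train_test",
    "tune_and_fit",
    "evaluate",
    "aggregate_to_tomato",
    "global_importance",
    "shap_explain",
    "restrict_wavelengths",
    "run_experiment",
    "DEFAULT_GRIDS",
]

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {
        "n_estimators": [200, 500],
        "max_depth": [None, 10],
        "max_features": ["sqrt", 0.33],
    },
    "xgb": {
        "n_estimators": [200, 500],
        "max_depth": [3, 6],
        "learning_rate": [0.05, 0.1],
    },
}


@dataclass(frozen=True)
class ModelConfig:
    """Algorithm, CV scheme and split policy for one severity-model experiment."""

    algorithm: str = "rf"
    cv_scheme: str = "kfold10"
    test_fraction: float = 0.2
    n_repeats: int = 5
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("rf", "xgb"):
            raise ValueError(f"algorithm must be 'rf' or 'xgb', got {self.algorithm!r}")
        if self.cv_scheme not in ("kfold10", "groupkfold"):
            raise ValueError(f"cv_scheme must be 'kfold10' or 'groupkfold', got {self.cv_scheme!r}")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")

    def resolved_grid(self) -> dict[str, list]:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.algorithm]


@dataclass
class FeatureMatrix:
    """Design matrix plus the per-column wavelength/family metadata.

    Columns are the mean spectrum followed by the std spectrum, each labeled
    ``mean_<nm>`` / ``std_<nm>``.
    """

    X: np.ndarray
    y: np.ndarray
    sepal_ids: np.ndarray
    batches: np.ndarray
    feature_names: list[str]
    feature_wavelengths: np.ndarray
    feature_family: np.ndarray  # "mean" or "std" per column

    @classmethod
    def from_records(cls, records: list[SepalRecord], wavelengths: np.ndarray) -> "FeatureMatrix":
        if not records:
            raise ValueError("no sepal records")
        if any(r.severity is None for r in records):
            raise ValueError("records lack fused severities; run grade fusion first")
        wavelengths = np.asarray(wavelengths, dtype=float)
        X = np.stack([np.concatenate([r.mean_spectrum, r.std_spectrum]) for r in records])
        names = [f"mean_{w:.0f}" for w in wavelengths] + [f"std_{w:.0f}" for w in wavelengths]
        return cls(
            X=X,
            y=np.array([r.severity for r in records], dtype=float),
            sepal_ids=np.array([r.sepal_id for r in records]),
            batches=np.array([r.batch for r in records]),
            feature_names=names,
            feature_wavelengths=np.concatenate([wavelengths, wavelengths]),
            feature_family=np.array(["mean"] * len(wavelengths) + ["std"] * len(wavelengths)),
        )

    @property
    def tomato_ids(self) -> np.ndarray:
        return np.array([s[:3] for s in self.sepal_ids])


@dataclass
class ModelReport:
    """Everything one experiment produced: config, metrics, importances, SHAP."""

    config: dict
    cv_metrics: list[dict]  # one dict per repeat: mean fold rmse/r2/pearson
    test_metrics: list[dict]  # one dict per repeat
    best_params: list[dict]
    tomato_pearson: float
    feature_importances: dict[str, float]
    shap_baseline: float
    shap_values: np.ndarray | None = None
    shap_feature_names: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        """Mean and sd of each metric over the repeats."""
        out: dict[str, float] = {}
        for stage, metrics in (("cv", self.cv_metrics), ("test", self.test_metrics)):
            for key in ("rmse", "r2", "pearson"):
                vals = np.array([m[key] for m in metrics])
                out[f"{stage}_{key}_mean"] = float(vals.mean())
                out[f"{stage}_{key}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out["tomato_pearson"] = self.tomato_pearson
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "config": self.config,
            "cv_metrics": self.cv_metrics,
            "test_metrics": self.test_metrics,
            "best_params": self.best_params,
            "summary": self.summary(),
            "tomato_pearson": self.tomato_pearson,
            "feature_importances": self.feature_importances,
            "shap_baseline": self.shap_baseline,
            "shap_values": None if self.shap_values is None else self.shap_values.tolist(),
            "shap_feature_names": self.shap_feature_names,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def make_estimator(algorithm: str, seed: int):
    """A fresh single-threaded, seeded estimator of the requested family."""
    if algorithm == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    if algorithm == "xgb":
        from xgboost import XGBRegressor

        return XGBRegressor(
            random_state=seed, n_jobs=1, tree_method="hist", verbosity=0, base_score=0.5
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def split_train_test(
    n_samples: int, cfg: ModelConfig, repeat: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint, exhaustive train/test index split for one repeat."""
    if n_samples < 20:
        raise ValueError(f"need at least 20 records to split, got {n_samples}")
    train_idx, test_idx = train_test_split(
        np.arange(n_samples),
        test_size=cfg.test_fraction,
        random_state=cfg.seed * 97 + repeat,
        shuffle=True,
    )
    return np.sort(train_idx), np.sort(test_idx)


def _make_cv(cfg: ModelConfig, groups: np.ndarray | None, repeat: int = 0):
    if cfg.cv_scheme == "kfold10":
        return KFold(n_splits=10, shuffle=True, random_state=cfg.seed * 131 + repeat), None
    if groups is None:
        raise ValueError("groupkfold requires batch labels as groups")
    n_groups = np.unique(groups).size
    if n_groups < 2:
        raise ValueError("groupkfold needs at least 2 batches")
    return GroupKFold(n_splits=n_groups), groups


def tune_and_fit(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ModelConfig,
    groups: np.ndarray | None = None,
    repeat: int = 0,
):
    """Exhaustive grid search maximizing mean CV R2, then refit on all of X.

    Returns (fitted best estimator, cv_metrics dict, best_params dict).  The
    CV metrics are those of the winning parameter set, averaged over folds.
    """
    if np.ptp(y) == 0:
        raise ValueError("severity target is constant; R2 undefined")
    cv, cv_groups = _make_cv(cfg, groups, repeat)
    search = GridSearchCV(
        make_estimator(cfg.algorithm, cfg.seed),
        param_grid=cfg.resolved_grid(),
        scoring={"r2": "r2", "nrmse": "neg_root_mean_squared_error"},
        refit="r2",
        cv=cv,
        n_jobs=1,
    )
    search.fit(X, y, groups=cv_groups)

    res = search.cv_results_
    i = search.best_index_
    cv_metrics = {
        "r2": float(res["mean_test_r2"][i]),
        "rmse": float(-res["mean_test_nrmse"][i]),
        "pearson": _cv_pearson(search.best_estimator_, X, y, cv, cv_groups, cfg),
    }
    return search.best_estimator_, cv_metrics, dict(search.best_params_)


def _cv_pearson(estimator, X, y, cv, groups, cfg: ModelConfig) -> float:
    """Mean per-fold Pearson correlation for the winning parameter set."""
    from sklearn.base import clone

    rs = []
    for train, valid in cv.split(X, y, groups):
        est = clone(estimator)
        est.fit(X[train], y[train])
        pred = est.predict(X[valid])
        if np.ptp(pred) == 0 or np.ptp(y[valid]) == 0:
            rs.append(0.0)
            continue
        rs.append(pearsonr(y[valid], pred).statistic)
    return float(np.mean(rs))


def evaluate(model, X: np.ndarray, y: np.ndarray) -> dict:
    """RMSE, R2 and Pearson correlation of the model on (X, y).

    Constant predictions leave Pearson undefined; it is reported as 0.0 with
    ``pearson_defined`` set False (R2 is still well defined).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 records to evaluate")
    pred = np.asarray(model.predict(X), dtype=float)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    defined = np.ptp(pred) > 0 and np.ptp(y) > 0
    pearson = float(pearsonr(y, pred).statistic) if defined else 0.0
    return {"rmse": rmse, "r2": r2, "pearson": pearson, "pearson_defined": bool(defined)}


def aggregate_to_tomato(
    sepal_ids: np.ndarray, y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Average sepal truths and predictions per tomato; return the table and Pearson r.

    A sepal id's first three digits (batch, truss, tomato) identify its fruit.
    """
    frame = pd.DataFrame(
        {
            "tomato_id": [str(s)[:3] for s in sepal_ids],
            "true": np.asarray(y_true, dtype=float),
            "pred": np.asarray(y_pred, dtype=float),
        }
    )
    per_tomato = frame.groupby("tomato_id", as_index=False).mean(numeric_only=True)
    if len(per_tomato) < 2 or np.ptp(per_tomato["pred"]) == 0:
        return per_tomato, 0.0
    r = float(pearsonr(per_tomato["true"], per_tomato["pred"]).statistic)
    return per_tomato, r


def global_importance(model, feature_names: list[str]) -> dict[str, float]:
    """Impurity-based feature importances, normalized to sum to 1."""
    imp = np.asarray(model.feature_importances_, dtype=float)
    if imp.size != len(feature_names):
        raise ValueError("importance length does not match feature names")
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return dict(zip(feature_names, imp.tolist()))


def shap_explain(
    model, X: np.ndarray, feature_names: list[str], top_k: int = 10
) -> tuple[np.ndarray, float, list[list[tuple[str, float]]]]:
    """Exact TreeSHAP attributions plus per-instance ranked explanations.

    Returns (shap matrix, baseline, per-sample list of the ``top_k``
    (feature, signed contribution) pairs sorted by |contribution| —
    positive pushes the predicted severity up, negative down).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_names):
        raise ValueError(
            f"X has {X.shape[1]} features but {len(feature_names)} names were given"
        )
    shap_matrix, baseline = tree_shap_values(model, X)
    explanations = []
    for row in shap_matrix:
        order = np.argsort(-np.abs(row))[:top_k]
        explanations.append([(feature_names[j], float(row[j])) for j in order])
    return shap_matrix, baseline, explanations


def restrict_wavelengths(
    features: FeatureMatrix, lo: float = 1390.0, hi: float = 1420.0
) -> FeatureMatrix:
    """Restrict the design matrix to feature columns with wavelength in [lo, hi]."""
    sel = (features.feature_wavelengths >= lo) & (features.feature_wavelengths <= hi)
    if not sel.any():
        raise ValueError(f"no feature wavelengths inside [{lo}, {hi}] nm")
    return FeatureMatrix(
        X=features.X[:, sel],
        y=features.y,
        sepal_ids=features.sepal_ids,
        batches=features.batches,
        feature_names=[n for n, s in zip(features.feature_names, sel) if s],
        feature_wavelengths=features.feature_wavelengths[sel],
        feature_family=features.feature_family[sel],
    )


def run_experiment(
    features: FeatureMatrix,
    cfg: ModelConfig,
    shap_samples: int | None = 40,
) -> ModelReport:
    """Repeated 80/20 splits: tune, refit, test; aggregate; explain.

    Tomato-level correlation pools the held-out predictions of every repeat
    (each tomato averaged over all its predicted sepals).  Importances and
    SHAP come from the last repeat's best model, SHAP evaluated on (at most
    ``shap_samples`` of) its training samples.
    """
    X, y = features.X, features.y
    cv_list, test_list, params_list = [], [], []
    pooled_ids, pooled_true, pooled_pred = [], [], []
    model = None
    train_idx = np.arange(len(y))
    for repeat in range(cfg.n_repeats):
        train_idx, test_idx = split_train_test(len(y), cfg, repeat)
        groups = features.batches[train_idx] if cfg.cv_scheme == "groupkfold" else None
        model, cv_metrics, best_params = tune_and_fit(
            X[train_idx], y[train_idx], cfg, groups=groups, repeat=repeat
        )
        cv_list.append(cv_metrics)
        params_list.append(best_params)
        test_list.append(evaluate(model, X[test_idx], y[test_idx]))
        pooled_ids.extend(features.sepal_ids[test_idx])
        pooled_true.extend(y[test_idx])
        pooled_pred.extend(model.predict(X[test_idx]))

    _, tomato_r = aggregate_to_tomato(
        np.array(pooled_ids), np.array(pooled_true), np.array(pooled_pred)
    )
    importances = global_importance(model, features.feature_names)
    shap_X = X[train_idx]
    if shap_samples is not None and shap_X.shape[0] > shap_samples:
        rng = np.random.default_rng(cfg.seed)
        shap_X = shap_X[rng.choice(shap_X.shape[0], shap_samples, replace=False)]
    shap_matrix, baseline, _ = shap_explain(model, shap_X, features.feature_names)
    return ModelReport(
        config={
            "algorithm": cfg.algorithm,
            "cv_scheme": cfg.cv_scheme,
            "test_fraction": cfg.test_fraction,
            "n_repeats": cfg.n_repeats,
            "grid": cfg.resolved_grid(),
            "seed": cfg.seed,
        },
        cv_metrics=cv_list,
        test_metrics=test_list,
        best_params=params_list,
        tomato_pearson=tomato_r,
        feature_importances=importances,
        shap_baseline=baseline,
        shap_values=shap_matrix,
        shap_feature_names=features.feature_names,
    )
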