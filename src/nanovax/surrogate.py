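"""Random-forest surrogate for the delta-AUC objective.

The forest regresses delta-AUC on the four formulation features in the
fixed order (size_nm, charge_mV, peg_molpct, targeting). It is trained on
an 80/20 split of the synthetic formulation dataset, evaluated by RMSE and
R^2 on the held-out part, interpreted via impurity-based feature
importances, and its sampling variability is profiled by refitting on
bootstrap resamples (B = 500 by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ._seeds import stage_rng, stage_seed
from .lnp_space import FEATURES, LNPDataset

__all__ = [
    "DEFAULT_HYPERPARAMS",
    "SurrogateModel",
    "SurrogateMetrics",
    "split_dataset",
    "train_rf",
    "evaluate",
    "feature_importance",
    "bootstrap_predictions",
    "save_model",
    "load_model",
]

DEFAULT_HYPERPARAMS = {"n_trees": 500, "min_leaf": 2, "max_depth": None}


@dataclass
class SurrogateModel:
    forest: RandomForestRegressor
    seed: int
    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))
    feature_names: tuple[str, ...] = FEATURES
    n_train: int = 0

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        return self.forest.predict(np.asarray(X, dtype=float))


@dataclass(frozen=True)
class SurrogateMetrics:
    rmse: float
    r2: float | None  # None when the validation target has zero variance
    n_train: int
    n_valid: int


def _frame(dataset: LNPDataset | pd.DataFrame) -> pd.DataFrame:
    return dataset.frame if isinstance(dataset, LNPDataset) else dataset


def split_dataset(
    dataset: LNPDataset | pd.DataFrame, train_frac: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/validation split by seeded shuffle.

    Train size is floor(train_frac * n); the remainder validates.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    frame = _frame(dataset)
    if len(frame) < 5:
        raise ValueError("dataset too small to split")
    rng = stage_rng(seed, "surrogate/split")
    perm = rng.permutation(len(frame))
    n_train = int(np.floor(train_frac * len(frame)))
    train = frame.iloc[perm[:n_train]]
    valid = frame.iloc[perm[n_train:]]
    return train, valid


def train_rf(
    train: pd.DataFrame,
    n_trees: int = 500,
    min_leaf: int = 2,
    max_depth: int | None = None,
    seed: int = 0,
) -> SurrogateModel:
    """Fit the regression forest on a training frame with a delta_auc column."""
    if len(train) < 10:
        raise ValueError("need at least 10 training rows")
    y = train["delta_auc"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        warnings.warn("degenerate single-valued target; forest predicts a constant", UserWarning)
    X = train.loc[:, list(FEATURES)].to_numpy(dtype=float)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=min_leaf,
        max_depth=max_depth,
        random_state=stage_seed(seed, "surrogate/train"),
        n_jobs=1,
    )
    forest.fit(X, y)
    return SurrogateModel(
        forest=forest,
        seed=seed,
        hyperparams={"n_trees": n_trees, "min_leaf": min_leaf, "max_depth": max_depth},
        n_train=len(train),
    )


def evaluate(model: SurrogateModel, valid: pd.DataFrame) -> SurrogateMetrics:
    """Held-out RMSE and coefficient of determination."""
    if len(valid) == 0:
        raise ValueError("validation set is empty")
    y = valid["delta_auc"].to_numpy(dtype=float)
    yhat = model.predict(valid)
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance validation target; R^2 undefined", UserWarning)
        r2 = None
    else:
        r2 = float(1.0 - np.sum((yhat - y) ** 2) / ss_tot)
    return SurrogateMetrics(rmse=rmse, r2=r2, n_train=model.n_train, n_valid=len(valid))


def feature_importance(model: SurrogateModel) -> pd.Series:
    """Impurity-based importances in fixed feature order, normalized to sum 1."""
    imp = np.asarray(model.forest.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=list(model.feature_names), name="importance")


def bootstrap_predictions(
    dataset: LNPDataset | pd.DataFrame,
    B: int = 500,
    seed: int = 0,
    level: float = 0.95,
    n_trees: int = 100,
    min_leaf: int = 2,
) -> pd.DataFrame:
    """Prediction variability across B forests refitted on bootstrap resamples.

    Each refit resamples the full dataset with replacement and predicts all
    original rows; the table reports per-row mean, SD and percentile CI of
    those predictions. The refits use a lighter forest (100 trees) than the
    production surrogate since only the spread matters.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B == 1:
        warnings.warn("B=1 bootstrap: reported SD is zero by construction", UserWarning)
    frame = _frame(dataset).reset_index(drop=True)
    X_all = frame.loc[:, list(FEATURES)].to_numpy(dtype=float)
    y = frame["delta_auc"].to_numpy(dtype=float)
    rng = stage_rng(seed, "surrogate/bootstrap")
    n = len(frame)
    preds = np.empty((B, n))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            min_samples_leaf=min_leaf,
            random_state=int(rng.integers(0, 2**31)),
            n_jobs=1,
        )
        forest.fit(X_all[idx], y[idx])
        preds[b] = forest.predict(X_all)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    ci = np.percentile(preds, [lo_q, hi_q], axis=0)
    return pd.DataFrame(
        {
            "pred_mean": preds.mean(axis=0),
            "pred_sd": preds.std(axis=0, ddof=0),
            "ci_low": ci[0],
            "ci_high": ci[1],
        },
        index=frame.index,
    )


def save_model(model: SurrogateModel, out_dir: str | Path) -> dict[str, Path]:
    """Persist the forest (joblib binary) with a JSON sidecar of metadata."""
    import joblib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_path = out / "surrogate.joblib"
    sidecar_path = out / "surrogate.json"
    joblib.dump(model.forest, model_path)
    sidecar_path.write_text(
        json.dumps(
            {
                "seed": model.seed,
                "hyperparams": model.hyperparams,
                "feature_names": list(model.feature_names),
                "n_train": model.n_train,
            },
            indent=2,
        )
    )
    return {"model": model_path, "sidecar": sidecar_path}


def load_model(in_dir: str | Path) -> SurrogateModel:
    import joblib

    indir = Path(in_dir)
    forest = joblib.load(indir / "surrogate.joblib")
    meta = json.loads((indir / "surrogate.json").read_text())
    return SurrogateModel(
        forest=forest,
        seed=meta["seed"],
        hyperparams=meta["hyperparams"],
        feature_names=tuple(meta["feature_names"]),
        n_train=meta["n_train"],
    )
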