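"""Feed-forward binding-affinity regressors on latent features.

One regressor per protein target maps a molecule's latent vector to its
binding free energy ΔG (kcal/mol). The network is a fully connected
multilayer perceptron with three hidden layers of 512, 1024 and 512
rectifier units, trained with the Adam optimizer at batch size 16 under a
two-phase learning-rate schedule — 1e-4 for the first half of the epochs,
1e-5 for the remainder (1000 epochs total by default) — minimizing mean
squared error. Model quality is reported as k-fold cross-validated Pearson
correlation (R) and RMSE, both per fold and pooled over the concatenated
out-of-fold predictions.

The estimator is scikit-learn compatible (``fit``/``predict``,
``get_params``/``set_params``) and composes with sklearn model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted, validate_data

from sgnc.codec import MoleculeRecord
from sgnc.exceptions import ConfigError, DataError


@dataclass
class PredictorConfig:
    """Training hyperparameters for one affinity regressor.

    ``lr_schedule`` is a list of (n_epochs, learning_rate) phases executed in
    order; None derives the default two-phase schedule (first half at 1e-4,
    second half at 1e-5) from ``epochs``.
    """

    hidden_sizes: tuple[int, int, int] = (512, 1024, 512)
    epochs: int = 1000
    lr_schedule: list[tuple[int, float]] | None = None
    batch_size: int = 16
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be a positive integer")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be a positive integer")
        if self.lr_schedule is None:
            first = self.epochs // 2
            self.lr_schedule = [(first, 1e-4), (self.epochs - first, 1e-5)]
            if first == 0:
                self.lr_schedule = [(self.epochs, 1e-4)]
        total = sum(n for n, _ in self.lr_schedule)
        if total != self.epochs:
            raise ConfigError(
                f"lr_schedule phases cover {total} epochs but epochs={self.epochs}"
            )
        if any(n < 1 or lr <= 0 for n, lr in self.lr_schedule):
            raise ConfigError("each schedule phase needs n_epochs >= 1 and lr > 0")


class AffinityRegressor(RegressorMixin, BaseEstimator):
    """MLP regressor from latent vectors to ΔG with a phased learning rate.

    Parameters mirror :class:`PredictorConfig`. Deterministic given
    ``random_state``: the same seed and data yield identical predictions.

    Attributes
    ----------
    model_ : MLPRegressor
        The fitted underlying network.
    n_features_in_ : int
        Latent dimension seen during fit.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (512, 1024, 512),
        epochs: int = 1000,
        lr_schedule: list[tuple[int, float]] | None = None,
        batch_size: int = 16,
        activation: str = "relu",
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.epochs = epochs
        self.lr_schedule = lr_schedule
        self.batch_size = batch_size
        self.activation = activation
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        if not np.all(np.isfinite(y)):
            raise DataError("affinity labels contain NaN or infinite values")
        cfg = PredictorConfig(
            hidden_sizes=tuple(self.hidden_sizes),
            epochs=self.epochs,
            lr_schedule=None if self.lr_schedule is None else list(self.lr_schedule),
            batch_size=self.batch_size,
            activation=self.activation,
            seed=self.random_state,
        )
        phases = cfg.lr_schedule
        model = MLPRegressor(
            hidden_layer_sizes=cfg.hidden_sizes,
            activation=cfg.activation,
            solver="adam",
            batch_size=min(cfg.batch_size, X.shape[0]),
            learning_rate_init=phases[0][1],
            max_iter=phases[0][0],
            n_iter_no_change=cfg.epochs + 1,  # run the schedule literally, no early stop
            tol=0.0,
            shuffle=True,
            random_state=cfg.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            model.fit(X, y)
            for n_epochs, lr in phases[1:]:
                model.set_params(
                    warm_start=True, learning_rate_init=lr, max_iter=n_epochs
                )
                model.fit(X, y)
        self.model_ = model
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.model_.predict(X)

    def save(self, path) -> None:
        """Serialize config + fitted weights to a single file (joblib)."""
        check_is_fitted(self)
        joblib.dump({"params": self.get_params(), "model": self.model_}, path)

    @classmethod
    def load(cls, path) -> "AffinityRegressor":
        """Restore a regressor saved by :meth:`save`."""
        payload = joblib.load(path)
        est = cls(**payload["params"])
        est.model_ = payload["model"]
        est.n_features_in_ = payload["model"].n_features_in_
        return est


def train(
    features: Sequence[np.ndarray], labels: Sequence[float], cfg: PredictorConfig
) -> AffinityRegressor:
    """Train one affinity regressor; thin wrapper over :class:`AffinityRegressor`."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise DataError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")
    est = AffinityRegressor(
        hidden_sizes=cfg.hidden_sizes,
        epochs=cfg.epochs,
        lr_schedule=cfg.lr_schedule,
        batch_size=cfg.batch_size,
        activation=cfg.activation,
        random_state=cfg.seed,
    )
    return est.fit(X, y)


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation coefficient between observations and predictions."""
    return float(stats.pearsonr(np.asarray(y_true), np.asarray(y_pred)).statistic)


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error in the units of the labels (kcal/mol here)."""
    diff = np.asarray(y_true, dtype=float) - np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean(diff**2)))


@dataclass
class CrossValReport:
    """k-fold cross-validation metrics for one affinity regressor.

    ``fold_assignments[i]`` is the fold in which sample i was held out.
    Pooled metrics are computed over the concatenated out-of-fold
    predictions; fold-averaged means are also provided since either
    convention appears in the literature.
    """

    fold_r: list[float]
    fold_rmse: list[float]
    pooled_r: float
    pooled_rmse: float
    fold_assignments: np.ndarray
    seed: int
    predictions: np.ndarray = field(repr=False, default=None)

    @property
    def mean_fold_r(self) -> float:
        return float(np.mean(self.fold_r))

    @property
    def mean_fold_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    def to_dict(self) -> dict:
        return {
            "pooled_r": self.pooled_r,
            "pooled_rmse": self.pooled_rmse,
            "mean_fold_r": self.mean_fold_r,
            "mean_fold_rmse": self.mean_fold_rmse,
            "fold_r": list(self.fold_r),
            "fold_rmse": list(self.fold_rmse),
            "seed": self.seed,
        }


def kfold_cv(
    features: Sequence[np.ndarray],
    labels: Sequence[float],
    cfg: PredictorConfig,
    k: int = 10,
) -> CrossValReport:
    """Seeded k-fold cross-validation of the affinity regressor.

    Rows are shuffled once with cfg.seed and split into k near-equal folds;
    each fold is held out exactly once while a fresh regressor is trained on
    the rest. Fold sizes differ by at most one sample.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise DataError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")
    n = X.shape[0]
    if not 2 <= k <= n:
        raise DataError(f"need 2 <= k <= n, got k={k}, n={n}")

    splitter = KFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    assignments = np.empty(n, dtype=int)
    predictions = np.empty(n, dtype=float)
    fold_r, fold_rmse = [], []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X)):
        fold_cfg = PredictorConfig(
            hidden_sizes=cfg.hidden_sizes,
            epochs=cfg.epochs,
            lr_schedule=list(cfg.lr_schedule),
            batch_size=cfg.batch_size,
            activation=cfg.activation,
            seed=cfg.seed + fold + 1,
        )
        est = train(X[train_idx], y[train_idx], fold_cfg)
        pred = est.predict(X[test_idx])
        assignments[test_idx] = fold
        predictions[test_idx] = pred
        fold_r.append(pearson_r(y[test_idx], pred))
        fold_rmse.append(rmse(y[test_idx], pred))
    return CrossValReport(
        fold_r=fold_r,
        fold_rmse=fold_rmse,
        pooled_r=pearson_r(y, predictions),
        pooled_rmse=rmse(y, predictions),
        fold_assignments=assignments,
        seed=cfg.seed,
        predictions=predictions,
    )


DEFAULT_TARGETS = ("DAT", "NET", "SERT", "hERG")


def predict_panel(
    mols: Sequence[tuple[MoleculeRecord, np.ndarray]],
    predictors: Mapping[str, AffinityRegressor],
    targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Predict ΔG for every molecule against every target.

    Returns a DataFrame indexed by molecule id with one kcal/mol column per
    target (DAT, NET, SERT, hERG by default).
    """
    if targets is None:
        targets = [t for t in DEFAULT_TARGETS if t in predictors] or list(predictors)
    missing = [t for t in targets if t not in predictors]
    if missing:
        raise ConfigError(f"no trained predictor for target(s) {missing}")
    ids = [m.id for m, _ in mols]
    panel = pd.DataFrame(index=pd.Index(ids, name="id"), columns=list(targets), dtype=float)
    if mols:
        Z = np.vstack([z for _, z in mols])
        for t in targets:
            panel[t] = predictors[t].predict(Z)
    return panel
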