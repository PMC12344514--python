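"""Penalized prediction of behavioral outcomes from connectivity features.

Elastic net with 10-fold cross-validation over a grid of mixing parameters
and an automatically scaled descending penalty path; the winning (mixing,
penalty) pair minimizes mean CV squared error. Features are standardized
internally on the training data; outcomes stay on their native scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

__all__ = [
    "PredictionModel",
    "ScoreTable",
    "DEFAULT_ALPHA_GRID",
    "fit_elastic_net_cv",
    "fit_elastic_net",
    "predict_scores",
    "performance_r",
]

# L1 mixing grid; 0 is excluded so "selected features" is well defined.
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass
class PredictionModel:
    """Fitted elastic net with its cross-validation record.

    ``mixing`` is the L1/L2 mixing parameter (sklearn ``l1_ratio``) and
    ``penalty`` the overall strength (sklearn ``alpha``). Coefficients are on
    the standardized-feature scale; predictions are invariant to that choice.
    """

    mixing: float
    penalty: float
    intercept: float
    coefficients: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    cv_curve: pd.DataFrame = field(repr=False, default=None)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)

    @property
    def n_features(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    @property
    def degenerate(self) -> bool:
        """True when no features were selected (predictions collapse to a constant)."""
        return self.n_selected == 0

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature count {X.shape[1]} does not match model ({self.n_features})"
            )
        return (X - self.feature_means) / self.feature_sds

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + self.standardize(X) @ self.coefficients


def _standardization(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)  # constant features stay at 0 after centering
    return mu, sd


def fit_elastic_net_cv(
    X_train: np.ndarray,
    y_train: np.ndarray,
    alpha_grid=None,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    max_iter: int = 20000,
) -> PredictionModel:
    """Grid-search elastic net by minimum mean cross-validated squared error.

    Folds are a single random partition fixed by ``seed`` and reused across
    the whole mixing grid; the penalty path is 100 log-spaced values
    auto-scaled from the training data for each mixing value. The winner is
    refit on the full training set.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X_train must be subjects x features aligned with y_train")
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"fewer subjects ({n}) than folds ({n_folds})")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome; nothing to fit")
    grid = list(DEFAULT_ALPHA_GRID if alpha_grid is None else alpha_grid)
    if any(not 0.0 < g <= 1.0 for g in grid):
        raise ValueError("mixing values must be in (0, 1]")

    mu, sd = _standardization(X)
    Xs = (X - mu) / sd
    folds = list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(Xs))
    enet = ElasticNetCV(
        l1_ratio=grid,
        alphas=n_lambdas,
        cv=folds,
        fit_intercept=True,
        max_iter=max_iter,
    )
    enet.fit(Xs, y)

    alphas = np.atleast_2d(enet.alphas_)
    mse_path = enet.mse_path_
    if mse_path.ndim == 2:  # single mixing value
        mse_path = mse_path[None, ...]
    records = []
    for gi, g in enumerate(grid):
        mean_mse = mse_path[gi].mean(axis=1)
        se_mse = mse_path[gi].std(axis=1, ddof=1) / np.sqrt(n_folds)
        for li in range(alphas.shape[1]):
            records.append(
                {
                    "mixing": float(g),
                    "penalty": float(alphas[gi, li]),
                    "mean_cv_error": float(mean_mse[li]),
                    "se_cv_error": float(se_mse[li]),
                }
            )
    cv_curve = pd.DataFrame.from_records(records)
    best = cv_curve["mean_cv_error"].idxmin()
    assert np.isclose(
        cv_curve.loc[best, "penalty"], enet.alpha_
    ) and np.isclose(cv_curve.loc[best, "mixing"], enet.l1_ratio_), (
        "selected (mixing, penalty) must minimize mean CV error"
    )
    return PredictionModel(
        mixing=float(enet.l1_ratio_),
        penalty=float(enet.alpha_),
        intercept=float(enet.intercept_),
        coefficients=enet.coef_.copy(),
        feature_means=mu,
        feature_sds=sd,
        cv_curve=cv_curve,
        seed=seed,
    )


def fit_elastic_net(
    X_train: np.ndarray,
    y_train: np.ndarray,
    mixing: float = 0.5,
    penalty: float = 1.0,
    max_iter: int = 20000,
) -> PredictionModel:
    """Single elastic net fit at a fixed (mixing, penalty); no CV.

    ``penalty = 0`` falls back to ordinary least squares.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    mu, sd = _standardization(X)
    Xs = (X - mu) / sd
    if penalty == 0.0:
        design = np.column_stack([np.ones(Xs.shape[0]), Xs])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept, coef = float(beta[0]), beta[1:]
    else:
        enet = ElasticNet(
            alpha=penalty, l1_ratio=mixing, fit_intercept=True, max_iter=max_iter
        )
        enet.fit(Xs, y)
        intercept, coef = float(enet.intercept_), enet.coef_.copy()
    return PredictionModel(
        mixing=float(mixing),
        penalty=float(penalty),
        intercept=intercept,
        coefficients=coef,
        feature_means=mu,
        feature_sds=sd,
        cv_curve=pd.DataFrame(),
    )


@dataclass
class ScoreTable:
    """Observed and model-predicted scores per subject for one measure."""

    frame: pd.DataFrame  # columns: subject_id, observed, predicted
    measure: str = ""
    set_label: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        required = {"subject_id", "observed", "predicted"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"frame must contain columns {sorted(required)}")


def predict_scores(
    model: PredictionModel,
    X: np.ndarray,
    y: np.ndarray,
    subject_ids=None,
    measure: str = "",
    set_label: str = "",
) -> ScoreTable:
    """Predicted vs observed scores; rows with missing outcomes are dropped."""
    y = np.asarray(y, dtype=float).ravel()
    predicted = model.predict(X)
    if predicted.shape != y.shape:
        raise ValueError("X and y row counts differ")
    ids = (
        list(subject_ids)
        if subject_ids is not None
        else [f"sub{i + 1:03d}" for i in range(y.shape[0])]
    )
    frame = pd.DataFrame(
        {"subject_id": ids, "observed": y, "predicted": predicted}
    ).dropna(subset=["observed"])
    return ScoreTable(
        frame.reset_index(drop=True),
        measure=measure,
        set_label=set_label,
        degenerate=model.degenerate,
    )


def performance_r(scores: ScoreTable) -> float:
    """Pearson correlation of predicted vs observed scores.

    Degenerate (zero-feature) models and constant predictions report r = 0,
    matching the convention used for empty models.
    """
    frame = scores.frame
    if len(frame) < 3:
        raise ValueError("need at least 3 scored subjects")
    pred = frame["predicted"].to_numpy()
    obs = frame["observed"].to_numpy()
    if scores.degenerate or np.ptp(pred) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])
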