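"""Regression backends for forest cover, NMSE comparison, and hindcasting.

The response is per-cell natural forest cover (NFC, a fraction in [0, 1]);
the predictors are static topography/climate (ELE, SLO, CPP) plus the
period-varying road indicators per class.  One model is trained on the
pooled observed periods and then applied to an earlier period's road
metrics — with topography and climate held fixed — to hindcast the
historical forest cover.

Four interchangeable backends are provided (ordinary linear regression, an
additive spline model, a single-hidden-layer neural network, and a random
forest); they are compared by normalized mean square error (NMSE) under a
shared cell-level cross-validation, and the lowest-NMSE backend wins.

NMSE here is mean squared error divided by the population variance of the
observations: 0 for a perfect predictor, 1 for the constant-mean predictor
(values above 1 are possible for models worse than the mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

__all__ = [
    "BACKENDS",
    "DEFAULT_FEATURES",
    "ModelSpec",
    "FittedModel",
    "ComparisonResult",
    "nmse",
    "make_estimator",
    "fit",
    "hindcast",
    "compare_backends",
    "cell_folds",
]

logger = logging.getLogger(__name__)

BACKENDS = ("linear", "additive", "neural", "forest")

DEFAULT_FEATURES = (
    "ELE", "SLO", "CPP",
    "SRL_main", "DNR_main", "NON_main", "MND_main",
    "SRL_secondary", "DNR_secondary", "NON_secondary", "MND_secondary",
)

#: factor applied to the largest observed distance-to-road when imputing a
#: missing DNR ("no road of the class anywhere" is informatively far)
DNR_IMPUTE_FACTOR = 1.5


def nmse(predicted: np.ndarray | pd.Series, observed: np.ndarray | pd.Series) -> float:
    """Normalized mean square error: MSE / population variance of observed.

    Raises
    ------
    ValueError
        If fewer than two values are given or the observations are
        constant (the normalizing variance would be zero).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if o.size < 2:
        raise ValueError("need at least two observations")
    var = o.var()  # population variance (ddof=0)
    if var == 0:
        raise ValueError("observed values are constant: NMSE undefined")
    return float(((p - o) ** 2).mean() / var)


@dataclass(frozen=True)
class ModelSpec:
    """Which backend, which features, which seed."""

    backend: str = "forest"
    features: tuple[str, ...] = DEFAULT_FEATURES
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}; expected one of {BACKENDS}")
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))


def make_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a spec."""
    hp = dict(spec.hyperparameters)
    if spec.backend == "linear":
        return LinearRegression(**hp)
    if spec.backend == "additive":
        # additive-in-features spline smoother with a light ridge penalty
        n_knots = hp.pop("n_knots", 5)
        alpha = hp.pop("alpha", 1e-3)
        return Pipeline(
            [
                ("splines", SplineTransformer(n_knots=n_knots, degree=3)),
                ("ridge", Ridge(alpha=alpha, **hp)),
            ]
        )
    if spec.backend == "neural":
        params = dict(
            hidden_layer_sizes=(16,), max_iter=2000, random_state=spec.seed,
        )
        params.update(hp)
        return Pipeline(
            [("scale", StandardScaler()), ("mlp", MLPRegressor(**params))]
        )
    # forest: conventional regression-forest defaults
    params = dict(
        n_estimators=500,
        max_features=1 / 3,
        min_samples_leaf=5,
        bootstrap=True,
        random_state=spec.seed,
        n_jobs=1,
    )
    params.update(hp)
    return RandomForestRegressor(**params)


def _design_matrix(
    table: pd.DataFrame,
    features: Sequence[str],
    imputation: Mapping[str, float] | None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Feature frame with DNR missingness handled.

    Every DNR feature gets a 0/1 ``*_missing`` indicator column and NaNs
    replaced by ``max observed x DNR_IMPUTE_FACTOR``.  When ``imputation``
    is given (prediction time) the stored training values are reused;
    otherwise they are derived from ``table`` and returned.
    """
    missing_cols = [f for f in features if f not in table.columns]
    if missing_cols:
        raise ValueError(f"cell table lacks covariate column(s): {missing_cols}")
    X = table.loc[:, list(features)].copy()
    learned: dict[str, float] = {}
    for col in features:
        if not col.startswith("DNR"):
            if X[col].isna().any():
                raise ValueError(f"covariate {col!r} has missing values beyond the DNR rule")
            continue
        if imputation is not None:
            fill = imputation[col]
        else:
            observed = X[col].dropna()
            if observed.empty:
                raise ValueError(f"covariate {col!r} has no observed values to impute from")
            fill = float(observed.max()) * DNR_IMPUTE_FACTOR
            learned[col] = fill
        X[f"{col}_missing"] = X[col].isna().astype(float)
        X[col] = X[col].fillna(fill)
    return X, learned


@dataclass
class FittedModel:
    """A trained backend plus everything needed to apply it elsewhere."""

    spec: ModelSpec
    estimator: object
    imputation: dict[str, float]
    training_periods: tuple[str, ...]
    n_training_rows: int
    training_nmse: float

    def predict(self, table: pd.DataFrame) -> pd.Series:
        """Predict NFC for the rows of ``table``, clipped to [0, 1]."""
        X, _ = _design_matrix(table, self.spec.features, self.imputation)
        pred = np.clip(self.estimator.predict(X.to_numpy()), 0.0, 1.0)
        return pd.Series(pred, index=table.index, name="nfc_pred")


def _select_periods(table: pd.DataFrame, periods: Sequence[str]) -> pd.DataFrame:
    have = table.index.get_level_values("period")
    missing = [p for p in periods if p not in set(have)]
    if missing:
        raise ValueError(f"period(s) {missing} absent from the cell table")
    return table[have.isin(list(periods))]


def fit(table: pd.DataFrame, spec: ModelSpec, periods: Sequence[str]) -> FittedModel:
    """Train one pooled model on the requested observed periods.

    ``table`` is the cell table indexed by (cell_id, period) with an
    ``NFC`` column and the spec's feature columns.  All (cell, period)
    rows of the listed periods train a single model with no period
    feature.  Deterministic under the spec's seed.
    """
    rows = _select_periods(table, periods)
    if rows["NFC"].isna().any():
        raise ValueError("training rows have missing NFC")
    X, imputation = _design_matrix(rows, spec.features, None)
    y = rows["NFC"].to_numpy(dtype=float)
    estimator = make_estimator(spec)
    estimator.fit(X.to_numpy(), y)
    pred = np.clip(estimator.predict(X.to_numpy()), 0.0, 1.0)
    return FittedModel(
        spec=spec,
        estimator=estimator,
        imputation=imputation,
        training_periods=tuple(periods),
        n_training_rows=len(rows),
        training_nmse=nmse(pred, y),
    )


def hindcast(model: FittedModel, table: pd.DataFrame, target_period: str) -> pd.Series:
    """Predict NFC per cell for ``target_period``.

    Uses the target period's road metrics with the period-invariant
    topography/climate columns already present in the table.  Returns a
    Series indexed by cell id, values in [0, 1].
    """
    rows = _select_periods(table, [target_period])
    pred = model.predict(rows)
    pred.index = rows.index.get_level_values("cell_id")
    return pred


def cell_folds(cell_ids: Sequence[int], k: int, seed: int) -> dict[int, int]:
    """Deterministic fold assignment by cell: all periods of a cell share a fold."""
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(set(cell_ids)))
    rng.shuffle(ids)
    return {int(cid): i % k for i, cid in enumerate(ids)}


@dataclass
class ComparisonResult:
    """Cross-validated NMSE per backend and the winner."""

    table: pd.DataFrame  # index backend, columns nmse + per-fold
    winner: str

    def nmse_of(self, backend: str) -> float:
        return float(self.table.loc[backend, "nmse"])


def compare_backends(
    table: pd.DataFrame,
    specs: Sequence[ModelSpec],
    *,
    periods: Sequence[str],
    k_folds: int = 10,
    seed: int = 0,
) -> ComparisonResult:
    """Cross-validate every backend on identical folds; lowest NMSE wins.

    Folds are assigned per cell so that all periods of one cell stay in
    the same fold (no leakage of a cell's static covariates across the
    train/test split).  NMSE is computed on the pooled out-of-fold
    predictions.  A backend that fails on any fold is disqualified
    (NMSE = inf) and logged.
    """
    if len(specs) < 1:
        raise ValueError("need at least one backend spec")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    rows = _select_periods(table, periods)
    folds = cell_folds(rows.index.get_level_values("cell_id"), k_folds, seed)
    fold_of_row = rows.index.get_level_values("cell_id").map(folds)
    y = rows["NFC"].to_numpy(dtype=float)

    records = {}
    for spec in specs:
        oof = np.full(len(rows), np.nan)
        per_fold: list[float] = []
        failed = False
        for k in range(k_folds):
            test = np.asarray(fold_of_row == k)
            train = ~test
            if test.sum() == 0:
                continue
            try:
                Xtr, imp = _design_matrix(rows[train], spec.features, None)
                Xte, _ = _design_matrix(rows[test], spec.features, imp)
                est = clone(make_estimator(spec))
                est.fit(Xtr.to_numpy(), y[train])
                pred = np.clip(est.predict(Xte.to_numpy()), 0.0, 1.0)
            except Exception:  # noqa: BLE001 - backend disqualification path
                logger.exception("backend %s failed on fold %d; disqualified", spec.backend, k)
                failed = True
                break
            oof[test] = pred
            per_fold.append(nmse(pred, y[test]) if y[test].var() > 0 else np.nan)
        if failed:
            records[spec.backend] = {"nmse": np.inf, "fold_nmse": []}
        else:
            records[spec.backend] = {
                "nmse": nmse(oof, y),
                "fold_nmse": per_fold,
            }
    result = pd.DataFrame(
        {
            "nmse": {b: r["nmse"] for b, r in records.items()},
            "fold_nmse": {b: r["fold_nmse"] for b, r in records.items()},
        }
    )
    winner = result["nmse"].idxmin()
    return ComparisonResult(table=result, winner=str(winner))
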