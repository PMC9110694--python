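"""Random-forest gestational-age regression with external leave-one-out CV.

The modeling protocol:

* hyperparameters (feature fraction per split, minimum leaf size) are tuned
  by internal K-fold cross-validation minimizing RMSE;
* an external leave-one-out loop provides out-of-fold ("blinded")
  predictions, aggregated into Spearman rho, its two-sided P-value, and RMSE
  in weeks;
* feature importances are averaged over the LOOCV fold models;
* a restricted (parsimonious) panel is selected by forward inclusion in
  importance order, choosing the smallest panel whose LOOCV RMSE is within
  one standard error of the best (1-SE rule);
* the restricted panel can be refit on the full discovery cohort and applied
  to an independent validation cohort.

Tuning happens inside every LOOCV fold, so the held-out sample never
influences model selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold

__all__ = [
    "ModelConfig",
    "PredictionResult",
    "RestrictedModel",
    "TunedForestRegressor",
    "loo_indices",
    "loocv_predict",
    "evaluate",
    "rank_importance",
    "select_restricted_model",
    "apply_model",
    "stratified_models",
]


@dataclass
class ModelConfig:
    """Forest size, tuning grid and internal-CV settings."""

    n_trees: int = 500
    feature_fractions: tuple[float, ...] = (0.1, 0.33, 0.5)
    min_leaf_sizes: tuple[int, ...] = (1, 3, 5)
    internal_cv_folds: int = 5
    #: "impurity" (fast, default) or "permutation" (unbiased, slower)
    importance: str = "impurity"
    seed: int = 0
    n_jobs: int = 1

    def validate(self) -> None:
        if self.n_trees < 100:
            raise ValueError("n_trees must be >= 100")
        if self.internal_cv_folds < 2:
            raise ValueError("internal_cv_folds must be >= 2")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError("importance must be 'impurity' or 'permutation'")

    def estimator(self) -> "TunedForestRegressor":
        return TunedForestRegressor(
            n_trees=self.n_trees,
            feature_fractions=self.feature_fractions,
            min_leaf_sizes=self.min_leaf_sizes,
            internal_cv_folds=self.internal_cv_folds,
            importance=self.importance,
            random_state=self.seed,
            n_jobs=self.n_jobs,
        )


class TunedForestRegressor(BaseEstimator, RegressorMixin):
    """Random-forest regressor with internal-CV hyperparameter tuning.

    ``fit`` grid-searches feature fraction x minimum leaf size by K-fold CV
    (scoring: negative RMSE) and refits at the best combination; with a
    single-cell grid the search is skipped. Exposes ``feature_importances_``
    (impurity-based) and ``best_params_``.
    """

    def __init__(
        self,
        n_trees: int = 500,
        feature_fractions: tuple[float, ...] = (0.1, 0.33, 0.5),
        min_leaf_sizes: tuple[int, ...] = (1, 3, 5),
        internal_cv_folds: int = 5,
        importance: str = "impurity",
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.n_trees = n_trees
        self.feature_fractions = feature_fractions
        self.min_leaf_sizes = min_leaf_sizes
        self.internal_cv_folds = internal_cv_folds
        self.importance = importance
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _base(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.random_state, n_jobs=self.n_jobs
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(X).any():
            raise ValueError("X contains NaN; impute before modeling")
        if np.ptp(y) == 0:
            raise ValueError("y is constant; nothing to regress")
        grid = list(itertools.product(self.feature_fractions, self.min_leaf_sizes))
        if len(grid) == 1:
            ff, leaf = grid[0]
            self.best_params_ = {"max_features": ff, "min_samples_leaf": leaf}
            self.model_ = self._base().set_params(max_features=ff, min_samples_leaf=leaf)
            self.model_.fit(X, y)
        else:
            cv = KFold(
                n_splits=min(self.internal_cv_folds, len(y)),
                shuffle=True,
                random_state=self.random_state,
            )
            search = GridSearchCV(
                self._base(),
                param_grid={
                    "max_features": list(self.feature_fractions),
                    "min_samples_leaf": list(self.min_leaf_sizes),
                },
                scoring="neg_root_mean_squared_error",
                cv=cv,
                n_jobs=self.n_jobs,
                refit=True,
            )
            search.fit(X, y)
            self.best_params_ = search.best_params_
            self.model_ = search.best_estimator_
        if self.importance == "permutation":
            from sklearn.inspection import permutation_importance

            perm = permutation_importance(
                self.model_, X, y, n_repeats=5, random_state=self.random_state
            )
            self.feature_importances_ = perm.importances_mean
        else:
            self.feature_importances_ = self.model_.feature_importances_
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))


@dataclass
class PredictionResult:
    """Aggregated out-of-fold predictions and their quality metrics."""

    y_true: pd.Series
    y_pred: pd.Series
    rho: float
    p_value: float
    rmse: float
    importances: pd.Series

    def summary(self) -> dict:
        return {
            "n": int(len(self.y_true)),
            "rho": float(self.rho),
            "p_value": float(self.p_value),
            "rmse_weeks": float(self.rmse),
        }


@dataclass
class RestrictedModel:
    selected_feature_ids: list[str]
    k: int
    cv_rmse_path: pd.Series  # indexed by candidate panel size
    tolerance_rule: str = "smallest k with RMSE <= min RMSE + 1 SE of the minimum"
    ranked_feature_ids: list[str] = field(default_factory=list)


def evaluate(y_true, y_pred) -> tuple[float, float, float]:
    """Spearman rho (tie-corrected), its two-sided P, and RMSE in weeks.

    A degenerate (constant) input vector makes rho undefined; it is reported
    as 0 with P = 1.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 3:
        raise ValueError("need at least 3 paired observations")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        return 0.0, 1.0, rmse
    rho, p = stats.spearmanr(y_true, y_pred)
    return float(rho), float(p), rmse


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def loo_indices(n: int):
    """Leave-one-out splits: (train_index, test_index) with i never in its
    own training set."""
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        yield np.flatnonzero(mask), np.array([i])


def loocv_predict(X, y, cfg: ModelConfig | None = None) -> PredictionResult:
    """External leave-one-out CV over a samples x features matrix.

    Each sample is predicted by a model tuned (internal CV) and trained on
    all other samples; metrics summarize the aggregated blinded predictions.
    """
    cfg = cfg or ModelConfig()
    cfg.validate()
    Xf = _as_frame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=Xf.index)
    if len(Xf) < 10:
        raise ValueError("LOOCV needs at least 10 samples")
    if Xf.isna().any().any():
        raise ValueError("X contains NaN; impute before modeling")
    if np.ptp(y.to_numpy()) == 0:
        raise ValueError("y is constant; nothing to regress")

    est = cfg.estimator()
    preds = np.empty(len(Xf))
    importances = np.zeros(Xf.shape[1])
    Xv = Xf.to_numpy(float)
    yv = y.to_numpy()
    for train_idx, test_idx in loo_indices(len(Xf)):
        model = clone(est)
        model.fit(Xv[train_idx], yv[train_idx])
        preds[test_idx[0]] = model.predict(Xv[test_idx])[0]
        importances += model.feature_importances_
    importances /= len(Xf)
    rho, p, rmse = evaluate(yv, preds)
    return PredictionResult(
        y_true=y,
        y_pred=pd.Series(preds, index=Xf.index, name="y_pred"),
        rho=rho,
        p_value=p,
        rmse=rmse,
        importances=pd.Series(importances, index=Xf.columns, name="importance"),
    )


def rank_importance(X, y, cfg: ModelConfig | None = None,
                    result: PredictionResult | None = None) -> list[str]:
    """Features in descending mean LOOCV importance; ties broken by id."""
    if result is None:
        result = loocv_predict(X, y, cfg)
    imp = result.importances
    return sorted(imp.index, key=lambda f: (-imp[f], str(f)))


def select_restricted_model(
    X, y, cfg: ModelConfig | None = None, max_k: int = 10,
    result: PredictionResult | None = None,
) -> RestrictedModel:
    """Parsimonious panel by forward selection in importance order + 1-SE rule.

    The SE of the minimum-RMSE panel is estimated from its per-sample squared
    errors by the delta method: se(RMSE) = sd(e^2) / (2 * RMSE * sqrt(n)).
    """
    cfg = cfg or ModelConfig()
    Xf = _as_frame(X)
    if max_k > Xf.shape[1]:
        import warnings

        warnings.warn(f"max_k={max_k} exceeds feature count; clamped to {Xf.shape[1]}")
        max_k = Xf.shape[1]
    ranked = rank_importance(Xf, y, cfg, result=result)
    rmse_path = {}
    sq_errors = {}
    for k in range(1, max_k + 1):
        sub = Xf[ranked[:k]]
        res = loocv_predict(sub, y, cfg)
        rmse_path[k] = res.rmse
        sq_errors[k] = (res.y_true.to_numpy() - res.y_pred.to_numpy()) ** 2
    path = pd.Series(rmse_path, name="loocv_rmse")
    k_min = int(path.idxmin())
    e2 = sq_errors[k_min]
    se = float(np.std(e2, ddof=1) / (2.0 * path[k_min] * np.sqrt(len(e2))))
    threshold = path[k_min] + se
    k_star = int(min(k for k in path.index if path[k] <= threshold))
    return RestrictedModel(
        selected_feature_ids=ranked[:k_star],
        k=k_star,
        cv_rmse_path=path,
        ranked_feature_ids=ranked,
    )


def apply_model(
    X_train, y_train, X_new, feature_subset: list[str],
    cfg: ModelConfig | None = None, y_new=None,
):
    """Train one model on the full discovery cohort (restricted to the panel)
    and predict an independently preprocessed cohort.

    Returns predictions (Series); if ``y_new`` is given, returns
    (predictions, (rho, p, rmse)).
    """
    cfg = cfg or ModelConfig()
    Xtr = _as_frame(X_train)
    Xnew = _as_frame(X_new)
    missing = [f for f in feature_subset if f not in Xnew.columns]
    if missing:
        raise ValueError(f"features absent from new cohort: {missing}")
    missing_tr = [f for f in feature_subset if f not in Xtr.columns]
    if missing_tr:
        raise ValueError(f"features absent from training cohort: {missing_tr}")
    model = cfg.estimator()
    model.fit(Xtr[feature_subset].to_numpy(float), np.asarray(y_train, float))
    preds = pd.Series(model.predict(Xnew[feature_subset].to_numpy(float)),
                      index=Xnew.index, name="y_pred")
    if y_new is None:
        return preds
    return preds, evaluate(np.asarray(y_new, float), preds.to_numpy())


def stratified_models(
    X, y, groups, cfg: ModelConfig | None = None, max_k: int = 10
) -> dict[str, dict]:
    """Independent LOOCV + restricted selection per delivery-outcome group."""
    cfg = cfg or ModelConfig()
    Xf = _as_frame(X)
    y = pd.Series(np.asarray(y, float), index=Xf.index)
    groups = pd.Series(np.asarray(groups), index=Xf.index)
    out: dict[str, dict] = {}
    for g in sorted(groups.unique()):
        idx = groups[groups == g].index
        if len(idx) < 10:
            raise ValueError(f"group {g!r} has {len(idx)} samples (< 10)")
        res = loocv_predict(Xf.loc[idx], y.loc[idx], cfg)
        restricted = select_restricted_model(Xf.loc[idx], y.loc[idx], cfg, max_k=max_k, result=res)
        out[str(g)] = {"prediction": res, "restricted": restricted}
    return out
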