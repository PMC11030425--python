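"""Supervised extension of V^G to genes without an allelic-expression estimate.

Allelic-expression-based V^G needs well-covered heterozygous sites and is
therefore missing for many genes.  Because V^G correlates with other gene
metrics (eQTL-based variance, loss-of-function constraint such as LOEUF,
expression level, tissue specificity, regulatory complexity), a gradient
boosted tree ensemble trained on those metrics can predict a V^G-like score
(V^G_ML) for genes lacking the direct estimate.  Labels are modelled on the
natural-log scale and predictions exponentiated back.

Pipeline: KNN-impute the gene x feature matrix (dropping genes with too many
missing features), split genes 80/20, fit :class:`VGRegressor` on ln V^G,
evaluate on the hold-out set, and merge predictions under the AE-precedence
rule to form V^G_AEML.
"""

from __future__ import annotations

import logging
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.impute import KNNImputer

from .errors import ValidationError

__all__ = [
    "DEFAULT_GBT_PARAMS",
    "KNNFeatureImputer",
    "ModelEvaluation",
    "VGRegressor",
    "evaluate_model",
    "knn_impute",
    "split_train_test",
    "train_tissue_models",
]

logger = logging.getLogger(__name__)

#: Final gradient-boosting hyperparameters (selected upstream by
#: cross-validated search; shipped here as the package default).
DEFAULT_GBT_PARAMS: dict = {
    "max_depth": 6,
    "learning_rate": 0.0236,
    "subsample": 0.96,
    "colsample_bytree": 0.746,
    "colsample_bylevel": 0.494,
    "n_estimators": 344,
    "min_split_loss": 2.0,
    "reg_lambda": 1.27,
    "reg_alpha": 4.5,
}


class KNNFeatureImputer(BaseEstimator, TransformerMixin):
    """K-nearest-neighbour imputation of a gene-feature matrix.

    Genes with more than ``max_missing`` missing features are dropped
    (they carry too little information to impute); remaining missing cells
    are replaced by the mean of the ``k`` nearest genes under Euclidean
    distance on the columns observed in both rows.  Features are
    standardised for the distance computation only — observed values pass
    through unchanged.

    Parameters
    ----------
    k : int, default=5
        Number of neighbour genes averaged per imputed cell.
    max_missing : int, default=5
        Maximum number of missing features a gene may have and still be
        imputed.
    """

    def __init__(self, k: int = 5, max_missing: int = 5):
        self.k = k
        self.max_missing = max_missing

    def fit(self, X: pd.DataFrame, y=None) -> "KNNFeatureImputer":
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        X = self._as_frame(X)
        keep = X.isna().sum(axis=1) <= self.max_missing
        donors = X.loc[keep]
        needs_imputation = donors.columns[donors.isna().any()]
        for col in needs_imputation:
            if donors[col].notna().sum() < self.k:
                raise ValidationError(
                    f"column {col!r} has fewer than k={self.k} observed donor rows"
                )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.mean_ = donors.mean()
        scale = donors.std(ddof=0)
        self.scale_ = scale.where(scale > 0, 1.0)
        self._imputer = KNNImputer(n_neighbors=self.k, weights="uniform")
        self._imputer.fit((donors - self.mean_) / self.scale_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the imputed matrix; rows over the missingness cap are dropped."""
        if not hasattr(self, "_imputer"):
            raise ValidationError("imputer is not fitted")
        X = self._as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValidationError("feature columns differ from those seen at fit")
        kept = X.loc[X.isna().sum(axis=1) <= self.max_missing]
        if kept.empty:
            return kept.copy()
        z = (kept - self.mean_) / self.scale_
        imputed_z = self._imputer.transform(z)
        imputed = pd.DataFrame(imputed_z, index=kept.index, columns=kept.columns)
        imputed = imputed * self.scale_ + self.mean_
        # observed cells are authoritative; only fill the holes
        return kept.where(kept.notna(), imputed)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        return X.astype(float)


def knn_impute(features: pd.DataFrame, k: int = 5, max_missing: int = 5) -> pd.DataFrame:
    """Functional wrapper: fit and apply :class:`KNNFeatureImputer` in one step."""
    return KNNFeatureImputer(k=k, max_missing=max_missing).fit(features).transform(features)


def split_train_test(
    gene_ids, train_frac: float = 0.8, seed: int | None = None
) -> tuple[list, list]:
    """Disjoint, exhaustive train/hold-out split of labelled genes.

    ``|train| = round(train_frac * n)``; the partition is a deterministic
    function of the id set and the seed (input order does not matter).
    """
    ids = sorted(set(gene_ids))
    n = len(ids)
    if n < 10 and train_frac < 1.0:
        raise ValidationError("need at least 10 labelled genes to split")
    if not (0.0 < train_frac <= 1.0):
        raise ValidationError("train_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


class VGRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted regressor of ln V^G from gene features.

    Thin scikit-learn estimator around an XGBoost tree ensemble with the
    package's default hyperparameters.  ``fit`` takes features and ln V^G
    labels; ``predict`` returns ln-scale values and :meth:`predict_vg`
    exponentiates back to strictly positive variances.

    Attributes
    ----------
    model_ : xgboost.XGBRegressor
        The fitted ensemble.
    feature_names_in_ : ndarray of str
        Training feature schema; prediction inputs must match.
    feature_importances_ : ndarray
        Per-feature gain shares (non-negative; sum to 1 whenever the
        ensemble contains at least one split).
    """

    def __init__(
        self,
        max_depth: int = DEFAULT_GBT_PARAMS["max_depth"],
        learning_rate: float = DEFAULT_GBT_PARAMS["learning_rate"],
        subsample: float = DEFAULT_GBT_PARAMS["subsample"],
        colsample_bytree: float = DEFAULT_GBT_PARAMS["colsample_bytree"],
        colsample_bylevel: float = DEFAULT_GBT_PARAMS["colsample_bylevel"],
        n_estimators: int = DEFAULT_GBT_PARAMS["n_estimators"],
        min_split_loss: float = DEFAULT_GBT_PARAMS["min_split_loss"],
        reg_lambda: float = DEFAULT_GBT_PARAMS["reg_lambda"],
        reg_alpha: float = DEFAULT_GBT_PARAMS["reg_alpha"],
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.colsample_bylevel = colsample_bylevel
        self.n_estimators = n_estimators
        self.min_split_loss = min_split_loss
        self.reg_lambda = reg_lambda
        self.reg_alpha = reg_alpha
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X: pd.DataFrame, y) -> "VGRegressor":
        """Fit on features ``X`` and natural-log labels ``y`` (ln V^G)."""
        X = self._check_X(X, fitting=True)
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValidationError("feature/label row counts differ")
        if not np.isfinite(y).all():
            raise ValidationError("labels must be finite (ln V^G)")
        self.model_ = xgb.XGBRegressor(
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            colsample_bylevel=self.colsample_bylevel,
            n_estimators=self.n_estimators,
            gamma=self.min_split_loss,
            reg_lambda=self.reg_lambda,
            reg_alpha=self.reg_alpha,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
            tree_method="hist",
            importance_type="total_gain",
            base_score=float(np.mean(y)),
        )
        self.model_.fit(X.to_numpy(dtype=float), y)
        self.booster_ = self.model_.get_booster()
        raw = self.model_.feature_importances_.astype(np.float64)
        total = raw.sum()
        self.feature_importances_ = raw / total if total > 0 else raw
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted ln V^G for each row of ``X``."""
        if not hasattr(self, "booster_"):
            raise ValidationError("model is not fitted")
        X = self._check_X(X, fitting=False)
        dmat = xgb.DMatrix(X.to_numpy(dtype=float))
        return self.booster_.predict(dmat).astype(float)

    def save(self, path) -> None:
        """Persist to a single self-describing JSON file (schema, params,
        label transform and the serialized tree ensemble)."""
        import json
        from pathlib import Path

        if not hasattr(self, "booster_"):
            raise ValidationError("model is not fitted")
        payload = {
            "format": "vgrecal-model",
            "label_transform": "ln",
            "feature_names": [str(f) for f in self.feature_names_in_],
            "params": self.get_params(),
            "importances": [float(x) for x in self.feature_importances_],
            "booster": json.loads(bytes(self.booster_.save_raw(raw_format="json"))),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "VGRegressor":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "vgrecal-model":
            raise ValidationError(f"{path} is not a vgrecal model file")
        est = cls(**payload["params"])
        est.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
        est.n_features_in_ = len(est.feature_names_in_)
        est.feature_importances_ = np.asarray(payload["importances"], dtype=float)
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]).encode()))
        est.booster_ = booster
        return est

    def predict_vg(self, X: pd.DataFrame) -> pd.Series:
        """Predicted V^G (exponentiated; strictly positive)."""
        pred = np.exp(self.predict(X))
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(pred))
        return pd.Series(pred, index=index, name="vg_ml")

    def _check_X(self, X, fitting: bool) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        X = X.astype(float)
        if fitting:
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            self.n_features_in_ = X.shape[1]
        elif list(X.columns) != list(self.feature_names_in_):
            raise ValidationError(
                "prediction features do not match the training schema: "
                f"expected {list(self.feature_names_in_)}, got {list(X.columns)}"
            )
        return X


class ModelEvaluation(NamedTuple):
    rmse_log: float
    spearman: float


def evaluate_model(model: VGRegressor, X_test: pd.DataFrame, y_test) -> ModelEvaluation:
    """Hold-out evaluation: RMSE on the ln scale and Spearman correlation."""
    y_test = np.asarray(y_test, dtype=float)
    if len(y_test) == 0:
        raise ValidationError("test set is empty")
    pred = model.predict(X_test)
    rmse = float(np.sqrt(np.mean((pred - y_test) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(y_test) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(pred, y_test).statistic)
    return ModelEvaluation(rmse_log=rmse, spearman=rho)


def train_tissue_models(
    labels_by_tissue: Mapping[str, pd.Series],
    shared_features: pd.DataFrame,
    tissue_features: Mapping[str, pd.DataFrame] | None = None,
    min_labeled: int = 100,
    seed: int = 0,
    **params,
) -> dict[str, VGRegressor]:
    """Fit one :class:`VGRegressor` per tissue.

    ``labels_by_tissue`` maps tissue -> gene-indexed ln V^G labels;
    ``shared_features`` is the cross-tissue gene x metric frame and
    ``tissue_features`` optionally adds per-tissue columns (expression
    level and eQTL-based variance in that tissue).  Tissues with fewer than
    ``min_labeled`` labelled genes are skipped with a warning.
    """
    models: dict[str, VGRegressor] = {}
    for tissue in sorted(labels_by_tissue):
        labels = labels_by_tissue[tissue].dropna()
        feats = shared_features
        if tissue_features is not None and tissue in tissue_features:
            extra = tissue_features[tissue].add_suffix("_tissue")
            feats = shared_features.join(extra, how="inner")
        common = labels.index.intersection(feats.index)
        if len(common) < min_labeled:
            logger.warning(
                "tissue %s skipped: %d labelled genes < minimum %d",
                tissue, len(common), min_labeled,
            )
            continue
        model = VGRegressor(random_state=seed, **params)
        model.fit(feats.loc[common], labels.loc[common].to_numpy())
        models[tissue] = model
    return models
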