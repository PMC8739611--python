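"""scikit-learn style estimators wrapping the extraction and classification
pipelines, so they compose with sklearn model selection and pipelines.

* :class:`EcgFeatureExtractor` — transformer: a list of ECG records in, a
  62-column feature DataFrame out.
* :class:`TraitRandomForest` — classifier: grid-tuned random forest over
  (n_estimators, max_features) selected by stratified cross-validation,
  exposing the tuned parameters, the winning CV accuracy and max-100
  normalised impurity importances as fitted attributes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from . import trait_pipeline as tp
from .config import ExtractionConfig
from .delineation import delineate, detect_r_peaks, preprocess
from .exceptions import NotFittedError
from .features import ALL_FEATURES
from .hrv_features import hrv_features, rr_from_rpeaks
from .morphology_features import (
    amplitude_features,
    assemble_feature_vector,
    temporal_features,
)
from .signal_io import EcgRecord

logger = logging.getLogger("cardiotrait")


def extract_features(record: EcgRecord,
                     config: ExtractionConfig | None = None) -> dict[str, float]:
    """Run the full single-record chain: preprocess, detect R peaks,
    delineate, and compute the 62 canonical features."""
    config = config or ExtractionConfig()
    pre = preprocess(record, config.delineation)
    rpeaks = detect_r_peaks(pre, config.delineation)
    fids = delineate(record, rpeaks, config.delineation)
    rr = rr_from_rpeaks(rpeaks, record.fs)
    hrv = hrv_features(
        rr, fs=record.fs,
        triangular_bin_width=config.triangular_bin_width,
        hr_mean_mode=config.hr_mean_mode,
        min_span_s=config.spectral_min_span_s)
    temporal = temporal_features(fids, rpeaks=rpeaks,
                                 bazett_literal=config.bazett_literal)
    amplitude = amplitude_features(fids, ek_weights=config.ek_weights,
                                   mode=config.relative_amplitude_mode)
    return assemble_feature_vector(hrv, temporal, amplitude)


class EcgFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer from ECG records to the 62-feature table."""

    def __init__(self, config: ExtractionConfig | None = None):
        self.config = config

    def fit(self, X=None, y=None):
        self.feature_names_out_ = list(ALL_FEATURES)
        return self

    def transform(self, X) -> pd.DataFrame:
        """``X``: iterable of :class:`EcgRecord`. Returns a DataFrame indexed
        by subject_id (or positional ids when absent)."""
        rows = {}
        for i, record in enumerate(X):
            sid = record.subject_id or f"record{i}"
            rows[sid] = extract_features(record, self.config)
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(ALL_FEATURES))
        df.index.name = "subject_id"
        return df

    def get_feature_names_out(self, input_features=None):
        return np.asarray(ALL_FEATURES, dtype=object)


class TraitRandomForest(ClassifierMixin, BaseEstimator):
    """Random forest with (ntree, mtry) tuning by cross-validated accuracy.

    Fitted attributes: ``best_ntree_``, ``best_mtry_``, ``cv_mean_accuracy_``
    (percent), ``model_``, ``classes_``, ``feature_importances_`` (max-100
    normalised) and ``ranked_importances_``.
    """

    def __init__(self, ntree_grid=tp.DEFAULT_NTREE_GRID, mtry_grid=None,
                 cv_folds: int = 10, random_state: int = 0):
        self.ntree_grid = ntree_grid
        self.mtry_grid = mtry_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"x{i}" for i in range(np.asarray(X).shape[1])]
        model, cv_acc, ntree, mtry = tp.train_rf(
            X, y, cv_folds=self.cv_folds, ntree_grid=tuple(self.ntree_grid),
            mtry_grid=None if self.mtry_grid is None else tuple(self.mtry_grid),
            seed=self.random_state)
        self.model_ = model
        self.classes_ = model.classes_
        self.cv_mean_accuracy_ = cv_acc
        self.best_ntree_ = ntree
        self.best_mtry_ = mtry
        self.feature_names_in_ = names
        self.ranked_importances_ = tp.feature_importance(model, names)
        by_name = dict(self.ranked_importances_)
        self.feature_importances_ = np.array([by_name[n] for n in names])
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError("TraitRandomForest is not fitted")

    def predict(self, X):
        self._check_fitted()
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        self._check_fitted()
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def evaluate(self, X, y):
        """Accuracy (%) with exact binomial 95% CI on held-out data."""
        self._check_fitted()
        return tp.evaluate(self.model_, X, y)
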