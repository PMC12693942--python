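"""Scikit-learn-style estimator facade over the assessment pipeline.

The method is template matching: an estimator is *fitted* on a standard
("template") execution of a movement and then *predicts* a 0-100 quality
score for test executions. Three estimators cover the pipeline stages:

``KinematicFeatures``
    stateless transformer turning keypoint sequences into 27-D per-frame
    feature matrices;
``AccelerationAnomalyDetector``
    fitted on a template, predicts the threshold coefficient ``t`` of each
    test sequence from acceleration-outlier discrepancy;
``QAQAScorer``
    the full scorer: features + anomaly-derived ``t`` + multi-resolution
    alignment + threshold-adjusted scoring.

All follow the usual conventions: parameters in ``__init__`` (inherited
``get_params``/``set_params``), fitted attributes with a trailing
underscore, ``NotFittedError`` before ``fit``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import anomaly as anomaly_mod
from .alignment import QaqaConfig, qaqa_align
from .anomaly import AnomalyConfig, AnomalyReport
from .features import build_features
from .scoring import DEFAULT_BASE, DEFAULT_T, assess, final_score
from .skeleton import KeypointSequence

__all__ = ["KinematicFeatures", "AccelerationAnomalyDetector", "QAQAScorer"]


def _as_sequences(X) -> list[KeypointSequence]:
    if isinstance(X, KeypointSequence):
        return [X]
    return list(X)


class KinematicFeatures(TransformerMixin, BaseEstimator):
    """Per-frame 27-D kinematic feature transformer.

    Stateless: ``fit`` only records the output dimensionality. ``transform``
    accepts a single :class:`KeypointSequence` (returns one ``(n, 27)``
    array) or an iterable of them (returns a list of arrays — sequences
    have different lengths, so no single stacked matrix exists).
    """

    def __init__(self, forward_axis=None, impute_missing: bool = True):
        self.forward_axis = forward_axis
        self.impute_missing = impute_missing

    def fit(self, X, y=None):
        self.n_features_out_ = 27
        return self

    def transform(self, X):
        single = isinstance(X, KeypointSequence)
        out = [
            build_features(
                seq, forward_axis=self.forward_axis, impute_missing=self.impute_missing
            ).values
            for seq in _as_sequences(X)
        ]
        return out[0] if single else out


class AccelerationAnomalyDetector(BaseEstimator):
    """Threshold-coefficient predictor from acceleration outliers.

    ``fit`` stores the template; ``predict`` returns the coefficient ``t``
    for each test sequence (1 flags suspected cheating, smaller values
    tighten the scoring tolerance). ``report`` exposes the full per-keypoint
    epsilon/outlier breakdown for one sequence.
    """

    def __init__(self, min_sample: int = 5, clustering_space: str = "value_1d"):
        self.min_sample = min_sample
        self.clustering_space = clustering_space

    def _config(self) -> AnomalyConfig:
        return AnomalyConfig(min_sample=self.min_sample, clustering_space=self.clustering_space)

    def fit(self, X: KeypointSequence, y=None):
        if not isinstance(X, KeypointSequence):
            raise TypeError("fit expects the template KeypointSequence")
        self._config()  # validate parameters eagerly
        self.template_ = X
        return self

    def _check_fitted(self):
        if not hasattr(self, "template_"):
            raise NotFittedError("call fit(template) first")

    def report(self, X: KeypointSequence) -> AnomalyReport:
        self._check_fitted()
        return anomaly_mod.detect(self.template_, X, self._config())

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return np.array([self.report(seq).t for seq in _as_sequences(X)])


class QAQAScorer(BaseEstimator):
    """Template-matching action quality scorer.

    Fit on the standard execution; ``predict`` returns the final 0-``base``
    score of each test sequence and ``assess`` the full report (threshold
    coefficient, outlier totals, alignment distance, cell accounting,
    per-pair breakdown).

    Parameters
    ----------
    radius : search-window dilation of the multi-resolution alignment.
    anomaly : run the anomaly module to derive ``t``; otherwise use
        ``default_t``.
    min_sample : DBSCAN minimum cluster size in the anomaly module.
    base : per-frame full mark (final scale is 0..base).
    """

    def __init__(
        self,
        radius: int = 10,
        min_size: int | None = None,
        anomaly: bool = True,
        min_sample: int = 5,
        clustering_space: str = "value_1d",
        default_t: float = DEFAULT_T,
        base: float = DEFAULT_BASE,
        distance_metric: str = "euclidean",
        divergence_mode: str = "l1_ratio",
        forward_axis=None,
    ):
        self.radius = radius
        self.min_size = min_size
        self.anomaly = anomaly
        self.min_sample = min_sample
        self.clustering_space = clustering_space
        self.default_t = default_t
        self.base = base
        self.distance_metric = distance_metric
        self.divergence_mode = divergence_mode
        self.forward_axis = forward_axis

    def _qaqa_config(self) -> QaqaConfig:
        return QaqaConfig(
            radius=self.radius, min_size=self.min_size, distance_metric=self.distance_metric
        )

    def _anomaly_config(self) -> AnomalyConfig:
        return AnomalyConfig(min_sample=self.min_sample, clustering_space=self.clustering_space)

    def fit(self, X: KeypointSequence, y=None):
        """Store the template and precompute its feature sequence."""
        if not isinstance(X, KeypointSequence):
            raise TypeError("fit expects the template KeypointSequence")
        self._qaqa_config()
        self._anomaly_config()
        self.template_ = X
        self.template_features_ = build_features(X, forward_axis=self.forward_axis)
        return self

    def _check_fitted(self):
        if not hasattr(self, "template_"):
            raise NotFittedError("call fit(template) first")

    def assess(self, X: KeypointSequence) -> dict:
        self._check_fitted()
        return assess(
            self.template_,
            X,
            anomaly_on=self.anomaly,
            qaqa_config=self._qaqa_config(),
            anomaly_config=self._anomaly_config(),
            default_t=self.default_t,
            base=self.base,
            forward_axis=self.forward_axis,
            divergence_mode=self.divergence_mode,
        )

    def predict(self, X) -> np.ndarray:
        """Final quality score of each test sequence, shape (n_sequences,)."""
        return np.array([self.assess(seq)["final"] for seq in _as_sequences(X)])

    def score_breakdown(self, X: KeypointSequence):
        """Per-pair q/S breakdown of one test sequence (alignment rerun)."""
        self._check_fitted()
        F_test = build_features(X, forward_axis=self.forward_axis)
        aln = qaqa_align(self.template_features_, F_test, self._qaqa_config())
        if self.anomaly:
            t = anomaly_mod.detect(self.template_, X, self._anomaly_config()).t
        else:
            t = self.default_t
        return final_score(
            aln.path, F_test, self.template_features_, t, self.base, self.divergence_mode
        )
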