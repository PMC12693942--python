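"""Acceleration-outlier detection and the score threshold coefficient.

Pipeline: for each retained keypoint of the template ("standard") and test
sequences, compute the per-keypoint acceleration series, select a DBSCAN
neighbourhood radius ``eps`` from the elbow of the sorted k-distance graph,
and count density outliers. The totals ``o1`` (template) and ``o2`` (test)
are compared through the relative difference ``r = |o1 - o2| / o1`` and
binned into a threshold coefficient ``t``:

====================  =====
condition             t
====================  =====
r = 0 (suspected       1
cheating: identical
outlier distribution)
0 < r <= 0.3           0.2
0.3 < r <= 0.5         0.15
r > 0.5                0.1
====================  =====

``t = 1`` zeroes the final score downstream; smaller ``t`` tightens the
per-frame tolerance. The spine, chest and hip-midpoint keypoints are
excluded (their accelerations barely vary in slow exercise), leaving 14
keypoints in the report.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .features import compute_acceleration
from .skeleton import N_KEYPOINTS, KeypointSequence

__all__ = [
    "DEFAULT_EXCLUDED",
    "AnomalyConfig",
    "AnomalyReport",
    "k_distance",
    "select_epsilon",
    "count_outliers",
    "outlier_labels",
    "threshold_coefficient",
    "detect",
]

logger = logging.getLogger(__name__)

#: Hip midpoint (0), spine (7) and thorax/chest (8) are dropped from the
#: anomaly pipeline; the remaining 14 keypoints are analysed.
DEFAULT_EXCLUDED: frozenset[int] = frozenset({0, 7, 8})

#: Upper bin edges and t values of the threshold rule, configurable.
DEFAULT_BINS: tuple[float, float] = (0.3, 0.5)
DEFAULT_T_VALUES: tuple[float, float, float, float] = (1.0, 0.2, 0.15, 0.1)


@dataclass(frozen=True)
class AnomalyConfig:
    """Tunables of the anomaly pipeline.

    ``min_sample`` is DBSCAN's minimum cluster size and the ``k`` of the
    k-distance graph. ``clustering_space`` selects the embedding in which
    density is measured: raw 1-D acceleration values (default) or 2-D
    (normalised time, value) points.
    """

    min_sample: int = 5
    excluded_keypoints: frozenset[int] = DEFAULT_EXCLUDED
    clustering_space: str = "value_1d"
    bins: tuple[float, float] = DEFAULT_BINS
    t_values: tuple[float, float, float, float] = DEFAULT_T_VALUES

    def __post_init__(self) -> None:
        if self.min_sample < 2:
            raise ValueError("min_sample must be >= 2")
        if not set(self.excluded_keypoints) <= set(range(N_KEYPOINTS)):
            raise ValueError("excluded_keypoints must be keypoint indices 0..16")
        if self.clustering_space not in ("value_1d", "time_value_2d"):
            raise ValueError("clustering_space must be 'value_1d' or 'time_value_2d'")

    @property
    def retained_keypoints(self) -> list[int]:
        return [k for k in range(N_KEYPOINTS) if k not in self.excluded_keypoints]


@dataclass
class AnomalyReport:
    """Per-keypoint epsilons/outlier counts and the derived coefficient."""

    per_keypoint: dict[int, dict[str, float]]
    o1: int
    o2: int
    ratio: float
    t: float
    config: AnomalyConfig = field(default_factory=AnomalyConfig)

    def to_dict(self) -> dict:
        return {
            "per_keypoint": {str(k): v for k, v in self.per_keypoint.items()},
            "o1": self.o1,
            "o2": self.o2,
            "ratio": self.ratio,
            "t": self.t,
            "min_sample": self.config.min_sample,
            "clustering_space": self.config.clustering_space,
        }


def _embed(values: np.ndarray, space: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if space == "value_1d":
        return values.reshape(-1, 1)
    m = len(values)
    time = np.linspace(0.0, 1.0, m) if m > 1 else np.zeros(m)
    scale = np.ptp(values) or 1.0  # keep the two axes comparable
    return np.column_stack([time, values / scale])


def k_distance(values: np.ndarray, k: int, clustering_space: str = "value_1d") -> np.ndarray:
    """Sorted distances of every point to its k-th nearest neighbour.

    This is the "sorted k-distance graph" whose elbow sets DBSCAN's eps.
    """
    pts = _embed(values, clustering_space)
    if len(pts) <= k:
        raise ValueError(
            f"series of length {len(pts)} has no {k}-th neighbour; use a smaller min_sample"
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)  # +1: first neighbour is self
    dists, _ = nn.kneighbors(pts)
    return np.sort(dists[:, k])


def select_epsilon(dists: np.ndarray) -> float:
    """Eps at the maximum slope change of the sorted k-distance graph.

    With unit index spacing the slope between consecutive points is just the
    forward difference, so eps is ``dists[j*]`` with
    ``j* = argmax_j (dists[j+1] - dists[j])``, ties broken by the smallest
    ``j``. A flat graph (all distances equal) returns that common value with
    a warning: there is no elbow.
    """
    dists = np.asarray(dists, dtype=float)
    if dists.size < 2:
        raise ValueError("need at least 2 k-distances to locate an elbow")
    diffs = np.diff(dists)
    if np.all(diffs == diffs[0]) and diffs[0] == 0:
        warnings.warn("flat k-distance graph: no elbow; using the common distance")
        return float(dists[0])
    j = int(np.argmax(diffs))
    return float(dists[j])


def outlier_labels(
    values: np.ndarray, min_sample: int, epsilon: float, clustering_space: str = "value_1d"
) -> np.ndarray:
    """DBSCAN cluster labels of the acceleration points (-1 = outlier)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.empty(0, dtype=int)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    # sklearn requires eps > 0; the smallest positive float keeps only exact
    # duplicates inside the neighbourhood, matching the eps = 0 semantics.
    eps = epsilon if epsilon > 0 else math.ulp(0.0)
    return DBSCAN(eps=eps, min_samples=min_sample).fit(_embed(values, clustering_space)).labels_


def count_outliers(
    values: np.ndarray, min_sample: int, epsilon: float, clustering_space: str = "value_1d"
) -> int:
    """Number of points DBSCAN labels noise; deterministic given inputs."""
    labels = outlier_labels(values, min_sample, epsilon, clustering_space)
    return int(np.sum(labels == -1))


def threshold_coefficient(
    o1: int,
    o2: int,
    bins: tuple[float, float] = DEFAULT_BINS,
    t_values: tuple[float, float, float, float] = DEFAULT_T_VALUES,
) -> float:
    """Map template/test outlier totals to the threshold coefficient ``t``.

    ``r = |o1 - o2| / o1``; ``r = 0`` (identical outlier distributions,
    suspected cheating) gives ``t = 1``, which downstream zeroes the score.
    An outlier-free template (``o1 = 0``) leaves ``r`` undefined: we take
    ``r = 0`` when the test is also clean and the strictest bin otherwise.
    """
    if o1 < 0 or o2 < 0:
        raise ValueError("outlier counts must be non-negative")
    lo, hi = bins
    t_cheat, t_small, t_mid, t_large = t_values
    if o1 == 0:
        return t_cheat if o2 == 0 else t_large
    r = abs(o1 - o2) / o1
    if r == 0:
        return t_cheat
    if r <= lo:
        return t_small
    if r <= hi:
        return t_mid
    return t_large


def _analyse_sequence(
    seq: KeypointSequence, config: AnomalyConfig
) -> dict[int, tuple[float, int]]:
    out: dict[int, tuple[float, int]] = {}
    for kp in range(N_KEYPOINTS):
        if kp in config.excluded_keypoints:
            logger.info("keypoint %d excluded from anomaly detection", kp)
            continue
        acc = compute_acceleration(seq, kp).values
        try:
            eps = select_epsilon(k_distance(acc, config.min_sample, config.clustering_space))
            count = count_outliers(acc, config.min_sample, eps, config.clustering_space)
        except ValueError as exc:
            raise ValueError(f"keypoint {kp}: {exc}") from exc
        out[kp] = (eps, count)
    return out


def detect(
    template: KeypointSequence, test: KeypointSequence, config: AnomalyConfig | None = None
) -> AnomalyReport:
    """Full anomaly comparison of a template/test pair.

    Each retained keypoint of each sequence gets its own eps (motion ranges
    differ strongly across joints, so a shared radius would over- or
    under-cluster); outlier counts are summed across keypoints into ``o1``
    and ``o2`` before binning.
    """
    config = config or AnomalyConfig()
    temp = _analyse_sequence(template, config)
    tst = _analyse_sequence(test, config)
    per_keypoint = {
        kp: {
            "epsilon_template": temp[kp][0],
            "outliers_template": temp[kp][1],
            "epsilon_test": tst[kp][0],
            "outliers_test": tst[kp][1],
        }
        for kp in temp
    }
    o1 = sum(c for _, c in temp.values())
    o2 = sum(c for _, c in tst.values())
    if o1 > 0:
        ratio = abs(o1 - o2) / o1
    else:
        ratio = 0.0 if o2 == 0 else math.inf
    t = threshold_coefficient(o1, o2, config.bins, config.t_values)
    return AnomalyReport(per_keypoint, o1, o2, ratio, t, config)
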