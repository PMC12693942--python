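"""Frame divergence, threshold-adjusted frame scores, and the final score.

For every aligned pair (i, j) on the warp path the divergence between the
test frame and the template frame is the relative L1 discrepancy

    q = |F_test - F_temp|_1 / |F_test|_1

(the test features normalise, as a fraction of the evaluated pose's own
feature mass; q = 0 iff the frames are identical). The per-frame score with
full mark ``base`` (default 100) and threshold coefficient ``t`` is

    S = base                    if q <= t  (and t < 1)
    S = base * (1 - q + t)      if t < q <= 1
    S = 0                       if q > 1 or t = 1

so ``t`` acts as a tolerance below which a frame scores full marks, and
``t = 1`` (suspected cheating) zeroes every frame. The final score is the
mean frame score over the warp path, on a 0..base scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import anomaly as anomaly_mod
from .alignment import QaqaConfig, WarpPath, qaqa_align
from .anomaly import AnomalyConfig
from .features import FeatureSequence, build_features
from .skeleton import KeypointSequence

__all__ = [
    "ScoreBreakdown",
    "frame_divergence",
    "frame_score",
    "final_score",
    "assess",
]

DEFAULT_T = 0.2  # tolerance used when the anomaly module is disabled
DEFAULT_BASE = 100.0


def frame_divergence(f_test: np.ndarray, f_temp: np.ndarray, mode: str = "l1_ratio") -> float:
    """Relative discrepancy ``q >= 0`` between a test and a template frame.

    ``l1_ratio`` (default) is the ratio of L1 norms of the difference and of
    the test frame — robust to individual near-zero features.
    ``mean_ratio`` averages per-feature relative errors instead.
    """
    f_test = np.asarray(f_test, dtype=float).ravel()
    f_temp = np.asarray(f_temp, dtype=float).ravel()
    if f_test.shape != f_temp.shape:
        raise ValueError(f"dimension mismatch: {f_test.shape} vs {f_temp.shape}")
    if mode == "l1_ratio":
        denom = np.abs(f_test).sum()
        if denom == 0:
            raise ValueError("all-zero test frame: divergence undefined")
        return float(np.abs(f_test - f_temp).sum() / denom)
    if mode == "mean_ratio":
        denom = np.abs(f_test)
        if np.any(denom == 0):
            raise ValueError("zero test feature: per-feature divergence undefined")
        return float(np.mean(np.abs(f_test - f_temp) / denom))
    raise ValueError(f"unknown divergence mode {mode!r}")


def frame_score(q: float, t: float, base: float = DEFAULT_BASE) -> float:
    """Threshold-adjusted score of one aligned frame pair, in [0, base]."""
    if q < 0:
        raise ValueError("divergence q must be >= 0")
    if t == 1:
        return 0.0
    if q <= t:
        return float(base)
    if q <= 1:
        return float(max(base * (1.0 - q + t), 0.0))
    return 0.0


@dataclass
class ScoreBreakdown:
    """Per-pair divergences and scores plus their mean, the final score."""

    q_values: np.ndarray
    frame_scores: np.ndarray
    t: float
    base: float
    final: float
    n_path: int

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "base": self.base,
            "final": self.final,
            "n_path": self.n_path,
            "q_values": [float(q) for q in self.q_values],
            "frame_scores": [float(s) for s in self.frame_scores],
        }


def final_score(
    path: WarpPath,
    F_test: FeatureSequence | np.ndarray,
    F_temp: FeatureSequence | np.ndarray,
    t: float,
    base: float = DEFAULT_BASE,
    mode: str = "l1_ratio",
) -> ScoreBreakdown:
    """Score a warp path: mean threshold-adjusted frame score along it.

    Path pairs are 1-based ``(i, j)`` with ``i`` indexing the template and
    ``j`` the test sequence.
    """
    if not len(path):
        raise ValueError("empty warp path")
    Vt = F_test.values if isinstance(F_test, FeatureSequence) else np.asarray(F_test, float)
    Vm = F_temp.values if isinstance(F_temp, FeatureSequence) else np.asarray(F_temp, float)
    q = np.array([frame_divergence(Vt[j - 1], Vm[i - 1], mode) for i, j in path])
    S = np.array([frame_score(qi, t, base) for qi in q])
    return ScoreBreakdown(q, S, t, base, float(S.mean()), len(path))


def assess(
    template: KeypointSequence,
    test: KeypointSequence,
    anomaly_on: bool = True,
    qaqa_config: QaqaConfig | None = None,
    anomaly_config: AnomalyConfig | None = None,
    default_t: float = DEFAULT_T,
    base: float = DEFAULT_BASE,
    forward_axis=None,
    divergence_mode: str = "l1_ratio",
) -> dict:
    """End-to-end assessment of a test sequence against a template.

    Builds kinematic features for both sequences, runs anomaly detection to
    obtain the threshold coefficient ``t`` (or uses ``default_t`` when the
    module is off), aligns with QAQA and scores along the warp path.
    Returns a flat report with the score, ``t``, outlier totals, alignment
    distance and cell accounting.
    """
    qaqa_config = qaqa_config or QaqaConfig()
    try:
        F_temp = build_features(template, forward_axis=forward_axis)
        F_test = build_features(test, forward_axis=forward_axis)
    except Exception as exc:
        raise RuntimeError(f"feature construction failed: {exc}") from exc
    o1 = o2 = None
    anomaly_report = None
    if anomaly_on:
        try:
            anomaly_report = anomaly_mod.detect(template, test, anomaly_config)
        except Exception as exc:
            raise RuntimeError(f"anomaly detection failed: {exc}") from exc
        t, o1, o2 = anomaly_report.t, anomaly_report.o1, anomaly_report.o2
    else:
        t = default_t
    try:
        aln = qaqa_align(F_temp, F_test, qaqa_config)
    except Exception as exc:
        raise RuntimeError(f"alignment failed: {exc}") from exc
    breakdown = final_score(aln.path, F_test, F_temp, t, base, divergence_mode)
    return {
        "final": breakdown.final,
        "t": t,
        "o1": o1,
        "o2": o2,
        "anomaly_on": anomaly_on,
        "distance": aln.distance,
        "cells_computed": aln.cells_computed,
        "levels": aln.levels,
        "n_path": breakdown.n_path,
        "radius": qaqa_config.radius,
        "base": base,
        "breakdown": breakdown,
        "anomaly_report": anomaly_report,
    }
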