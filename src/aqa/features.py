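"""Kinematic feature construction from 17-joint keypoint sequences.

Each frame is summarised by a 27-dimensional angle vector

``F = [theta_1..theta_11, P_1..P_4, alpha_1..alpha_4, beta_1..beta_4, gamma_1..gamma_4]``

where

* ``theta`` are 11 joint angles at named skeletal triples (neck, trunk,
  shoulders, elbows, hips, knees), each the angle at a hinge vertex between
  the vectors to its two neighbouring joints;
* ``P`` / ``alpha`` are spatial angles between the spine vector and the
  vector from a reference point (hip for ``P``, neck for ``alpha``) to the
  geometric centre of each of four limb blocks;
* ``beta`` are body-orientation and opening features: continuous radian
  orientations of the shoulder and hip lines (forward-facing mapped to
  1.5*pi, reverse to 0.5*pi) and two binary opening angles for the feet and
  hands taking values in {0.5*pi, 1.5*pi};
* ``gamma`` are four contralateral limb angles (forearm vs. shank pairs).

All features are translation-invariant; ``theta``/``P``/``alpha``/``gamma``
are additionally rotation-invariant while ``beta_1``/``beta_2`` rotate with
the body by design. The module also provides the per-keypoint acceleration
series used by anomaly detection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .skeleton import NECK, KeypointSequence, recenter_neck

__all__ = [
    "FEATURE_NAMES",
    "JOINT_ANGLE_TRIPLES",
    "LIMB_BLOCKS",
    "CONTRALATERAL_PAIRS",
    "FeatureSequence",
    "AccelerationSeries",
    "DegenerateGeometryError",
    "angle_between",
    "compute_joint_angles",
    "limb_block_center",
    "limb_block_features",
    "orientation_features",
    "contralateral_angles",
    "build_features",
    "compute_acceleration",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES: list[str] = (
    [f"theta_{i}" for i in range(1, 12)]
    + [f"P_{i}" for i in range(1, 5)]
    + [f"alpha_{i}" for i in range(1, 5)]
    + [f"beta_{i}" for i in range(1, 5)]
    + [f"gamma_{i}" for i in range(1, 5)]
)

#: (vertex, end_a, end_b) keypoint triples for the 11 joint angles, ordered
#: I..XI. The vertex is the anatomical hinge of each triple (neck/thorax/hip
#: for the axial rows, elbow and knee for the limb rows), so a straight limb
#: reads pi and a right-angle bend reads pi/2.
JOINT_ANGLE_TRIPLES: list[tuple[int, int, int]] = [
    (9, 8, 14),   # I    neck:   thorax vs R-shoulder
    (0, 8, 14),   # II   hip:    thorax vs R-shoulder
    (8, 14, 15),  # III  thorax: R-shoulder vs R-elbow
    (15, 14, 16), # IV   R-elbow flexion
    (9, 11, 12),  # V    neck:   L-shoulder vs L-elbow
    (12, 11, 13), # VI   L-elbow flexion
    (8, 0, 1),    # VII  thorax: hip vs R-hip
    (0, 1, 2),    # VIII hip:    R-hip vs R-knee
    (2, 1, 3),    # IX   R-knee flexion
    (0, 4, 5),    # X    hip:    L-hip vs L-knee
    (5, 4, 6),    # XI   L-knee flexion
]

#: Limb-block keypoint index sets. The printed block names pair "left arm"
#: with indices 14-16 and "right arm" with 11-13, the opposite of the joint
#: labels; the printed sets are kept verbatim and remain configurable via
#: the ``blocks`` argument of the block operations.
LIMB_BLOCKS: dict[str, tuple[int, int, int, int]] = {
    "left_arm": (8, 14, 15, 16),
    "right_arm": (8, 11, 12, 13),
    "left_leg": (0, 1, 2, 3),
    "right_leg": (0, 4, 5, 6),
}

BLOCK_ORDER = ("left_arm", "right_arm", "left_leg", "right_leg")

#: Contralateral (forearm, shank) vector pairs for gamma_1..gamma_4: the two
#: printed same-side pairs followed by the two cross-side completions.
CONTRALATERAL_PAIRS: list[tuple[tuple[int, int], tuple[int, int]]] = [
    ((15, 16), (2, 3)),
    ((12, 13), (5, 6)),
    ((15, 16), (5, 6)),
    ((12, 13), (2, 3)),
]

HIP, SPINE, THORAX = 0, 7, 8
L_SHOULDER, R_SHOULDER = 11, 14
L_WRIST, R_WRIST = 13, 16
L_FOOT, R_FOOT = 6, 3
R_HIP, L_HIP = 1, 4

UP = np.array([0.0, 0.0, 1.0])
FORWARD_DEFAULT = np.array([0.0, 1.0, 0.0])


class DegenerateGeometryError(ValueError):
    """An angle is undefined because an input vector has zero length."""


def _angle(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle between vectors along the last axis; NaN where degenerate."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("...i,...i->...", v1, v2) / (n1 * n2)
    cos = np.clip(cos, -1.0, 1.0)
    return np.where((n1 == 0) | (n2 == 0), np.nan, np.arccos(cos))


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in radians between two nonzero 3-vectors, in [0, pi].

    The normalized dot product is clamped to [-1, 1] before ``arccos`` so
    floating-point round-off never produces NaN.
    """
    out = _angle(v1, v2)
    if np.isnan(out).any():
        raise DegenerateGeometryError("angle undefined for a zero-length vector")
    return float(out) if np.ndim(out) == 0 else out


def compute_joint_angles(frame: np.ndarray, triples=None) -> np.ndarray:
    """The 11 joint angles theta_1..theta_11 of a single ``(17, 3)`` frame.

    Degenerate triples (coincident keypoints) yield NaN rather than raising,
    so callers can impute.
    """
    return _joint_angles(np.asarray(frame, dtype=float)[None], triples)[0]


def _joint_angles(coords: np.ndarray, triples=None) -> np.ndarray:
    triples = JOINT_ANGLE_TRIPLES if triples is None else triples
    out = np.empty((coords.shape[0], len(triples)))
    for k, (b, a, c) in enumerate(triples):
        out[:, k] = _angle(coords[:, a] - coords[:, b], coords[:, c] - coords[:, b])
    return out


def limb_block_center(frame: np.ndarray, block: str, blocks=None) -> np.ndarray:
    """Geometric centre (coordinate mean) of a 4-keypoint limb block."""
    blocks = LIMB_BLOCKS if blocks is None else blocks
    if block not in blocks:
        raise KeyError(f"unknown limb block {block!r}; expected one of {sorted(blocks)}")
    frame = np.asarray(frame, dtype=float)
    idx = list(blocks[block])
    if np.isnan(frame[..., idx, :]).any():
        raise ValueError(f"limb block {block!r} has a missing keypoint")
    return frame[..., idx, :].mean(axis=-2)


def limb_block_features(frame: np.ndarray, blocks=None) -> tuple[np.ndarray, np.ndarray]:
    """Spatial limb-block angles ``(P, alpha)`` of a single frame.

    With ``M`` the spine vector (hip -> thorax) and ``p0`` a block centre,
    ``P = angle(M, hip -> p0)`` and ``alpha = angle(M, neck -> p0)``.
    """
    P, alpha = _limb_block(np.asarray(frame, dtype=float)[None], blocks)
    if np.isnan(P).any() or np.isnan(alpha).any():
        raise DegenerateGeometryError("degenerate spine vector or block centre")
    return P[0], alpha[0]


def _limb_block(coords: np.ndarray, blocks=None) -> tuple[np.ndarray, np.ndarray]:
    blocks = LIMB_BLOCKS if blocks is None else blocks
    M = coords[:, THORAX] - coords[:, HIP]
    P = np.empty((coords.shape[0], len(BLOCK_ORDER)))
    alpha = np.empty_like(P)
    for k, name in enumerate(BLOCK_ORDER):
        idx = list(blocks[name])
        p0 = coords[:, idx, :].mean(axis=1)
        P[:, k] = _angle(M, p0 - coords[:, HIP])
        alpha[:, k] = _angle(M, p0 - coords[:, NECK])
    return P, alpha


def _line_orientation(line_vec: np.ndarray, forward: np.ndarray) -> np.ndarray:
    """Continuous radian orientation of a body line.

    The facing normal is ``up x line_vec`` (line taken left joint -> right
    joint) projected onto the horizontal plane; the returned value is
    ``(1.5*pi - signed_angle(forward, facing)) mod 2*pi`` so that facing the
    configured forward axis reads exactly 1.5*pi and facing away 0.5*pi.
    """
    facing = np.cross(UP, line_vec)
    facing[..., 2] = 0.0
    norm = np.linalg.norm(facing, axis=-1)
    s = np.arctan2(
        np.einsum("...i,...i->...", np.cross(forward, facing), UP),
        np.einsum("...i,...i->...", facing, forward),
    )
    beta = np.mod(1.5 * np.pi - s, 2.0 * np.pi)
    return np.where(norm == 0, np.nan, beta)


def orientation_features(frame: np.ndarray, forward_axis=None) -> np.ndarray:
    """Orientation/opening features ``(beta_1..beta_4)`` of a single frame.

    ``beta_1``/``beta_2`` are the shoulder-line and hip-line orientations
    (both lines taken left -> right so that a forward-facing pose yields
    1.5*pi for both). ``beta_3`` is 1.5*pi when the feet are more than 0.5
    shoulder-widths apart, else 0.5*pi; ``beta_4`` likewise for the wrists
    at 1.5 shoulder-widths. Both thresholds are strict inequalities.
    """
    out = _orientation(np.asarray(frame, dtype=float)[None], forward_axis)[0]
    if np.isnan(out[2:]).any():
        raise DegenerateGeometryError("zero shoulder width: opening angles undefined")
    return out


def _orientation(coords: np.ndarray, forward_axis=None) -> np.ndarray:
    forward = FORWARD_DEFAULT if forward_axis is None else np.asarray(forward_axis, float)
    out = np.empty((coords.shape[0], 4))
    out[:, 0] = _line_orientation(coords[:, R_SHOULDER] - coords[:, L_SHOULDER], forward)
    out[:, 1] = _line_orientation(coords[:, R_HIP] - coords[:, L_HIP], forward)
    shoulder_w = np.linalg.norm(coords[:, L_SHOULDER] - coords[:, R_SHOULDER], axis=-1)
    feet = np.linalg.norm(coords[:, L_FOOT] - coords[:, R_FOOT], axis=-1)
    hands = np.linalg.norm(coords[:, L_WRIST] - coords[:, R_WRIST], axis=-1)
    out[:, 2] = np.where(feet > 0.5 * shoulder_w, 1.5 * np.pi, 0.5 * np.pi)
    out[:, 3] = np.where(hands > 1.5 * shoulder_w, 1.5 * np.pi, 0.5 * np.pi)
    out[:, 2:] = np.where(shoulder_w[:, None] == 0, np.nan, out[:, 2:])
    return out


def contralateral_angles(frame: np.ndarray, pairs=None) -> np.ndarray:
    """Contralateral limb angles ``gamma_1..gamma_4`` of a single frame."""
    return _contralateral(np.asarray(frame, dtype=float)[None], pairs)[0]


def _contralateral(coords: np.ndarray, pairs=None) -> np.ndarray:
    pairs = CONTRALATERAL_PAIRS if pairs is None else pairs
    out = np.empty((coords.shape[0], len(pairs)))
    for k, ((a1, a2), (b1, b2)) in enumerate(pairs):
        out[:, k] = _angle(coords[:, a2] - coords[:, a1], coords[:, b2] - coords[:, b1])
    return out


@dataclass
class FeatureSequence:
    """Per-frame 27-D kinematic feature matrix with its source frame rate."""

    values: np.ndarray
    fps: float
    names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D (n, d) array")

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class AccelerationSeries:
    """Non-negative accelerations of one keypoint, length ``n - 2``."""

    keypoint_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _impute_carry_forward(coords: np.ndarray) -> np.ndarray:
    """Replace missing keypoints by the previous frame's coordinates."""
    missing = np.isnan(coords).all(axis=2)
    if not missing.any():
        return coords
    first_bad = np.nonzero(missing[0])[0]
    if first_bad.size:
        raise ValueError(
            f"keypoint {first_bad[0]} missing in frame 0: carry-forward imputation "
            "has no earlier frame to copy from"
        )
    out = coords.copy()
    for f in range(1, out.shape[0]):
        gone = missing[f]
        if gone.any():
            out[f, gone] = out[f - 1, gone]
    return out


def _fill_degenerate(values: np.ndarray) -> np.ndarray:
    """Carry forward the previous frame's value over NaN entries.

    A NaN in the first frame becomes 0 with a warning (nothing earlier to
    copy); this keeps NaN out of the downstream alignment cost matrix.
    """
    if not np.isnan(values).any():
        return values
    out = values.copy()
    if np.isnan(out[0]).any():
        warnings.warn("degenerate geometry in first frame; affected features set to 0")
        out[0] = np.nan_to_num(out[0], nan=0.0)
    for f in range(1, out.shape[0]):
        bad = np.isnan(out[f])
        if bad.any():
            out[f, bad] = out[f - 1, bad]
    return out


def build_features(
    seq: KeypointSequence,
    forward_axis=None,
    impute_missing: bool = True,
    blocks=None,
) -> FeatureSequence:
    """Construct the 27-D feature sequence ``[theta, P, alpha, beta, gamma]``.

    The skeleton is re-centered on the neck first (features are angles, so
    this is a no-op numerically, but it fixes the working frame). Missing
    keypoints are imputed by previous-frame carry-forward when
    ``impute_missing`` is on (default); degenerate per-frame angles are
    likewise carried forward.
    """
    coords = seq.coords
    if np.isnan(coords).any():
        if not impute_missing:
            bad = np.nonzero(np.isnan(coords).all(axis=2).any(axis=1))[0]
            raise ValueError(f"frame {bad[0]} has missing keypoints and imputation is off")
        coords = _impute_carry_forward(coords)
    coords = recenter_neck(KeypointSequence(coords, seq.fps, seq.convention)).coords
    theta = _joint_angles(coords)
    P, alpha = _limb_block(coords, blocks)
    beta = _orientation(coords, forward_axis)
    gamma = _contralateral(coords)
    values = np.concatenate([theta, P, alpha, beta, gamma], axis=1)
    return FeatureSequence(_fill_degenerate(values), seq.fps)


def compute_acceleration(seq: KeypointSequence, keypoint: int) -> AccelerationSeries:
    """Two-frame-span acceleration magnitudes of one keypoint.

    ``values[i] = ||coords[i+2, kp] - coords[i, kp]|| / time^2`` for
    ``i = 0..n-3`` with ``time = 1 / fps``; the motion over each two-frame
    span is treated as uniform. Length is always ``n - 2``.
    """
    if not 0 <= keypoint < seq.coords.shape[1]:
        raise IndexError(f"keypoint index {keypoint} out of range")
    pts = seq.coords[:, keypoint, :]
    disp = np.linalg.norm(pts[2:] - pts[:-2], axis=1)
    return AccelerationSeries(keypoint, disp * seq.fps**2)
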