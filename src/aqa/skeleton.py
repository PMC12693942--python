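"""Read, validate, write and re-center 3D keypoint sequences.

The package uses a fixed 17-joint skeleton in the Human3.6M-style indexing
common to monocular 3D pose lifters: pelvis/hip midpoint at index 0, the
spine chain at 7-10, the left arm at 11-13 and the right arm at 14-16.
Coordinates are unit-agnostic (every downstream feature is an angle or a
ratio of distances), and a missing keypoint is an explicit NaN triple,
never a silent zero.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "JOINT_NAMES",
    "N_KEYPOINTS",
    "SkeletonConvention",
    "KeypointSequence",
    "ValidationError",
    "read_keypoints",
    "write_keypoints",
    "recenter_neck",
]

N_KEYPOINTS = 17

#: index -> joint name for the 17-joint convention.
JOINT_NAMES: dict[int, str] = {
    0: "Hip",
    1: "R-hip",
    2: "R-knee",
    3: "R-foot",
    4: "L-hip",
    5: "L-knee",
    6: "L-foot",
    7: "Spine",
    8: "Thorax",
    9: "Neck",
    10: "Head",
    11: "L-shoulder",
    12: "L-elbow",
    13: "L-wrist",
    14: "R-shoulder",
    15: "R-elbow",
    16: "R-wrist",
}

NECK = 9


class ValidationError(ValueError):
    """A keypoint sequence or file violates the skeleton contract."""


@dataclass(frozen=True)
class SkeletonConvention:
    """A named 17-joint indexing scheme.

    The default is the Human3.6M-style map in :data:`JOINT_NAMES`; the class
    exists so an alternative ordering can be threaded through feature
    construction without editing constants.
    """

    index_to_name: dict[int, str] = field(default_factory=lambda: dict(JOINT_NAMES))

    def __post_init__(self) -> None:
        if sorted(self.index_to_name) != list(range(N_KEYPOINTS)):
            raise ValidationError(
                f"skeleton convention must map indices 0..{N_KEYPOINTS - 1} exactly once"
            )
        names = list(self.index_to_name.values())
        if len(set(names)) != N_KEYPOINTS:
            raise ValidationError("joint names must be unique")

    def name(self, index: int) -> str:
        return self.index_to_name[index]


@dataclass
class KeypointSequence:
    """A motion record: ``n`` frames of 17 keypoints with x/y/z coordinates.

    Parameters
    ----------
    coords
        Array of shape ``(n, 17, 3)``. Missing keypoints are NaN triples.
    fps
        Frames per second, > 0. The frame interval is ``1 / fps`` seconds.
    """

    coords: np.ndarray
    fps: float
    convention: SkeletonConvention = field(default_factory=SkeletonConvention)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_KEYPOINTS, 3):
            raise ValidationError(
                f"coords must have shape (n, {N_KEYPOINTS}, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise ValidationError(
                f"need at least 3 frames (acceleration spans i..i+2), got {self.coords.shape[0]}"
            )
        if not (np.isscalar(self.fps) or np.ndim(self.fps) == 0) or not self.fps > 0:
            raise ValidationError(f"fps must be > 0, got {self.fps!r}")
        self.fps = float(self.fps)
        # a keypoint is either fully present or fully missing (all-NaN triple)
        nan = np.isnan(self.coords)
        partial = nan.any(axis=2) & ~nan.all(axis=2)
        if partial.any():
            f, k = np.argwhere(partial)[0]
            raise ValidationError(
                f"keypoint {k} in frame {f} has a partially-missing coordinate triple"
            )
        if np.isinf(self.coords).any():
            raise ValidationError("coordinates must be finite or NaN (missing)")

    @property
    def n(self) -> int:
        """Frame count."""
        return self.coords.shape[0]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, 17)`` mask, True where a keypoint is missing."""
        return np.isnan(self.coords).all(axis=2)

    def copy(self) -> "KeypointSequence":
        return KeypointSequence(self.coords.copy(), self.fps, self.convention)


# ---------------------------------------------------------------------------
# I/O
#
# JSON schema: {"fps": number, "convention": "h36m17",
#               "frames": [[[x, y, z] * 17], ...]}, missing keypoint = null
#               triple (or [null, null, null]).
# CSV schema:  header "frame,kp,x,y,z", one row per keypoint per frame,
#              empty x/y/z fields for a missing keypoint; fps travels in a
#              "<path>.meta.json" sidecar or is passed explicitly.
# ---------------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("json", "csv"):
            raise ValueError(f"format must be 'json' or 'csv', got {format!r}")
        return format
    return "csv" if path.suffix.lower() == ".csv" else "json"


def read_keypoints(path: str | Path, format: str | None = None, fps: float | None = None) -> KeypointSequence:
    """Read a keypoint sequence from a JSON or CSV file.

    ``format`` defaults from the file extension. For CSV, ``fps`` is taken
    from the ``<path>.meta.json`` sidecar unless passed explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        return _read_json(path)
    return _read_csv(path, fps)


def _read_json(path: Path) -> KeypointSequence:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:  # pragma: no cover - message passthrough
        raise ValidationError(f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    for key in ("fps", "frames"):
        if key not in doc:
            raise ValidationError(f"{path}: missing required key {key!r}")
    frames = doc["frames"]
    coords = np.empty((len(frames), N_KEYPOINTS, 3))
    for f, frame in enumerate(frames):
        if len(frame) != N_KEYPOINTS:
            raise ValidationError(
                f"{path}: frame {f} has {len(frame)} keypoints, expected {N_KEYPOINTS}"
            )
        for k, triple in enumerate(frame):
            if triple is None:
                coords[f, k] = np.nan
                continue
            if len(triple) != 3:
                raise ValidationError(
                    f"{path}: frame {f} keypoint {k} has {len(triple)} coordinates, expected 3"
                )
            coords[f, k] = [math.nan if v is None else float(v) for v in triple]
    return KeypointSequence(coords, float(doc["fps"]))


def _read_csv(path: Path, fps: float | None) -> KeypointSequence:
    if fps is None:
        sidecar = path.with_name(path.name + ".meta.json")
        if not sidecar.exists():
            raise ValidationError(
                f"{path}: CSV input needs fps via the {sidecar.name} sidecar or the fps argument"
            )
        with open(sidecar) as fh:
            fps = float(json.load(fh)["fps"])
    rows: dict[tuple[int, int], tuple[float, float, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"frame", "kp", "x", "y", "z"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: CSV header must contain {sorted(expected)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                f, k = int(row["frame"]), int(row["kp"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{path}: line {lineno}: bad frame/kp index") from exc
            if not 0 <= k < N_KEYPOINTS:
                raise ValidationError(f"{path}: line {lineno}: keypoint index {k} out of range")
            vals = tuple(
                math.nan if row[c] in ("", None) else float(row[c]) for c in ("x", "y", "z")
            )
            rows[(f, k)] = vals
    if not rows:
        raise ValidationError(f"{path}: no keypoint rows")
    n = max(f for f, _ in rows) + 1
    coords = np.full((n, N_KEYPOINTS, 3), np.nan)
    for (f, k), vals in rows.items():
        coords[f, k] = vals
    per_frame = np.zeros(n, dtype=int)
    for f, _ in rows:
        per_frame[f] += 1
    short = np.nonzero(per_frame != N_KEYPOINTS)[0]
    if short.size:
        raise ValidationError(
            f"{path}: frame {short[0]} has {per_frame[short[0]]} keypoint rows, expected {N_KEYPOINTS}"
        )
    return KeypointSequence(coords, fps)


def write_keypoints(seq: KeypointSequence, path: str | Path, format: str | None = None) -> None:
    """Write a sequence so that :func:`read_keypoints` recovers it.

    JSON round-trips exactly (``repr`` floats); CSV round-trips within 1e-9.
    Parent directories are created as needed.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _infer_format(path, format)
    if fmt == "json":
        frames = [
            [None if np.isnan(kp).all() else [float(v) for v in kp] for kp in frame]
            for frame in seq.coords
        ]
        with open(path, "w") as fh:
            json.dump({"fps": seq.fps, "convention": "h36m17", "frames": frames}, fh)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "kp", "x", "y", "z"])
        for f in range(seq.n):
            for k in range(N_KEYPOINTS):
                kp = seq.coords[f, k]
                if np.isnan(kp).all():
                    writer.writerow([f, k, "", "", ""])
                else:
                    writer.writerow([f, k, repr(float(kp[0])), repr(float(kp[1])), repr(float(kp[2]))])
    with open(path.with_name(path.name + ".meta.json"), "w") as fh:
        json.dump({"fps": seq.fps}, fh)


def recenter_neck(seq: KeypointSequence) -> KeypointSequence:
    """Translate every frame so the neck (index 9) sits at the origin.

    All inter-keypoint distances are preserved; the operation is idempotent.
    """
    neck = seq.coords[:, NECK, :]
    bad = np.nonzero(np.isnan(neck).any(axis=1))[0]
    if bad.size:
        raise ValidationError(f"neck keypoint missing in frame {bad[0]}; cannot re-center")
    out = seq.coords - neck[:, None, :]
    out[:, NECK, :] = 0.0  # exact zero, no -0.0/rounding residue
    return KeypointSequence(out, seq.fps, seq.convention)
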