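"""Synthetic articulated motion with controllable, known-ground-truth flaws.

Sequences are produced by forward kinematics over a rigid 17-joint skeleton
(fixed bone lengths, unit-vector segment directions), with slow sinusoidal
joint trajectories that mimic the stretching/twisting/balancing character
of mind-body exercise. Perturbations emulate the artifact classes seen in
real pose-lifter output: monotone time warps (tempo differences), amplitude
errors (over/under-shooting the movement), Gaussian coordinate jitter,
isolated single-keypoint displacement spikes (tracking glitches that create
acceleration outliers), and keypoint dropout (occlusion). Every injected
flaw is echoed in a ground-truth record so detection and scoring can be
validated without any real dataset.

The default clip shape — 150 frames at 30 fps (a 5 s clip) — and noise
levels are chosen to resemble consumer-camera pose capture of slow
exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anomaly import DEFAULT_EXCLUDED
from .skeleton import N_KEYPOINTS, KeypointSequence

__all__ = [
    "PerturbationSpec",
    "GroundTruth",
    "PRESETS",
    "canonical_pose",
    "generate_template",
    "perturb",
    "make_pair",
]

DEFAULT_FPS = 30.0
DEFAULT_N_FRAMES = 150

# bone lengths in metres (adult average proportions)
PELVIS_HALF = 0.11
LUMBAR = 0.22
THORACIC = 0.22
CERVICAL = 0.11
HEAD = 0.13
SHOULDER_LAT = 0.19
SHOULDER_UP = 0.05
UPPER_ARM = 0.26
FOREARM = 0.24
THIGH = 0.42
SHANK = 0.40

PRESETS = ("reach", "squat", "flow")

UP = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class PerturbationSpec:
    """Controlled deviations applied to a clean sequence, in order:
    time warp, amplitude scaling, jitter, spikes, dropout.

    ``spike_magnitude`` is a multiple of the keypoint's clean acceleration
    maximum; individual spike sizes are jittered uniformly in [1.0, 1.5] of
    it, since identical-size glitches (unlike real ones) could pool into a
    dense cluster of their own and evade density-based detection.
    """

    time_warp_strength: float = 0.0
    amplitude_error: float = 0.0
    noise_sd: float = 0.0
    n_spikes: int = 0
    spike_magnitude: float = 10.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("time_warp_strength", "amplitude_error", "noise_sd", "spike_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was injected: spike sites, the applied warp, and the spec."""

    injected_spike_locations: list[tuple[int, int]] = field(default_factory=list)
    true_warp: np.ndarray | None = None
    spec: PerturbationSpec | None = None


def _rot(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices, shape (n, 3, 3), unit axis per frame."""
    axis = np.broadcast_to(axis, (len(angle), 3))
    c, s = np.cos(angle), np.sin(angle)
    K = np.zeros((len(angle), 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    eye = np.eye(3)[None]
    outer = axis[:, :, None] * axis[:, None, :]
    return c[:, None, None] * eye + s[:, None, None] * K + (1 - c)[:, None, None] * outer


def _apply(R: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.einsum("nij,nj->ni", R, np.broadcast_to(v, (R.shape[0], 3)))


def _preset_angles(preset: str, tt: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Slow sinusoidal joint-angle trajectories; tt is time in seconds."""

    def osc(amp, freq, phase=0.0, offset=0.0):
        amp = amp * rng.uniform(0.9, 1.1)
        phase = phase + rng.uniform(-0.2, 0.2)
        return offset + amp * np.sin(2 * np.pi * freq * tt + phase)

    z = np.zeros_like(tt)
    if preset == "reach":
        return {
            "yaw": osc(0.10, 0.10),
            "pitch": osc(0.12, 0.15, offset=0.05),
            "elev_l": osc(1.10, 0.15, offset=1.30),
            "elev_r": osc(1.10, 0.15, phase=0.3, offset=1.30),
            "elbow_l": osc(0.35, 0.15, offset=0.45),
            "elbow_r": osc(0.35, 0.15, phase=0.3, offset=0.45),
            "hip_flex": osc(0.08, 0.15, offset=0.05),
            "knee_l": osc(0.06, 0.15, offset=0.08),
            "knee_r": osc(0.06, 0.15, phase=0.2, offset=0.08),
            "sway": osc(0.03, 0.10),
        }
    if preset == "squat":
        return {
            "yaw": z + osc(0.04, 0.08),
            "pitch": osc(0.25, 0.20, offset=0.25),
            "elev_l": z + osc(0.15, 0.20, offset=0.85),
            "elev_r": z + osc(0.15, 0.20, phase=0.1, offset=0.85),
            "elbow_l": z + osc(0.10, 0.20, offset=0.25),
            "elbow_r": z + osc(0.10, 0.20, offset=0.25),
            "hip_flex": osc(0.55, 0.20, offset=0.60),
            "knee_l": osc(0.75, 0.20, offset=0.80),
            "knee_r": osc(0.75, 0.20, offset=0.80),
            "sway": osc(0.02, 0.08),
        }
    if preset == "flow":
        return {
            "yaw": osc(0.55, 0.12),
            "pitch": osc(0.18, 0.17, offset=0.12),
            "elev_l": osc(0.90, 0.12, phase=0.0, offset=1.00),
            "elev_r": osc(0.90, 0.12, phase=np.pi, offset=1.00),
            "elbow_l": osc(0.45, 0.17, offset=0.55),
            "elbow_r": osc(0.45, 0.17, phase=np.pi, offset=0.55),
            "hip_flex": osc(0.25, 0.12, offset=0.25),
            "knee_l": osc(0.30, 0.12, offset=0.35),
            "knee_r": osc(0.30, 0.12, phase=np.pi, offset=0.35),
            "sway": osc(0.05, 0.12),
        }
    raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")


def canonical_pose() -> np.ndarray:
    """One upright neutral frame facing the +y forward axis, shape (17, 3).

    Arms hang slightly away from the trunk and the feet sit under the hips;
    useful as a reference for orientation-feature checks and as a building
    block for hand-constructed poses.
    """
    P = np.zeros((N_KEYPOINTS, 3))
    root = np.array([0.0, 0.0, 0.95])
    right = np.array([1.0, 0.0, 0.0])
    trunk = UP
    P[0] = root
    P[1] = root + PELVIS_HALF * right
    P[4] = root - PELVIS_HALF * right
    P[7] = root + LUMBAR * trunk
    P[8] = P[7] + THORACIC * trunk
    P[9] = P[8] + CERVICAL * trunk
    P[10] = P[9] + HEAD * trunk
    P[11] = P[8] - SHOULDER_LAT * right + SHOULDER_UP * trunk
    P[14] = P[8] + SHOULDER_LAT * right + SHOULDER_UP * trunk
    down_out_l = np.array([-0.25, 0.0, -1.0])
    down_out_l /= np.linalg.norm(down_out_l)
    down_out_r = down_out_l * np.array([-1.0, 1.0, 1.0])
    P[12] = P[11] + UPPER_ARM * down_out_l
    P[13] = P[12] + FOREARM * down_out_l
    P[15] = P[14] + UPPER_ARM * down_out_r
    P[16] = P[15] + FOREARM * down_out_r
    P[2] = P[1] - THIGH * UP
    P[3] = P[2] - SHANK * UP
    P[5] = P[4] - THIGH * UP
    P[6] = P[5] - SHANK * UP
    return P


def generate_template(
    n_frames: int = DEFAULT_N_FRAMES,
    fps: float = DEFAULT_FPS,
    motion_preset: str = "reach",
    seed: int = 0,
) -> KeypointSequence:
    """Generate a rigid-skeleton exercise clip, deterministic per seed.

    The subject faces the +y axis in a z-up world; the seed perturbs
    trajectory amplitudes and phases slightly so seeds give distinct but
    same-style executions.
    """
    if n_frames < 16:
        raise ValueError("n_frames must be >= 16")
    if motion_preset not in PRESETS:
        raise ValueError(f"unknown preset {motion_preset!r}; expected one of {PRESETS}")
    rng = np.random.default_rng(seed)
    tt = np.arange(n_frames) / fps
    ang = _preset_angles(motion_preset, tt, rng)

    yaw = ang["yaw"]
    right = np.column_stack([np.cos(yaw), np.sin(yaw), np.zeros_like(yaw)])
    R_pitch = _rot_about(right, ang["pitch"])
    trunk = np.einsum("nij,j->ni", R_pitch, UP)  # unit, perpendicular to right

    root = np.column_stack([ang["sway"], np.zeros_like(yaw), np.full_like(yaw, 0.95)])
    P = np.empty((n_frames, N_KEYPOINTS, 3))
    P[:, 0] = root
    P[:, 1] = root + PELVIS_HALF * right  # R-hip
    P[:, 4] = root - PELVIS_HALF * right  # L-hip
    P[:, 7] = root + LUMBAR * trunk
    P[:, 8] = P[:, 7] + THORACIC * trunk
    P[:, 9] = P[:, 8] + CERVICAL * trunk
    P[:, 10] = P[:, 9] + HEAD * trunk
    P[:, 11] = P[:, 8] - SHOULDER_LAT * right + SHOULDER_UP * trunk  # L-shoulder
    P[:, 14] = P[:, 8] + SHOULDER_LAT * right + SHOULDER_UP * trunk  # R-shoulder

    down = -trunk
    for side, sh, el, wr, elev, flex in (
        (-1.0, 11, 12, 13, ang["elev_l"], ang["elbow_l"]),
        (+1.0, 14, 15, 16, ang["elev_r"], ang["elbow_r"]),
    ):
        # raise the arm forward (about the body's right axis), flex the elbow
        upper = np.einsum("nij,nj->ni", _rot_about(right, -elev), down)
        fore = np.einsum("nij,nj->ni", _rot_about(right, -flex), upper)
        P[:, el] = P[:, sh] + UPPER_ARM * upper
        P[:, wr] = P[:, el] + FOREARM * fore

    for hip, kn, ft, knee in ((1, 2, 3, ang["knee_r"]), (4, 5, 6, ang["knee_l"])):
        thigh = np.einsum("nij,nj->ni", _rot_about(right, -ang["hip_flex"]), -UP[None].repeat(n_frames, 0))
        shank = np.einsum("nij,nj->ni", _rot_about(right, knee), thigh)
        P[:, kn] = P[:, hip] + THIGH * thigh
        P[:, ft] = P[:, kn] + SHANK * shank

    return KeypointSequence(P, fps)


def _rot_about(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    angle = np.asarray(angle, dtype=float)
    return _rot(axis, angle)


def _monotone_warp(n: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Frame re-indexing tau in [0, n-1], strictly monotone."""
    s = np.linspace(0.0, 1.0, n)
    w = min(strength, 0.95) * rng.uniform(0.6, 1.0)
    phase = rng.uniform(0, 2 * np.pi)
    u = s + w * np.sin(np.pi * s) * np.sin(2 * np.pi * s + phase) / (2 * np.pi)
    u = np.maximum.accumulate(u)
    u = (u - u[0]) / (u[-1] - u[0])
    return u * (n - 1)


def perturb(seq: KeypointSequence, spec: PerturbationSpec) -> tuple[KeypointSequence, GroundTruth]:
    """Apply a :class:`PerturbationSpec` and report exactly what was done."""
    rng = np.random.default_rng(spec.seed)
    coords = seq.coords.copy()
    n = len(coords)
    gt = GroundTruth(spec=spec)

    if spec.time_warp_strength > 0:
        tau = _monotone_warp(n, spec.time_warp_strength, rng)
        lo = np.floor(tau).astype(int)
        hi = np.minimum(lo + 1, n - 1)
        frac = (tau - lo)[:, None, None]
        coords = (1 - frac) * coords[lo] + frac * coords[hi]
        gt.true_warp = tau

    if spec.amplitude_error > 0:
        mean_pose = coords.mean(axis=0, keepdims=True)
        coords = mean_pose + (1.0 + spec.amplitude_error) * (coords - mean_pose)

    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, coords.shape)

    if spec.n_spikes > 0:
        candidates = [k for k in range(N_KEYPOINTS) if k not in DEFAULT_EXCLUDED]
        time2 = 1.0 / seq.fps**2
        frames: list[int] = []
        pool = list(range(2, n - 2))
        rng.shuffle(pool)
        for f in pool:  # spikes kept >= 4 frames apart so outliers stay isolated
            if all(abs(f - g) >= 4 for g in frames):
                frames.append(f)
            if len(frames) == spec.n_spikes:
                break
        if len(frames) < spec.n_spikes:
            raise ValueError(f"sequence too short for {spec.n_spikes} isolated spikes")
        pre_spike = coords.copy()  # spike sizes scale with the *clean* acceleration range
        for f in frames:
            kp = int(rng.choice(candidates))
            pts = pre_spike[:, kp, :]
            clean_acc = np.linalg.norm(pts[2:] - pts[:-2], axis=1).max() / time2
            size = spec.spike_magnitude * rng.uniform(1.0, 1.5) * clean_acc * time2
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords[f, kp] += size * direction
            gt.injected_spike_locations.append((f, kp))

    if spec.dropout_rate > 0:
        drop = rng.random((n, N_KEYPOINTS)) < spec.dropout_rate
        drop[0] = False  # keep frame 0 complete so carry-forward imputation works
        coords[drop] = np.nan

    return KeypointSequence(coords, seq.fps, seq.convention), gt


#: Perturbation profiles of the pair scenarios (the study conditions).
SCENARIO_SPECS: dict[str, PerturbationSpec] = {
    "perfect": PerturbationSpec(),
    "cheat_copy": PerturbationSpec(),
    "noisy": PerturbationSpec(noise_sd=0.005, amplitude_error=0.05),
    "warped": PerturbationSpec(time_warp_strength=0.3),
    "wrong_action": PerturbationSpec(),
}


def make_pair(
    scenario: str,
    n_frames: int = DEFAULT_N_FRAMES,
    seed: int = 0,
    fps: float = DEFAULT_FPS,
    motion_preset: str = "reach",
) -> tuple[KeypointSequence, KeypointSequence, GroundTruth]:
    """A (template, test, ground-truth) triple for a named scenario.

    ``perfect``/``cheat_copy`` are identical copies (the latter is what the
    anti-cheat rule should flag); ``noisy``/``warped`` perturb the same
    motion; ``wrong_action`` pairs two different presets.
    """
    if scenario not in SCENARIO_SPECS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIO_SPECS)}")
    template = generate_template(n_frames, fps, motion_preset, seed)
    if scenario == "wrong_action":
        other = next(p for p in PRESETS if p != motion_preset)
        test = generate_template(n_frames, fps, other, seed + 1)
        return template, test, GroundTruth(spec=SCENARIO_SPECS[scenario])
    spec = replace(SCENARIO_SPECS[scenario], seed=seed + 1)
    if scenario in ("perfect", "cheat_copy"):
        return template, template.copy(), GroundTruth(spec=spec)
    test, gt = perturb(template, spec)
    return template, test, gt
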