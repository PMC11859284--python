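"""Synthetic pose-landmark data with the structure the pipeline assumes.

The generator emulates what a pose backend would emit for a person performing
one of a small set of workplace motions in front of a fixed camera: smooth,
phase-parameterized trajectories of the ten landmarks of interest in
normalized image coordinates (y grows downward), corrupted by Gaussian
per-coordinate estimation noise and by whole-landmark dropout (a backend
losing a joint reports it missing, which quantizes to a zero triplet).

Three built-in motion classes mirror a manual-handling task set:

* ``idle`` — standing with small postural sway, arms hanging;
* ``lift`` — a cyclic crouch, grasp at knee height, raise to chest;
* ``bend`` — cyclic forward trunk flexion with hanging arms.

All three pass near a neutral standing posture at the cycle end-points, so
classes are close but not identical there — the kind of overlap real motion
data exhibits.  An ``overhead_reach`` motion (arms raised above the head,
a posture none of the three classes visits) is provided as the default
outlier motion for contamination experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .landmarks import FEATURE_DIM, N_LANDMARKS, FeatureMatrix, build_feature_matrix

__all__ = [
    "MotionClassSpec",
    "SyntheticDatasetConfig",
    "motion_class",
    "default_classes",
    "outlier_class",
    "generate_sequence",
    "generate_dataset",
    "inject_outliers",
]

# Neutral standing pose: rows follow the landmark-of-interest order
# (L/R shoulder, L/R elbow, L/R wrist, L/R hip, L/R knee); columns (x, y, z).
_STAND = np.array(
    [
        [0.44, 0.30, -0.02],
        [0.56, 0.30, 0.02],
        [0.42, 0.43, -0.03],
        [0.58, 0.43, 0.03],
        [0.41, 0.55, -0.04],
        [0.59, 0.55, 0.04],
        [0.46, 0.55, -0.02],
        [0.54, 0.55, 0.02],
        [0.46, 0.72, -0.02],
        [0.54, 0.72, 0.02],
    ]
)


def _cycle(phase: float) -> float:
    """Cosine-eased progress through one motion cycle, 0 -> 1 -> 0."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


def _idle(phase: float) -> np.ndarray:
    pose = _STAND.copy()
    sway = 0.012 * np.sin(2.0 * np.pi * phase)
    pose[:, 0] += sway
    # slight relaxed arm drift, out of phase with the sway
    pose[2:6, 1] += 0.006 * np.sin(4.0 * np.pi * phase)
    return pose


# Crouched grasp posture (cycle start) and chest-height carry (cycle peak),
# expressed as offsets from the neutral stand.
_LIFT_CROUCH = np.array(
    [
        [0.02, 0.14, -0.05],
        [-0.02, 0.14, 0.05],
        [0.03, 0.16, -0.07],
        [-0.03, 0.16, 0.07],
        [0.05, 0.17, -0.09],  # wrists reach the box at knee height
        [-0.05, 0.17, 0.09],
        [0.00, 0.10, -0.02],  # hips drop into the squat
        [0.00, 0.10, 0.02],
        [0.02, 0.00, -0.04],  # knees track forward
        [-0.02, 0.00, 0.04],
    ]
)
_LIFT_CARRY = np.array(
    [
        [0.00, -0.01, -0.02],
        [0.00, -0.01, 0.02],
        [0.03, -0.06, -0.06],
        [-0.03, -0.06, 0.06],
        [0.05, -0.17, -0.08],  # wrists up to chest height
        [-0.05, -0.17, 0.08],
        [0.00, 0.00, 0.00],
        [0.00, 0.00, 0.00],
        [0.00, 0.00, 0.00],
        [0.00, 0.00, 0.00],
    ]
)


def _lift(phase: float) -> np.ndarray:
    u = _cycle(phase)
    return _STAND + (1.0 - u) * _LIFT_CROUCH + u * _LIFT_CARRY


def _bend(phase: float) -> np.ndarray:
    # continuous bending work oscillates between mild and deep trunk flexion;
    # the trunk never fully straightens, keeping the class distinct from idle
    u = 0.35 + 0.65 * _cycle(phase)
    pose = _STAND.copy()
    # trunk flexion: shoulders travel forward (+x) and down; arms hang after
    pose[0:2] += u * np.array([0.08, 0.20, 0.0])
    pose[2:4] += u * np.array([0.10, 0.17, 0.0])
    pose[4:6] += u * np.array([0.11, 0.14, 0.0])
    # hips hinge back slightly, knees near-static
    pose[6:8] += u * np.array([-0.04, -0.01, 0.0])
    pose[8:10] += u * np.array([-0.01, 0.00, 0.0])
    return pose


def _overhead_reach(phase: float) -> np.ndarray:
    u = _cycle(phase)
    pose = _STAND.copy()
    # arms swing overhead: wrists well above the shoulders, elbows high
    pose[2:4] += np.array([0.0, -0.23 - 0.05 * u, 0.0]) * [1, 1, 1]
    pose[2, 0] -= 0.04
    pose[3, 0] += 0.04
    pose[4:6, 1] = 0.12 - 0.04 * u
    pose[4, 0] = 0.40
    pose[5, 0] = 0.60
    # up on the toes: whole body rises a little
    pose[:, 1] -= 0.02 * u
    return pose


_PROTOTYPES: dict[str, Callable[[float], np.ndarray]] = {
    "idle": _idle,
    "lift": _lift,
    "bend": _bend,
    "overhead_reach": _overhead_reach,
}


@dataclass(frozen=True)
class MotionClassSpec:
    """One motion class: a phase-parameterized pose trajectory plus noise.

    ``prototype`` maps phase in [0, 1] to a (10, 3) landmark array;
    ``noise_sd`` is the per-coordinate Gaussian estimation noise (normalized
    image units); ``dropout_rate`` the probability that a whole landmark
    triplet is lost for a frame.
    """

    name: str
    prototype: Callable[[float], np.ndarray]
    noise_sd: float = 0.02
    dropout_rate: float = 0.05

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")


def motion_class(name: str, noise_sd: float = 0.02, dropout_rate: float = 0.05) -> MotionClassSpec:
    """Look up a built-in motion prototype by name."""
    try:
        proto = _PROTOTYPES[name]
    except KeyError:
        raise ValueError(f"unknown motion class {name!r}; known: {sorted(_PROTOTYPES)}")
    return MotionClassSpec(name=name, prototype=proto, noise_sd=noise_sd, dropout_rate=dropout_rate)


def default_classes(noise_sd: float = 0.02, dropout_rate: float = 0.05) -> list[MotionClassSpec]:
    """The idle / lift / bend class set at the default noise conditions."""
    return [motion_class(n, noise_sd, dropout_rate) for n in ("idle", "lift", "bend")]


def outlier_class(noise_sd: float = 0.02, dropout_rate: float = 0.05) -> MotionClassSpec:
    """Default out-of-distribution motion (overhead reach)."""
    return motion_class("overhead_reach", noise_sd, dropout_rate)


@dataclass
class SyntheticDatasetConfig:
    classes: list[MotionClassSpec] = field(default_factory=default_classes)
    frames_per_class: int = 200
    seed: int = 0
    outlier_spec: MotionClassSpec | None = None
    n_outliers: int = 0

    def __post_init__(self):
        if self.frames_per_class <= 0:
            raise ValueError("frames_per_class must be positive")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 motion classes")
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")
        if self.n_outliers > 0 and self.outlier_spec is None:
            self.outlier_spec = outlier_class()


def generate_sequence(
    spec: MotionClassSpec, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n_frames`` feature vectors from one motion class.

    Frame t sits at phase t / n_frames; noise is added per coordinate, then
    whole landmark triplets are independently zeroed with the dropout rate
    (mirroring how quantization encodes missing joints).
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    frames = np.empty((n_frames, FEATURE_DIM))
    for t in range(n_frames):
        # copy: dropout mutates the pose, prototypes may return shared arrays
        pose = np.array(spec.prototype(t / n_frames), dtype=np.float64)
        if pose.shape != (N_LANDMARKS, 3) or not np.isfinite(pose).all():
            raise ValueError(f"prototype for {spec.name!r} returned invalid pose")
        if spec.noise_sd > 0:
            pose = pose + rng.normal(0.0, spec.noise_sd, size=pose.shape)
        if spec.dropout_rate > 0:
            dropped = rng.random(N_LANDMARKS) < spec.dropout_rate
            pose[dropped] = 0.0
        frames[t] = pose.ravel()
    return frames


def generate_dataset(config: SyntheticDatasetConfig) -> FeatureMatrix:
    """Generate a labeled dataset: ``frames_per_class`` rows per class.

    Deterministic given the config seed; each class draws from its own
    spawned random stream so class blocks are independent.
    """
    seq = np.random.SeedSequence(config.seed)
    streams = seq.spawn(len(config.classes))
    blocks, labels = [], []
    for spec, stream in zip(config.classes, streams):
        rng = np.random.default_rng(stream)
        blocks.append(generate_sequence(spec, config.frames_per_class, rng))
        labels.extend([spec.name] * config.frames_per_class)
    matrix = build_feature_matrix(
        np.vstack(blocks),
        labels=labels,
        class_names=[c.name for c in config.classes],
    )
    if config.n_outliers > 0:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x0DD)))
        matrix, _ = inject_outliers(matrix, config.outlier_spec, config.n_outliers, rng)
    return matrix


def inject_outliers(
    matrix: FeatureMatrix,
    outlier_spec: MotionClassSpec,
    n_outliers: int,
    rng: np.random.Generator,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Append ``n_outliers`` rows of an out-of-distribution motion.

    Returns the augmented matrix and a boolean mask over its rows marking
    the injected outliers (the contamination indicator).
    """
    if n_outliers < 0:
        raise ValueError("n_outliers must be >= 0")
    if n_outliers == 0:
        mask = np.zeros(len(matrix), dtype=bool)
        return matrix, mask
    extra = generate_sequence(outlier_spec, n_outliers, rng)
    values = np.vstack([matrix.values, extra])
    labels = None
    if matrix.labels is not None:
        labels = np.concatenate([matrix.labels, [outlier_spec.name] * n_outliers])
    next_id = matrix.frame_ids.max() + 1 if len(matrix) else 0
    frame_ids = np.concatenate(
        [matrix.frame_ids, np.arange(next_id, next_id + n_outliers)]
    )
    out = FeatureMatrix(values, labels=labels, frame_ids=frame_ids, class_names=matrix.class_names)
    mask = np.zeros(len(out), dtype=bool)
    mask[len(matrix) :] = True
    return out, mask
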