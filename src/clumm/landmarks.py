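"""Pose-landmark feature engineering.

A pose backend (BlazePose-style, 33 landmarks per frame) produces per-frame
landmark records in normalized image coordinates.  This module selects the
ten landmarks of interest (shoulders, elbows, wrists, hips, knees), quantizes
each frame into a 30-element feature vector of (x, y, z) triplets, and stacks
frames into the dataset matrix used by the rest of the pipeline.  Missing or
non-finite landmarks contribute zeros, so every frame maps to a finite,
fixed-length vector regardless of backend behaviour.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: BlazePose indices of the landmarks of interest, in fixed vector order:
#: left/right shoulder, left/right elbow, left/right wrist, left/right hip,
#: left/right knee.
LANDMARKS_OF_INTEREST: tuple[int, ...] = (11, 12, 13, 14, 15, 16, 23, 24, 25, 26)

LANDMARK_NAMES: dict[int, str] = {
    11: "left_shoulder",
    12: "right_shoulder",
    13: "left_elbow",
    14: "right_elbow",
    15: "left_wrist",
    16: "right_wrist",
    23: "left_hip",
    24: "right_hip",
    25: "left_knee",
    26: "right_knee",
}

N_LANDMARKS = len(LANDMARKS_OF_INTEREST)
FEATURE_DIM = 3 * N_LANDMARKS  # (x, y, z) per landmark

#: CSV column names for the 30 coordinates, e.g. ``L11_x``.
COORDINATE_COLUMNS: tuple[str, ...] = tuple(
    f"L{idx}_{axis}" for idx in LANDMARKS_OF_INTEREST for axis in ("x", "y", "z")
)

#: A pose backend maps one image frame to an iterable of Landmark records.
PoseBackend = Callable[[object], Iterable["Landmark"]]


@dataclass(frozen=True)
class Landmark:
    """One body joint estimate in normalized image coordinates."""

    index: int
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    present: bool = True

    def __post_init__(self):
        if not 0 <= self.index <= 32:
            raise ValueError(f"landmark index {self.index} outside [0, 32]")

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def is_usable(self) -> bool:
        return self.present and all(np.isfinite(self.coords))


@dataclass
class FeatureMatrix:
    """An (m, 30) dataset matrix of per-frame feature vectors.

    ``labels`` (when present) aligns one-to-one with rows; ``frame_ids``
    preserves source frame numbering across filtering and round-trips.
    """

    values: np.ndarray
    labels: np.ndarray | None = None
    frame_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    class_names: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != FEATURE_DIM:
            raise ValueError(
                f"feature matrix must be (m, {FEATURE_DIM}); got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.frame_ids is None:
            self.frame_ids = np.arange(len(self.values))
        else:
            self.frame_ids = np.asarray(self.frame_ids, dtype=np.int64)
            if len(self.frame_ids) != len(self.values):
                raise ValueError("frame_ids must align with rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.values):
                raise ValueError("labels must align one-to-one with rows")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def subset(self, rows) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(
            self.values[rows],
            labels=None if self.labels is None else self.labels[rows],
            frame_ids=self.frame_ids[rows],
            class_names=self.class_names,
        )


def select_landmarks(
    frame_landmarks: Sequence[Landmark],
    index_set: Sequence[int] = LANDMARKS_OF_INTEREST,
) -> list[Landmark]:
    """Pick the landmarks of interest from one frame, in ``index_set`` order.

    Indices absent from the frame (or reported with non-finite coordinates)
    come back as absent zero landmarks; duplicate indices in the input signal
    a malformed backend and raise.
    """
    by_index: dict[int, Landmark] = {}
    for lm in frame_landmarks:
        if lm.index in by_index:
            raise ValueError(f"duplicate landmark index {lm.index} in frame")
        by_index[lm.index] = lm
    selected = []
    for idx in index_set:
        lm = by_index.get(idx)
        if lm is None or not lm.is_usable():
            selected.append(Landmark(index=idx, present=False))
        else:
            selected.append(lm)
    return selected


def quantize_frame(selected: Sequence[Landmark], frame_id: int = 0) -> np.ndarray:
    """Concatenate 10 landmarks into the 30-element vector (x1,y1,z1,...).

    Absent landmarks contribute (0, 0, 0), marking missing coordinates.
    """
    if len(selected) != N_LANDMARKS:
        raise ValueError(f"expected {N_LANDMARKS} landmarks, got {len(selected)}")
    del frame_id  # bookkeeping only; the caller tracks row order
    vec = np.zeros(FEATURE_DIM)
    for j, lm in enumerate(selected):
        if lm.is_usable():
            vec[3 * j : 3 * j + 3] = lm.coords
    return vec


def build_feature_matrix(
    frames: Sequence[np.ndarray],
    labels: Sequence | None = None,
    frame_ids: Sequence[int] | None = None,
    class_names: list[str] | None = None,
) -> FeatureMatrix:
    """Stack per-frame feature vectors into the (m, 30) dataset matrix."""
    if len(frames) == 0:
        raise ValueError("cannot build a feature matrix from zero frames")
    rows = [np.asarray(f, dtype=np.float64).ravel() for f in frames]
    lengths = {len(r) for r in rows}
    if lengths != {FEATURE_DIM}:
        raise ValueError(f"ragged or mis-sized rows: lengths {sorted(lengths)}")
    return FeatureMatrix(
        np.vstack(rows),
        labels=None if labels is None else np.asarray(labels),
        frame_ids=None if frame_ids is None else np.asarray(frame_ids),
        class_names=class_names,
    )


def extract_from_frames(
    frame_source: Iterable,
    backend: PoseBackend,
    index_set: Sequence[int] = LANDMARKS_OF_INTEREST,
) -> FeatureMatrix:
    """Run the pose backend over frames and quantize each into a vector.

    A backend exception on a single frame yields an all-missing (zero) row
    with a warning rather than aborting the whole video.
    """
    rows = []
    for frame_id, frame in enumerate(frame_source):
        try:
            landmarks = list(backend(frame))
            selected = select_landmarks(landmarks, index_set)
        except Exception as exc:  # noqa: BLE001 - backend is third-party code
            warnings.warn(
                f"pose backend failed on frame {frame_id} ({exc}); recording all-missing row",
                stacklevel=2,
            )
            selected = [Landmark(index=idx, present=False) for idx in index_set]
        rows.append(quantize_frame(selected, frame_id))
    return build_feature_matrix(rows)


# -- on-disk formats ----------------------------------------------------------


def save_matrix_csv(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write the landmark matrix as CSV: ``frame_id`` + 30 named columns."""
    df = pd.DataFrame(matrix.values, columns=list(COORDINATE_COLUMNS))
    df.insert(0, "frame_id", matrix.frame_ids)
    df.to_csv(path, index=False)


def load_matrix_csv(path: str | Path, labels_path: str | Path | None = None) -> FeatureMatrix:
    # round_trip parsing so save -> load reproduces the matrix bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["frame_id", *COORDINATE_COLUMNS]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected landmark CSV header in {path}")
    labels = None
    if labels_path is not None:
        labels = load_labels_csv(labels_path, df["frame_id"].to_numpy())
    return FeatureMatrix(
        df[list(COORDINATE_COLUMNS)].to_numpy(dtype=np.float64),
        labels=labels,
        frame_ids=df["frame_id"].to_numpy(dtype=np.int64),
    )


def save_labels_csv(matrix: FeatureMatrix, path: str | Path) -> None:
    if matrix.labels is None:
        raise ValueError("matrix has no labels to save")
    pd.DataFrame({"frame_id": matrix.frame_ids, "label": matrix.labels}).to_csv(
        path, index=False
    )


def load_labels_csv(path: str | Path, frame_ids: np.ndarray) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns) != ["frame_id", "label"]:
        raise ValueError(f"unexpected labels CSV header in {path}")
    mapping = dict(zip(df["frame_id"], df["label"]))
    missing = [fid for fid in frame_ids if fid not in mapping]
    if missing:
        raise ValueError(f"labels missing for frame_ids {missing[:5]}...")
    return np.array([mapping[fid] for fid in frame_ids])


def save_matrix_npz(matrix: FeatureMatrix, path: str | Path) -> None:
    """Binary twin of the CSV format (NPZ)."""
    payload = {"values": matrix.values, "frame_ids": matrix.frame_ids}
    if matrix.labels is not None:
        payload["labels"] = matrix.labels
    np.savez(path, **payload)


def load_matrix_npz(path: str | Path) -> FeatureMatrix:
    with np.load(path, allow_pickle=False) as data:
        return FeatureMatrix(
            data["values"],
            labels=data["labels"] if "labels" in data else None,
            frame_ids=data["frame_ids"],
        )
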