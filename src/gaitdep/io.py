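"""Reading, writing and validating 25-joint skeleton recordings.

A recording is a ``T x 25 x 3`` array of joint positions in meters, captured
at a fixed frame rate in the sensor's coordinate frame: X grows to the
sensor's left, Y grows up, Z grows out from the sensor toward the walker.
Recordings are serialized to a plain-text CSV dialect (one row per
``(frame, joint)`` pair, positions in meters, metadata in ``#`` header
comments) or to an equivalent JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "JOINT_MAP",
    "JOINT_MAP_VERSION",
    "JointMap",
    "SkeletonRecording",
    "SkeletonFormatError",
    "read_recording",
    "write_recording",
    "validate_recording",
]

JOINT_MAP_VERSION = 1

#: Canonical joint-index -> anatomical-role map (1-based indices, Kinect v2
#: style).  Eleven roles are load-bearing for the pipeline (head, neck,
#: clavicle, shoulders, spine, wrists, feet, left toe); the remaining indices
#: carry conventional names and are only passed through.
JOINT_MAP: dict[int, str] = {
    1: "head",
    2: "neck",
    3: "clavicle",
    4: "shoulder_left",
    5: "shoulder_right",
    6: "elbow_left",
    7: "elbow_right",
    8: "spine_mid",
    9: "spine",
    10: "wrist_left",
    11: "hand_left",
    12: "hand_tip_left",
    13: "thumb_left",
    14: "wrist_right",
    15: "hand_right",
    16: "hand_tip_right",
    17: "thumb_right",
    18: "hip_left",
    19: "hip_right",
    20: "knee_left",
    21: "knee_right",
    22: "foot_left",
    23: "foot_right",
    24: "toe_left",
    25: "toe_right",
}

N_JOINTS = 25
AXES = ("x", "y", "z")

_REQUIRED_ROLES = {
    "head": 1,
    "neck": 2,
    "clavicle": 3,
    "shoulder_left": 4,
    "shoulder_right": 5,
    "spine": 9,
    "wrist_left": 10,
    "wrist_right": 14,
    "foot_left": 22,
    "foot_right": 23,
    "toe_left": 24,
}


class SkeletonFormatError(ValueError):
    """Raised for malformed recording files or invalid recordings."""


@dataclass(frozen=True)
class JointMap:
    """Bijective index -> anatomical-role map over joints 1..25."""

    roles: dict[int, str] = field(default_factory=lambda: dict(JOINT_MAP))
    version: int = JOINT_MAP_VERSION

    def __post_init__(self) -> None:
        if set(self.roles) != set(range(1, N_JOINTS + 1)):
            raise SkeletonFormatError("joint map must cover indices 1..25 exactly")
        if len(set(self.roles.values())) != N_JOINTS:
            raise SkeletonFormatError("joint map roles must be unique")
        for role, idx in _REQUIRED_ROLES.items():
            if self.roles.get(idx) != role:
                raise SkeletonFormatError(
                    f"joint {idx} must carry role {role!r}, got {self.roles.get(idx)!r}"
                )

    def index(self, role: str) -> int:
        """Return the 1-based joint index carrying ``role``."""
        for idx, r in self.roles.items():
            if r == role:
                return idx
        raise KeyError(role)


@dataclass
class SkeletonRecording:
    """A skeleton time series: ``T x 25 x 3`` joint positions in meters.

    Parameters
    ----------
    positions
        Array of shape ``(T, 25, 3)``; axis order X, Y, Z.
    frame_rate
        Sampling rate in Hz (the capture protocol records at 30 Hz).
    participant_id
        Free-form identifier.
    group_label
        Optional binary label, 1 = case (depressed), 0 = control.
    coordinate_frame
        ``"sensor"`` for raw captures, ``"spine_relative"`` after the
        spine-origin transform.
    """

    positions: np.ndarray
    frame_rate: float = 30.0
    participant_id: str = ""
    group_label: int | None = None
    coordinate_frame: Literal["sensor", "spine_relative"] = "sensor"
    joint_map: JointMap = field(default_factory=JointMap)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (N_JOINTS, 3):
            raise SkeletonFormatError(
                f"positions must have shape (T, 25, 3), got {self.positions.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def joint(self, role: str) -> np.ndarray:
        """Return the ``T x 3`` trajectory of the joint carrying ``role``."""
        return self.positions[:, self.joint_map.index(role) - 1, :]

    def copy(self, **changes) -> "SkeletonRecording":
        rec = replace(self, **changes)
        if "positions" not in changes:
            rec.positions = self.positions.copy()
        return rec


def _header_dict(rec: SkeletonRecording) -> dict:
    return {
        "frame_rate": rec.frame_rate,
        "joint_map_version": rec.joint_map.version,
        "coordinate_frame": rec.coordinate_frame,
        "participant_id": rec.participant_id,
        "group": "" if rec.group_label is None else int(rec.group_label),
    }


def write_recording(rec: SkeletonRecording, path: str | Path, format: str = "csv") -> Path:
    """Serialize a recording to ``path`` in CSV or JSON.

    Floats are written with 9 significant digits so a write -> read round
    trip preserves positions to well below sensor resolution.
    """
    path = Path(path)
    issues = validate_recording(rec)
    if issues:
        raise SkeletonFormatError(f"refusing to write invalid recording: {issues[0]}")
    if format == "csv":
        lines = [f"# {key}: {value}" for key, value in _header_dict(rec).items()]
        lines.append("frame,joint,x,y,z")
        T = rec.n_frames
        frames = np.repeat(np.arange(T), N_JOINTS)
        joints = np.tile(np.arange(1, N_JOINTS + 1), T)
        flat = rec.positions.reshape(T * N_JOINTS, 3)
        for f, j, (x, y, z) in zip(frames, joints, flat):
            lines.append(f"{f},{j},{x:.9g},{y:.9g},{z:.9g}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        doc = _header_dict(rec)
        doc["positions"] = [
            [[float(f"{v:.9g}") for v in joint] for joint in frame]
            for frame in rec.positions
        ]
        path.write_text(json.dumps(doc))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _parse_header_lines(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def _recording_from_table(df: pd.DataFrame, meta: dict, origin: str) -> SkeletonRecording:
    if "frame_rate" not in meta:
        raise SkeletonFormatError(f"{origin}: header must declare frame_rate")
    frame_rate = float(meta["frame_rate"])
    frames = df["frame"].to_numpy()
    unique_frames = np.unique(frames)
    expected = np.arange(unique_frames.min(), unique_frames.min() + len(unique_frames))
    if not np.array_equal(unique_frames, expected) or unique_frames.min() != 0:
        raise SkeletonFormatError(f"{origin}: frame index not contiguous from 0")
    T = len(unique_frames)
    positions = np.full((T, N_JOINTS, 3), np.nan)
    joints = df["joint"].to_numpy(dtype=int)
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if joints.min() < 1 or joints.max() > N_JOINTS:
        bad = int(np.argmax((joints < 1) | (joints > N_JOINTS)))
        raise SkeletonFormatError(f"{origin}: joint index out of range at row {bad}")
    # detect non-monotone frame order before scattering
    if np.any(np.diff(frames) < 0):
        bad = int(np.argmax(np.diff(frames) < 0)) + 1
        raise SkeletonFormatError(f"{origin}: non-monotone frame index at row {bad}")
    positions[frames, joints - 1, :] = coords
    missing = np.argwhere(np.isnan(positions).all(axis=2))
    if len(missing):
        t, j = missing[0]
        raise SkeletonFormatError(f"{origin}: joint {j + 1} absent in frame {t}")
    if not np.all(np.isfinite(coords)):
        bad = int(np.argmax(~np.isfinite(coords).all(axis=1)))
        raise SkeletonFormatError(f"{origin}: non-finite coordinate at row {bad}")
    group = meta.get("group", "")
    return SkeletonRecording(
        positions=positions,
        frame_rate=frame_rate,
        participant_id=meta.get("participant_id", ""),
        group_label=None if group in ("", "None") else int(group),
        coordinate_frame=meta.get("coordinate_frame", "sensor"),  # type: ignore[arg-type]
    )


def read_recording(path: str | Path, format: str | None = None) -> SkeletonRecording:
    """Read a recording written by :func:`write_recording`.

    ``format`` defaults to the file suffix (``.csv`` or ``.json``).
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    if format == "csv":
        text = path.read_text().splitlines()
        header = [ln for ln in text if ln.startswith("#")]
        meta = _parse_header_lines(header)
        df = pd.read_csv(path, comment="#")
        required = {"frame", "joint", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise SkeletonFormatError(f"{path}: missing columns {required - set(df.columns)}")
        return _recording_from_table(df[["frame", "joint", "x", "y", "z"]], meta, str(path))
    if format == "json":
        doc = json.loads(path.read_text())
        positions = np.asarray(doc.pop("positions"), dtype=float)
        T = positions.shape[0]
        df = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(T), N_JOINTS),
                "joint": np.tile(np.arange(1, N_JOINTS + 1), T),
                "x": positions[:, :, 0].ravel(),
                "y": positions[:, :, 1].ravel(),
                "z": positions[:, :, 2].ravel(),
            }
        )
        return _recording_from_table(df, {k: str(v) for k, v in doc.items()}, str(path))
    raise ValueError(f"unknown format {format!r}")


def validate_recording(rec: SkeletonRecording) -> list[str]:
    """Check recording invariants; return a (possibly empty) list of issues.

    Reports rather than raises: an empty list means the recording is safe for
    every downstream preprocessing and feature operation.
    """
    issues: list[str] = []
    if rec.n_frames < 2:
        issues.append(f"too few frames: T={rec.n_frames} < 2")
    if not rec.frame_rate > 0:
        issues.append("nonpositive frame rate")
    bad = np.argwhere(~np.isfinite(rec.positions))
    for t, j, a in bad[:20]:
        issues.append(
            f"non-finite value at frame {t}, joint {j + 1}, axis {AXES[a].upper()}"
        )
    if len(bad) > 20:
        issues.append(f"... {len(bad) - 20} further non-finite values")
    if rec.coordinate_frame not in ("sensor", "spine_relative"):
        issues.append(f"unknown coordinate frame {rec.coordinate_frame!r}")
    return issues
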