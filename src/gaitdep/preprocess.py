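"""Preprocessing: spine-origin transform, pass splitting, gait-cycle segmentation.

The raw capture is a two-minute back-and-forth walk.  Preprocessing reduces
it to the analysis unit of the whole pipeline: a two-gait-cycle excerpt of
the middle face-toward pass, expressed in spine-relative coordinates and
low-pass filtered with a 5-tap binomial Gaussian kernel.

Stages, in order:

1. :func:`to_spine_relative` — subtract the per-frame spine position so the
   spine joint becomes the origin, removing whole-body translation.  The
   sensor-frame spine Z track is retained; it is the only place walking
   speed can still be measured.
2. :func:`split_walk_passes` — classify maximal runs of smoothed spine-Z
   velocity sign into toward (Z decreasing) and away passes.
3. :func:`select_middle_face_toward` — keep the middle toward pass, away
   from start/end transients.
4. :func:`detect_toe_off_events` — gait cycles start at left-foot toe-off,
   found as local minima (followed by a rise) of the filtered left-toe
   vertical trajectory.
5. :func:`extract_two_cycle_segment` — crop two consecutive cycles from the
   middle of the pass and Gaussian-filter the cropped channels once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, signal

from .io import JointMap, SkeletonRecording

__all__ = [
    "GAUSSIAN_KERNEL",
    "GaussianKernel",
    "WalkPass",
    "GaitSegment",
    "SegmentationError",
    "to_spine_relative",
    "split_walk_passes",
    "select_middle_face_toward",
    "gaussian_filter",
    "detect_toe_off_events",
    "extract_two_cycle_segment",
    "preprocess_recording",
]

#: The 5-tap binomial Gaussian smoothing kernel (1/16)[1, 4, 6, 4, 1].
GAUSSIAN_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


class SegmentationError(RuntimeError):
    """Raised when a recording cannot be segmented into gait cycles."""


@dataclass(frozen=True)
class GaussianKernel:
    """Fixed 5-point Gaussian low-pass kernel; coefficients sum to 1."""

    coefficients: tuple[float, ...] = tuple(GAUSSIAN_KERNEL)

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients)
        if c.shape != (5,) or not np.isclose(c.sum(), 1.0):
            raise ValueError("kernel must have 5 coefficients summing to 1")


@dataclass(frozen=True)
class WalkPass:
    """A maximal single-direction run of frames, ``[start_frame, end_frame)``."""

    start_frame: int
    end_frame: int
    direction: Literal["toward", "away"]

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class GaitSegment:
    """A filtered, spine-relative two-gait-cycle excerpt.

    ``relative_positions`` is ``T' x 25 x 3`` with the spine identically at
    the origin; ``sensor_spine_z`` is the unfiltered sensor-frame spine Z
    over the same frames (for walking speed); ``cycle_boundaries`` are the
    three toe-off frame offsets ``(0, b, T')`` delimiting the two cycles.
    """

    relative_positions: np.ndarray
    sensor_spine_z: np.ndarray
    frame_rate: float
    cycle_boundaries: tuple[int, int, int]
    participant_id: str = ""
    group_label: int | None = None

    def __post_init__(self) -> None:
        b0, b1, b2 = self.cycle_boundaries
        T = self.relative_positions.shape[0]
        if not (b0 == 0 and 0 < b1 < b2 and b2 == T):
            raise ValueError(
                f"cycle_boundaries {self.cycle_boundaries} inconsistent with T'={T}"
            )
        if self.sensor_spine_z.shape != (T,):
            raise ValueError("sensor_spine_z length must match segment length")

    @property
    def n_frames(self) -> int:
        return self.relative_positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def cycle_slices(self) -> tuple[slice, slice]:
        b0, b1, b2 = self.cycle_boundaries
        return slice(b0, b1), slice(b1, b2)

    def joint(self, role: str, joint_map: JointMap | None = None) -> np.ndarray:
        jm = joint_map or JointMap()
        return self.relative_positions[:, jm.index(role) - 1, :]


def to_spine_relative(rec: SkeletonRecording) -> tuple[SkeletonRecording, np.ndarray]:
    """Re-express a recording with the spine joint as the per-frame origin.

    Returns the transformed recording (flagged ``spine_relative``) and the
    retained ``T x 3`` sensor-frame spine trajectory.
    """
    if rec.coordinate_frame != "sensor":
        raise ValueError("recording is already spine-relative")
    spine = rec.joint("spine").copy()
    relative = rec.positions - spine[:, None, :]
    out = rec.copy(positions=relative, coordinate_frame="spine_relative")
    return out, spine


def gaussian_filter(series: np.ndarray, axis: int = 0,
                    kernel: GaussianKernel | None = None,
                    boundary: str = "replicate") -> np.ndarray:
    """Convolve each channel with the 5-tap Gaussian kernel.

    Output length equals input length; boundaries are handled by edge
    replication by default (``boundary`` accepts any :func:`scipy.ndimage
    .convolve1d` mode, replicate = ``"nearest"``).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[axis] < 5:
        raise ValueError("series must have at least 5 samples along the filter axis")
    coeffs = np.asarray((kernel or GaussianKernel()).coefficients)
    mode = {"replicate": "nearest"}.get(boundary, boundary)
    return ndimage.convolve1d(series, coeffs, axis=axis, mode=mode)


def split_walk_passes(rec: SkeletonRecording,
                      sensor_spine: np.ndarray | None = None,
                      min_pass_duration: float = 1.0) -> list[WalkPass]:
    """Split the walk into toward / away passes from spine-Z velocity sign.

    Walking toward the sensor strictly decreases sensor Z under the capture
    axis convention, so maximal runs of negative smoothed velocity are
    toward passes and positive runs are away passes.  Runs shorter than
    ``min_pass_duration`` seconds (spurious flips at turnarounds) are merged
    into their longer neighbor.
    """
    if sensor_spine is not None:
        spine_z = np.asarray(sensor_spine)[:, 2] if sensor_spine.ndim == 2 else np.asarray(sensor_spine)
    elif rec.coordinate_frame == "sensor":
        spine_z = rec.joint("spine")[:, 2]
    else:
        raise ValueError("spine-relative recording requires an explicit sensor spine track")

    # smooth over ~1/3 s before differencing to suppress sensor noise
    win = max(5, int(round(rec.frame_rate / 3)) | 1)
    smooth = ndimage.uniform_filter1d(spine_z, size=win, mode="nearest")
    vel = np.gradient(smooth)
    direction = np.where(vel < 0, -1, 1)

    # run-length encode, then merge short runs into neighbors
    change = np.flatnonzero(np.diff(direction)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(direction)]))
    runs = [[int(s), int(e), int(direction[s])] for s, e in zip(starts, ends)]
    min_len = int(round(min_pass_duration * rec.frame_rate))
    merged = True
    while merged and len(runs) > 1:
        merged = False
        lengths = [e - s for s, e, _ in runs]
        i = int(np.argmin(lengths))
        if lengths[i] < min_len:
            if i == 0:
                runs[1][0] = runs[0][0]
                del runs[0]
            elif i == len(runs) - 1:
                runs[-2][1] = runs[-1][1]
                del runs[-1]
            else:
                # absorb into the longer neighbor, then re-join equal directions
                left, right = runs[i - 1], runs[i + 1]
                target = left if (left[1] - left[0]) >= (right[1] - right[0]) else right
                if target is left:
                    left[1] = runs[i][1]
                else:
                    right[0] = runs[i][0]
                del runs[i]
            # coalesce adjacent same-direction runs
            j = 0
            while j < len(runs) - 1:
                if runs[j][2] == runs[j + 1][2]:
                    runs[j][1] = runs[j + 1][1]
                    del runs[j + 1]
                else:
                    j += 1
            merged = True

    passes = [
        WalkPass(s, e, "toward" if d < 0 else "away") for s, e, d in runs
    ]
    if not any(p.direction == "toward" for p in passes):
        raise SegmentationError("no face-toward pass found")
    return passes


def select_middle_face_toward(passes: Sequence[WalkPass],
                              rec: SkeletonRecording | None = None) -> WalkPass:
    """Return the middle toward pass (of k, the ceil(k/2)-th; ties earlier)."""
    toward = [p for p in passes if p.direction == "toward"]
    if not toward:
        raise SegmentationError("no face-toward pass found")
    k = len(toward)
    return toward[(k + 1) // 2 - 1]


def detect_toe_off_events(left_toe_y: np.ndarray, frame_rate: float,
                          refractory_s: float = 0.5,
                          rise_window_s: float = 0.2) -> list[int]:
    """Find toe-off events: local minima of left-toe Y followed by a rise.

    ``left_toe_y`` should already be Gaussian-filtered.  Events closer than
    ``refractory_s`` are suppressed (keeping the deeper minimum); a candidate
    counts only if the trajectory has risen ``rise_window_s`` later.
    """
    y = np.asarray(left_toe_y, dtype=float)
    if y.size < 5 or np.ptp(y) == 0:
        raise SegmentationError("insufficient gait cycles: flat or too-short trajectory")
    distance = max(1, int(round(refractory_s * frame_rate)))
    # a true toe-off valley spans a sizeable fraction of the lift amplitude;
    # residual filtered noise does not, so demand a quarter of the range
    prominence = 0.25 * np.ptp(y)
    minima, _ = signal.find_peaks(-y, distance=distance, prominence=prominence)
    rise = max(1, int(round(rise_window_s * frame_rate)))
    events = [
        int(i) for i in minima
        if i + rise < len(y) and y[i + rise] > y[i]
    ]
    return events


def extract_two_cycle_segment(rec: SkeletonRecording,
                              interval: WalkPass,
                              events: Sequence[int],
                              sensor_spine_z: np.ndarray,
                              boundary: str = "replicate") -> GaitSegment:
    """Crop two consecutive gait cycles from the middle of a toward pass.

    ``events`` are toe-off frame indices relative to the full recording;
    the three consecutive events nearest the middle of the pass delimit the
    segment.  The cropped spine-relative channels are Gaussian-filtered once
    here; the sensor-frame spine Z is carried unfiltered.
    """
    inside = [e for e in events if interval.start_frame <= e < interval.end_frame]
    if len(inside) < 3:
        raise SegmentationError(
            f"insufficient gait cycles: {len(inside)} toe-off events in pass"
        )
    start_idx = (len(inside) - 3) // 2
    e0, e1, e2 = inside[start_idx : start_idx + 3]
    positions = rec.positions[e0:e2]
    filtered = gaussian_filter(positions, axis=0, boundary=boundary)
    # pin the spine channel exactly at the origin (filtering noise around 0
    # keeps it ~0 anyway; exact zero preserves the frame invariant)
    jm = rec.joint_map
    filtered = filtered.copy()
    filtered[:, jm.index("spine") - 1, :] = 0.0
    return GaitSegment(
        relative_positions=filtered,
        sensor_spine_z=np.asarray(sensor_spine_z[e0:e2], dtype=float),
        frame_rate=rec.frame_rate,
        cycle_boundaries=(0, e1 - e0, e2 - e0),
        participant_id=rec.participant_id,
        group_label=rec.group_label,
    )


def preprocess_recording(rec: SkeletonRecording,
                         min_pass_duration: float = 1.0,
                         boundary: str = "replicate") -> GaitSegment:
    """Run the full preprocessing chain on a sensor-frame recording."""
    relative, spine = to_spine_relative(rec)
    passes = split_walk_passes(rec, sensor_spine=spine,
                               min_pass_duration=min_pass_duration)
    middle = select_middle_face_toward(passes)
    toe_y = relative.joint("toe_left")[:, 1]
    toe_y_smooth = gaussian_filter(toe_y, boundary=boundary)
    events = detect_toe_off_events(toe_y_smooth, rec.frame_rate)
    return extract_two_cycle_segment(relative, middle, events, spine[:, 2],
                                     boundary=boundary)
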