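"""The three gait feature banks: spatiotemporal, time-domain, frequency-domain.

Every valid two-cycle segment yields exactly 10 + 300 + 825 named features:

* 10 spatiotemporal features — interpretable stride-level quantities (body
  sway, arm swing, head movement and posture, stride length, toe clearance,
  walking speed), computed per gait cycle and averaged over the two cycles;
* 300 time-domain features — mean, SD, skewness and excess kurtosis of each
  of the 75 joint-axis channels (3 axes x 25 joints x 4 statistics);
* 825 frequency-domain features — per channel, the DC component (signal
  mean) plus mean, variance, SD, skewness and kurtosis of the DFT amplitude
  and phase sequences (3 x 25 x (1 + 5 x 2)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io import AXES, N_JOINTS, JointMap
from .preprocess import GaitSegment

__all__ = [
    "FeatureVector",
    "Spectrum",
    "SPATIOTEMPORAL_NAMES",
    "spatiotemporal_features",
    "moment_stats",
    "time_domain_features",
    "dft",
    "frequency_domain_features",
    "extract_all_features",
]

logger = logging.getLogger(__name__)

SPATIOTEMPORAL_NAMES = (
    "body_sway",
    "arm_swing_left",
    "arm_swing_right",
    "vertical_head_move",
    "head_posture",
    "stride_left",
    "stride_right",
    "toe_clearance_left",
    "toe_clearance_right",
    "walking_speed",
)

_BLOCK_SIZES = {"spatiotemporal": 10, "time": 300, "frequency": 825}


@dataclass
class FeatureVector:
    """Ordered named features for one participant and one block."""

    names: tuple[str, ...]
    values: np.ndarray
    block: Literal["spatiotemporal", "time", "frequency"]
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if len(self.names) != _BLOCK_SIZES[self.block]:
            raise ValueError(
                f"block {self.block!r} must have {_BLOCK_SIZES[self.block]} features,"
                f" got {len(self.names)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.participant_id)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass
class Spectrum:
    """One channel's DFT summary: DC component plus amplitude/phase arrays.

    ``dc_component`` is F_0 / n, the signal mean; ``amplitudes`` and
    ``phases`` cover bins k = 1..n-1 (full spectrum excluding DC), phases as
    principal values in (-pi, pi].
    """

    dc_component: float
    amplitudes: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.amplitudes.shape != self.phases.shape:
            raise ValueError("amplitudes and phases must have equal length")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")


def _per_cycle_mean(segment: GaitSegment, fn) -> float:
    return float(np.mean([fn(sl) for sl in segment.cycle_slices()]))


def spatiotemporal_features(segment: GaitSegment,
                            joint_map: JointMap | None = None,
                            toe_clearance_mode: str = "max",
                            head_posture_degrees: bool = False) -> FeatureVector:
    """Compute the 10 stride-level features, averaged over the two cycles.

    ``toe_clearance_mode`` selects the published convention ``"max"`` (the
    maximum spine-relative foot height — negative, since feet stay below the
    spine) or ``"ptp"`` (max - min change in height).  Head posture is the
    mean angle between the vertical and the neck-clavicle line in the Y-Z
    plane, in radians unless ``head_posture_degrees``.
    """
    jm = joint_map or JointMap()
    rel = segment.relative_positions

    def chan(role: str, axis: int) -> np.ndarray:
        return rel[:, jm.index(role) - 1, axis]

    sway_series = np.abs(chan("shoulder_left", 0) - chan("shoulder_right", 0))
    neck = rel[:, jm.index("neck") - 1, :]
    clav = rel[:, jm.index("clavicle") - 1, :]
    dyz = neck[:, 1:3] - clav[:, 1:3]           # neck-clavicle line, Y-Z plane
    norm = np.hypot(dyz[:, 0], dyz[:, 1])
    zero_norm = norm == 0
    if np.any(zero_norm):
        logger.warning("degenerate neck-clavicle geometry in %d frames",
                       int(zero_norm.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        angle = np.arccos(np.clip(np.abs(dyz[:, 0]) / np.where(zero_norm, 1.0, norm),
                                  -1.0, 1.0))
    angle = np.where(zero_norm, 0.0, angle)

    def ptp(series: np.ndarray):
        return lambda sl: float(np.ptp(series[sl]))

    def cyc_max(series: np.ndarray):
        return lambda sl: float(np.max(series[sl]))

    toe_fn = cyc_max if toe_clearance_mode == "max" else ptp
    if toe_clearance_mode not in ("max", "ptp"):
        raise ValueError("toe_clearance_mode must be 'max' or 'ptp'")

    def speed(sl: slice) -> float:
        z = segment.sensor_spine_z[sl]
        # displacement spans len(z) - 1 inter-frame intervals
        dur = (len(z) - 1) / segment.frame_rate
        return float(abs(z[-1] - z[0]) / dur)

    values = {
        "body_sway": _per_cycle_mean(segment, cyc_max(sway_series)),
        "arm_swing_left": _per_cycle_mean(segment, ptp(chan("wrist_left", 2))),
        "arm_swing_right": _per_cycle_mean(segment, ptp(chan("wrist_right", 2))),
        "vertical_head_move": _per_cycle_mean(segment, ptp(chan("head", 1))),
        "head_posture": _per_cycle_mean(
            segment, lambda sl: float(np.mean(angle[sl]))
        ),
        "stride_left": _per_cycle_mean(segment, ptp(chan("foot_left", 2))),
        "stride_right": _per_cycle_mean(segment, ptp(chan("foot_right", 2))),
        "toe_clearance_left": _per_cycle_mean(segment, toe_fn(chan("foot_left", 1))),
        "toe_clearance_right": _per_cycle_mean(segment, toe_fn(chan("foot_right", 1))),
        "walking_speed": _per_cycle_mean(segment, speed),
    }
    if head_posture_degrees:
        values["head_posture"] = float(np.degrees(values["head_posture"]))
    for name, v in values.items():
        if v == 0.0 and name != "head_posture":
            logger.debug("zero-valued spatiotemporal feature %s", name)
    return FeatureVector(
        names=SPATIOTEMPORAL_NAMES,
        values=np.array([values[n] for n in SPATIOTEMPORAL_NAMES]),
        block="spatiotemporal",
        participant_id=segment.participant_id,
    )


def moment_stats(series: np.ndarray) -> tuple[float, float, float, float]:
    """Sample mean, SD (n-1), skewness g1 and excess kurtosis g2.

    Central moments use the 1/n convention (g1 = m3 / m2^1.5,
    g2 = m4 / m2^2 - 3).  A zero-variance series has skewness and kurtosis
    defined as 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ValueError("moment statistics require at least 4 samples")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return mean, 0.0, 0.0, 0.0
    # numerically-degenerate (near-constant) channels: higher moments lose all
    # precision to cancellation; define them as 0 like the exact-constant case
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        skew = float(sstats.skew(x, bias=True))
        kurt = float(sstats.kurtosis(x, fisher=True, bias=True))
    if not np.isfinite(skew) or sd < 1e-12 * max(1.0, abs(mean)):
        skew = 0.0
        kurt = 0.0
    if not np.isfinite(kurt):
        kurt = 0.0
    return mean, sd, skew, kurt


_STAT_NAMES = ("mean", "sd", "skew", "kurt")


def _channel_names() -> list[tuple[str, int, int]]:
    out = []
    for j in range(1, N_JOINTS + 1):
        for a, axis in enumerate(AXES):
            out.append((f"j{j:02d}_{axis}", j, a))
    return out


def time_domain_features(segment: GaitSegment) -> FeatureVector:
    """Four moment statistics for each of the 75 joint-axis channels."""
    names: list[str] = []
    values: list[float] = []
    for cname, j, a in _channel_names():
        stats4 = moment_stats(segment.relative_positions[:, j - 1, a])
        for sname, v in zip(_STAT_NAMES, stats4):
            names.append(f"{cname}_{sname}")
            values.append(v)
    return FeatureVector(tuple(names), np.array(values), "time",
                         segment.participant_id)


def dft(series: np.ndarray) -> Spectrum:
    """Discrete Fourier transform summary of one channel.

    Computes F_k = sum_j x_j exp(-2 pi i k j / n) and returns the DC
    component F_0 / n (the signal mean) with amplitudes |F_k| and principal
    phases arg(F_k) for k = 1..n-1.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("DFT requires at least 2 samples")
    F = np.fft.fft(x)
    phases = np.angle(F[1:])
    phases = np.where(phases <= -np.pi, np.pi, phases)  # principal value (-pi, pi]
    return Spectrum(
        dc_component=float(F[0].real / x.size),
        amplitudes=np.abs(F[1:]),
        phases=phases,
    )


def _spectrum_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """mean, variance, SD, skewness, kurtosis of an amplitude/phase sequence."""
    mean, sd, skew, kurt = moment_stats(values)
    return mean, sd * sd, sd, skew, kurt


_FREQ_STAT_NAMES = ("mean", "var", "sd", "skew", "kurt")


def frequency_domain_features(segment: GaitSegment,
                              amplitude_floor: float = 0.0) -> FeatureVector:
    """DC plus amplitude/phase moment statistics per channel (11 x 75 = 825).

    ``amplitude_floor`` optionally excludes near-zero-amplitude bins from
    the phase statistics (default: include all bins).
    """
    names: list[str] = []
    values: list[float] = []
    for cname, j, a in _channel_names():
        spec = dft(segment.relative_positions[:, j - 1, a])
        names.append(f"{cname}_dc")
        values.append(spec.dc_component)
        phases = spec.phases
        if amplitude_floor > 0:
            keep = spec.amplitudes >= amplitude_floor
            if keep.sum() >= 4:
                phases = phases[keep]
        for part, series in (("amp", spec.amplitudes), ("phase", phases)):
            for sname, v in zip(_FREQ_STAT_NAMES, _spectrum_stats(series)):
                names.append(f"{cname}_{part}_{sname}")
                values.append(v)
    return FeatureVector(tuple(names), np.array(values), "frequency",
                         segment.participant_id)


def extract_all_features(segment: GaitSegment, **st_kwargs) -> dict[str, FeatureVector]:
    """All three banks for one segment, keyed by block name."""
    return {
        "spatiotemporal": spatiotemporal_features(segment, **st_kwargs),
        "time": time_domain_features(segment),
        "frequency": frequency_domain_features(segment),
    }
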