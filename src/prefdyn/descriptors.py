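"""Dispersion-based video descriptors.

For a frame, the *center* is the mean of the landmark coordinates and
the *dispersion* is the mean Euclidean distance of the landmarks to that
center — a per-frame proxy for how spread out (mobile) the face is.
Across the frames of a video, two statistics summarise variation in
dispersion:

* ``d_std`` — the standard deviation of the dispersion series (every
  frame contributes, so it is relatively noise resistant);
* ``d_maxmin`` — the range (max minus min) of the series (better at
  exploiting brief extreme gestures, more noise sensitive).

Neither statistic uses the temporal order of frames.

For the learned pipeline the same two summaries are computed per
landmark on its radial-distance series (distance to the frame center
over time), giving a 132-dimensional feature vector per video: 66
max-min values followed by 66 standard deviations, in landmark order.

Standard deviations use the population convention (divide by n)
throughout.  Descriptors operate on whatever frames they are given;
middle-third selection is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import N_LANDMARKS, LandmarkDataError, LandmarkFrame, LandmarkVideo

STATISTICS = ("dstd", "dmaxmin")


@dataclass(frozen=True)
class DispersionSeries:
    """Per-frame centers and dispersions of a video."""

    centers: np.ndarray  # (n, 2)
    dispersions: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        if self.centers.shape != (len(self.dispersions), 2):
            raise ValueError("centers and dispersions lengths disagree")

    @property
    def n(self) -> int:
        return len(self.dispersions)


def frame_center(frame: LandmarkFrame) -> np.ndarray:
    """Coordinate-wise mean of the frame's landmarks."""
    return frame.points.mean(axis=0)


def frame_dispersion(frame: LandmarkFrame) -> float:
    """Mean Euclidean distance of the landmarks to the frame center.

    Accepts any point count (closed-form test geometries use fewer than
    66 points); the public video path enforces the full landmark set.
    """
    c = frame_center(frame)
    return float(np.linalg.norm(frame.points - c, axis=1).mean())


def dispersion_series(video: LandmarkVideo) -> DispersionSeries:
    """Per-frame centers and dispersions, order preserved."""
    coords = video.coords  # (n, p, 2)
    centers = coords.mean(axis=1)
    disp = np.linalg.norm(coords - centers[:, None, :], axis=2).mean(axis=1)
    return DispersionSeries(centers=centers, dispersions=disp)


def _population_std(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Population std with an order-independent reduction.

    Values are sorted before the two-pass computation, so any
    permutation of the input yields a bit-identical result — the
    statistics are functions of the multiset of frames, never of their
    order.
    """
    v = np.sort(values, axis=axis)
    n = v.shape[axis]
    mean = v.sum(axis=axis) / n
    dev2 = (v - np.expand_dims(mean, axis)) ** 2
    return np.sqrt(dev2.sum(axis=axis) / n)


def d_std(series: DispersionSeries | np.ndarray) -> float:
    """Population standard deviation of the dispersion series."""
    d = series.dispersions if isinstance(series, DispersionSeries) else np.asarray(series, float)
    if d.size < 2:
        raise LandmarkDataError(f"d_std requires >=2 frames, got {d.size}")
    return float(_population_std(d))


def d_maxmin(series: DispersionSeries | np.ndarray) -> float:
    """Range (max minus min) of the dispersion series."""
    d = series.dispersions if isinstance(series, DispersionSeries) else np.asarray(series, float)
    if d.size < 1:
        raise LandmarkDataError("d_maxmin requires >=1 frame")
    return float(np.max(d) - np.min(d))


def video_statistic(video: LandmarkVideo, statistic: str) -> float:
    """Compute one of the two video statistics ('dstd' or 'dmaxmin')."""
    series = dispersion_series(video)
    if statistic == "dstd":
        return d_std(series)
    if statistic == "dmaxmin":
        return d_maxmin(series)
    raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")


def landmark_radial_series(video: LandmarkVideo, landmark: int) -> np.ndarray:
    """Distance of one landmark (1-based index) to the frame center, per frame."""
    if not 1 <= landmark <= N_LANDMARKS:
        raise LandmarkDataError(
            f"landmark index must be in 1..{N_LANDMARKS}, got {landmark}"
        )
    coords = video.coords
    centers = coords.mean(axis=1)
    return np.linalg.norm(coords[:, landmark - 1, :] - centers, axis=1)


def feature_vector(video: LandmarkVideo) -> np.ndarray:
    """Per-landmark descriptor vector of length 132.

    Entries 1-66 hold each landmark's max-min of its radial-distance
    series; entries 67-132 its population standard deviation, both in
    landmark order.
    """
    video.validate_full()
    if len(video) < 2:
        raise LandmarkDataError(f"feature_vector requires >=2 frames, got {len(video)}")
    coords = video.coords  # (n, 66, 2)
    centers = coords.mean(axis=1)
    radial = np.linalg.norm(coords - centers[:, None, :], axis=2)  # (n, 66)
    maxmin = radial.max(axis=0) - radial.min(axis=0)
    std = _population_std(radial, axis=0)
    return np.concatenate([maxmin, std])


def pair_feature(v1: LandmarkVideo, v2: LandmarkVideo) -> np.ndarray:
    """Coordinate-wise difference feature_vector(v1) - feature_vector(v2)."""
    return feature_vector(v1) - feature_vector(v2)
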