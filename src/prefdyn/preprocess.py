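"""Frame normalization to an eye-based canonical coordinate system.

Each frame is mapped by a similarity transform (uniform scale plus
translation, no rotation) so that the left-eye center — the mean of
landmarks 37-42 — lands at (100, 100) and the distance between the two
eye centers becomes 100 pixels.  Scaling is performed about the left-eye
center, so both conditions hold simultaneously.  Head roll is left
uncorrected: the procedure registers position and scale only.

Because spontaneous recordings show exaggerated mobility at stimulus
onset and offset (task engagement and disengagement), analysis keeps
only the middle third of each video; :func:`middle_third` implements the
frame selection.
"""

from __future__ import annotations

import numpy as np

from .types import (
    LEFT_EYE_SLICE,
    RIGHT_EYE_SLICE,
    DegenerateGeometryError,
    LandmarkDataError,
    LandmarkFrame,
    LandmarkVideo,
)

#: Canonical left-eye-center position and inter-eye distance after
#: normalization, in pixels.
CANONICAL_EYE_CENTER = np.array([100.0, 100.0])
CANONICAL_INTER_EYE_DISTANCE = 100.0

#: Minimum inter-eye distance (pixels) below which a frame is treated as
#: geometrically degenerate.
DEGENERACY_TOL = 1e-9


def eye_centers(frame: LandmarkFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return (left, right) eye centers of a frame.

    The left center is the arithmetic mean of landmarks 37-42, the right
    of 43-48 (1-based numbering).  "Left" is the viewer's left, i.e. the
    cluster with smaller x in the image convention.
    """
    frame.require_full()
    left = frame.points[LEFT_EYE_SLICE].mean(axis=0)
    right = frame.points[RIGHT_EYE_SLICE].mean(axis=0)
    return left, right


def normalize_frame(frame: LandmarkFrame) -> LandmarkFrame:
    """Map a frame so the left-eye center is (100, 100) and the inter-eye
    distance is 100 pixels.

    The transform scales all landmarks uniformly by ``100 / d`` about the
    left-eye center (``d`` being the inter-eye distance) and then places
    that center at (100, 100).  Idempotent to numerical precision.
    """
    left, right = eye_centers(frame)
    d = float(np.linalg.norm(right - left))
    if d <= DEGENERACY_TOL:
        raise DegenerateGeometryError(
            f"frame {frame.index}: coincident eye centers (inter-eye "
            f"distance {d:.3g} px)"
        )
    s = CANONICAL_INTER_EYE_DISTANCE / d
    new_points = (frame.points - left) * s + CANONICAL_EYE_CENTER
    return LandmarkFrame(index=frame.index, points=new_points)


def normalize_video(video: LandmarkVideo) -> LandmarkVideo:
    """Apply :func:`normalize_frame` to every frame, preserving order."""
    out = []
    for frame in video.frames:
        try:
            out.append(normalize_frame(frame))
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(
                f"video ({video.domain}, target {video.target_id}, "
                f"pair {video.pair_id}, slot {video.slot}): {exc}"
            ) from exc
    return video.with_frames(out)


def middle_third(video: LandmarkVideo) -> LandmarkVideo:
    """Keep frames with 0-based position i in [floor(n/3), floor(2n/3)).

    Discards the first and last thirds of the video, where task
    engagement and disengagement inflate facial mobility.  For n not
    divisible by 3 the half-open convention keeps between floor(n/3) and
    ceil(n/3) frames; the precise boundary choice does not matter for
    the downstream statistics.
    """
    n = len(video)
    if n < 3:
        raise LandmarkDataError(f"middle_third requires >=3 frames, got {n}")
    lo, hi = n // 3, (2 * n) // 3
    return video.with_frames(video.frames[lo:hi])


def preprocess_video(
    video: LandmarkVideo, *, keep_middle_third: bool = True
) -> LandmarkVideo:
    """Standard preprocessing: normalize every frame, then (optionally)
    keep only the middle third."""
    out = normalize_video(video)
    if keep_middle_third:
        out = middle_third(out)
    return out
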