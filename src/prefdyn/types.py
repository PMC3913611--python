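"""Core domain types for landmark videos and video pairs.

Coordinates follow the image convention: x increases rightward, y
increases downward, origin at the top-left of the frame.  Landmarks are
numbered 1-66 in documentation and on disk (eye clusters at 37-42 and
43-48); in-memory arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: Number of landmarks in the annotation scheme.
N_LANDMARKS = 66

#: 0-based index ranges of the left and right eye landmark clusters
#: (1-based landmarks 37-42 and 43-48).
LEFT_EYE_SLICE = slice(36, 42)
RIGHT_EYE_SLICE = slice(42, 48)

#: Stimulus domains of the preference task.
DOMAINS = ("people", "cartoons", "paintings", "animals")


class LandmarkDataError(ValueError):
    """Structural problem in landmark data (wrong point count, bad index...)."""


class DegenerateGeometryError(ValueError):
    """Frame geometry prevents normalization (coincident eye centers)."""


@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame's landmark annotation.

    Parameters
    ----------
    index : int
        Frame ordinal within the video (0-based).
    points : ndarray of shape (66, 2)
        Pixel coordinates ordered by landmark number.
    """

    index: int
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise LandmarkDataError(
                f"frame {self.index}: points must be (n, 2), got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise LandmarkDataError(f"frame {self.index}: non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def require_full(self) -> None:
        """Raise unless the frame carries the full 66-landmark set."""
        if self.n_points != N_LANDMARKS:
            raise LandmarkDataError(
                f"frame {self.index}: expected {N_LANDMARKS} landmarks, "
                f"found {self.n_points}"
            )


@dataclass(frozen=True)
class LandmarkVideo:
    """An ordered sequence of landmark frames plus recording metadata."""

    frames: tuple[LandmarkFrame, ...]
    fps: float
    domain: str
    target_id: int
    pair_id: int
    slot: int

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) < 1:
            raise LandmarkDataError("video has no frames")
        idx = [f.index for f in frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise LandmarkDataError("frame indices must be strictly increasing")
        if self.fps <= 0:
            raise LandmarkDataError(f"fps must be positive, got {self.fps}")
        if self.domain not in DOMAINS:
            raise LandmarkDataError(f"unknown domain {self.domain!r}")
        if self.slot not in (1, 2):
            raise LandmarkDataError(f"slot must be 1 or 2, got {self.slot}")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[LandmarkFrame]:
        return iter(self.frames)

    @property
    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_points, 2)."""
        return np.stack([f.points for f in self.frames])

    def with_frames(self, frames: Sequence[LandmarkFrame]) -> "LandmarkVideo":
        return replace(self, frames=tuple(frames))

    def validate_full(self) -> None:
        for f in self.frames:
            f.require_full()


@dataclass(frozen=True)
class VideoPair:
    """Two videos of the same observer examining the two images of a pair.

    ``preferred`` records which slot (1 or 2) showed the image the
    observer subsequently chose.  ``excluded`` flags pairs pruned from
    analysis (e.g. occluded faces); exclusion never alters stored data,
    only selection.
    """

    video1: LandmarkVideo
    video2: LandmarkVideo
    preferred: int
    excluded: bool = False

    def __post_init__(self) -> None:
        v1, v2 = self.video1, self.video2
        for name in ("domain", "target_id", "pair_id"):
            a, b = getattr(v1, name), getattr(v2, name)
            if a != b:
                raise LandmarkDataError(
                    f"pair videos disagree on {name}: {a!r} vs {b!r}"
                )
        if {v1.slot, v2.slot} != {1, 2}:
            raise LandmarkDataError(
                f"pair slots must be {{1, 2}}, got {{{v1.slot}, {v2.slot}}}"
            )
        if self.preferred not in (1, 2):
            raise LandmarkDataError(f"preferred must be 1 or 2, got {self.preferred}")

    @property
    def domain(self) -> str:
        return self.video1.domain

    @property
    def target_id(self) -> int:
        return self.video1.target_id

    @property
    def pair_id(self) -> int:
        return self.video1.pair_id

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.domain, self.target_id, self.pair_id)


@dataclass
class DatasetManifest:
    """Bookkeeping for a dataset of video pairs.

    ``records`` holds one dict per pair (paths, labels, flags) in the
    on-disk manifest schema; ``pairs`` the loaded :class:`VideoPair`
    objects in the same order.
    """

    records: list[dict] = field(default_factory=list)
    pairs: list[VideoPair] = field(default_factory=list)

    @property
    def active_pairs(self) -> list[VideoPair]:
        return [p for p in self.pairs if not p.excluded]

    @property
    def excluded_pairs(self) -> list[VideoPair]:
        return [p for p in self.pairs if p.excluded]

    def by_domain(self, active_only: bool = True) -> dict[str, list[VideoPair]]:
        out: dict[str, list[VideoPair]] = {}
        pool = self.active_pairs if active_only else self.pairs
        for p in pool:
            out.setdefault(p.domain, []).append(p)
        return out

    def counts(self) -> dict[str, int]:
        """Active pair count per domain."""
        return {d: len(ps) for d, ps in self.by_domain().items()}
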