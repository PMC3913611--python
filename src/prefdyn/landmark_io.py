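"""Reading and writing landmark-trajectory files and dataset manifests.

On-disk formats
---------------
* Landmark CSV (long form), one file per video, header ``frame,landmark,x,y``
  with 1-based landmark numbers and one row per (frame, landmark).
  Coordinates are written with 6 decimal places — below landmark-detection
  noise, lossless for round-trip purposes.
* Dataset manifest: a JSON array of pair records
  ``{domain, target_id, pair_id, preferred, excluded, video1_path,
  video2_path, fps}``; relative paths are resolved against the manifest's
  directory.

The CSV dialect is this package's own; ``read_landmark_video`` accepts a
``reader`` plugin so files from other annotation tools can be adapted
without touching the rest of the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .types import (
    N_LANDMARKS,
    DatasetManifest,
    LandmarkDataError,
    LandmarkFrame,
    LandmarkVideo,
    VideoPair,
)

#: Write precision for coordinates (decimal places).
COORD_DECIMALS = 6

FrameReader = Callable[[Path], list[LandmarkFrame]]


def _read_frames_csv(path: Path) -> list[LandmarkFrame]:
    """Default reader for the long-form landmark CSV dialect."""
    try:
        df = pd.read_csv(path, dtype={"frame": int, "landmark": int})
    except ValueError as exc:
        raise LandmarkDataError(f"{path}: cannot parse landmark CSV: {exc}") from exc
    required = {"frame", "landmark", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise LandmarkDataError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise LandmarkDataError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
        df[col] = vals

    frames = []
    for frame_idx, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("landmark")
        lmks = grp["landmark"].to_numpy()
        if len(lmks) != N_LANDMARKS or not np.array_equal(
            lmks, np.arange(1, N_LANDMARKS + 1)
        ):
            raise LandmarkDataError(
                f"{path}: frame {frame_idx} has {len(lmks)} landmarks "
                f"(expected 1..{N_LANDMARKS} exactly once)"
            )
        frames.append(
            LandmarkFrame(index=int(frame_idx), points=grp[["x", "y"]].to_numpy())
        )
    if not frames:
        raise LandmarkDataError(f"{path}: no frames found")
    return frames


def read_landmark_video(
    path: str | Path,
    *,
    fps: float,
    domain: str,
    target_id: int,
    pair_id: int,
    slot: int,
    reader: FrameReader | None = None,
) -> LandmarkVideo:
    """Read a landmark video from ``path`` and attach recording metadata.

    Parameters
    ----------
    reader
        Optional plugin mapping a file path to a list of
        :class:`LandmarkFrame`; defaults to the package's CSV dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    frames = (reader or _read_frames_csv)(path)
    video = LandmarkVideo(
        frames=tuple(frames),
        fps=fps,
        domain=domain,
        target_id=target_id,
        pair_id=pair_id,
        slot=slot,
    )
    video.validate_full()
    return video


def write_landmark_video(video: LandmarkVideo, path: str | Path) -> Path:
    """Write a video to the long-form landmark CSV dialect.

    The output is readable by :func:`read_landmark_video` with coordinate
    round-trip error below 1e-6.
    """
    video.validate_full()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = len(video)
    frame_col = np.repeat([f.index for f in video.frames], N_LANDMARKS)
    lmk_col = np.tile(np.arange(1, N_LANDMARKS + 1), n)
    coords = video.coords.reshape(-1, 2)
    df = pd.DataFrame(
        {"frame": frame_col, "landmark": lmk_col, "x": coords[:, 0], "y": coords[:, 1]}
    )
    df.to_csv(path, index=False, float_format=f"%.{COORD_DECIMALS}f")
    return path


def write_manifest(records: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(records, indent=2) + "\n")
    return path


def load_dataset(
    manifest_path: str | Path, *, reader: FrameReader | None = None
) -> DatasetManifest:
    """Load a dataset manifest and every video pair it references.

    Excluded pairs are loaded and retained with their flag set — mirroring
    the pruning of occlusion-defective recordings, which removes pairs from
    analysis without deleting their data.  All missing landmark files are
    reported together.
    """
    manifest_path = Path(manifest_path)
    records = json.loads(manifest_path.read_text())
    base = manifest_path.parent

    missing = []
    for rec in records:
        for key in ("video1_path", "video2_path"):
            p = base / rec[key]
            if not p.exists():
                missing.append(str(p))
    if missing:
        raise FileNotFoundError(
            "manifest references missing landmark files: " + ", ".join(missing)
        )

    seen: set[tuple[str, int, int]] = set()
    pairs = []
    for rec in records:
        videos = []
        for slot, key in ((1, "video1_path"), (2, "video2_path")):
            videos.append(
                read_landmark_video(
                    base / rec[key],
                    fps=float(rec["fps"]),
                    domain=rec["domain"],
                    target_id=int(rec["target_id"]),
                    pair_id=int(rec["pair_id"]),
                    slot=slot,
                    reader=reader,
                )
            )
        pair = VideoPair(
            video1=videos[0],
            video2=videos[1],
            preferred=int(rec["preferred"]),
            excluded=bool(rec.get("excluded", False)),
        )
        if pair.key in seen:
            raise LandmarkDataError(f"duplicate pair id {pair.key} in manifest")
        seen.add(pair.key)
        pairs.append(pair)

    return DatasetManifest(records=list(records), pairs=pairs)
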