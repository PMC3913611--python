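"""Synthetic landmark-video generator.

Emulates the statistical structure the preference predictors rely on,
so every pipeline stage is testable without the original covert
recordings:

* a schematic 66-point face template with the standard numbering (eye
  clusters at landmarks 37-42 and 43-48);
* per-frame rigid jitter (small whole-face translations from head and
  camera motion);
* transient expression bursts — temporally contiguous displacements of
  a contiguous landmark subset, pushed radially outward from the face
  center under a raised-cosine envelope, with amplitude scaled by the
  video's "mobility" level.  Outward displacement guarantees bursts
  increase frame dispersion, the mechanism linking facial mobility to
  the dispersion statistics;
* an onset/offset mobility surge: jitter and landmark noise in the
  first and last thirds of each video are multiplied by a surge factor,
  emulating task engagement and disengagement;
* additive i.i.d. landmark-localization noise.

Pairs encode the preference-mobility link the predictors decode: for
cartoons and paintings the preferred video receives extra mobility
(base + gap); for people and animals the NON-preferred video does, so
the baseline's domain reversal is the correct decoder.

All randomness flows through explicitly seeded generators; identical
(config, seed) reproduce bit-identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import landmark_io
from .types import (
    DOMAINS,
    N_LANDMARKS,
    DatasetManifest,
    LandmarkFrame,
    LandmarkVideo,
    VideoPair,
)

#: Video duration in seconds per stimulus domain: cartoons play longer
#: because the stimuli are animated clips rather than still images.
DEFAULT_DURATIONS = {"people": 3.0, "cartoons": 7.0, "paintings": 3.0, "animals": 3.0}


@dataclass(frozen=True)
class SimConfig:
    """All simulator parameters.

    Amplitudes and SDs are in pixels of the template coordinate frame
    (inter-eye distance 120 px, i.e. a webcam-scale face); durations in
    seconds, burst windows in frames.

    ``mobility_base`` is every video's baseline expression-burst
    amplitude; ``mobility_gap`` is the extra amplitude given to one
    video of each pair according to the preference-mobility link.
    """

    fps: float = 24.0
    durations: dict = field(default_factory=lambda: dict(DEFAULT_DURATIONS))
    rigid_jitter_sd: float = 1.0
    landmark_noise_sd: float = 0.5
    mobility_base: float = 2.0
    mobility_gap: float = 2.0
    burst_rate_hz: float = 2.0
    burst_duration_range: tuple[int, int] = (6, 18)
    burst_landmark_span: tuple[int, int] = (12, 24)
    boundary_surge: float = 2.0
    n_targets: int = 8
    pairs_per_target: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name in ("rigid_jitter_sd", "landmark_noise_sd", "mobility_base",
                     "mobility_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v <= 0 for v in self.durations.values()):
            raise ValueError("durations must be positive")

    def n_frames(self, domain: str) -> int:
        return int(round(self.fps * self.durations[domain]))

    @classmethod
    def strong_signal(cls, seed: int = 0) -> "SimConfig":
        """A high mobility-gap / low-noise regime in which the
        preference signal clearly dominates localization noise."""
        return cls(
            mobility_base=1.0,
            mobility_gap=8.0,
            landmark_noise_sd=0.3,
            rigid_jitter_sd=0.5,
            seed=seed,
        )

    @classmethod
    def null_signal(cls, seed: int = 0) -> "SimConfig":
        """Mobility gap zero: preference carries no mobility signal."""
        return cls(mobility_gap=0.0, seed=seed)


# ---------------------------------------------------------------------------
# Template face
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FaceTemplate:
    """Fixed 66-point schematic face layout."""

    points: np.ndarray  # (66, 2)

    @property
    def inter_eye_distance(self) -> float:
        left = self.points[36:42].mean(axis=0)
        right = self.points[42:48].mean(axis=0)
        return float(np.linalg.norm(right - left))

    @property
    def center(self) -> np.ndarray:
        return self.points.mean(axis=0)


def make_template_face() -> FaceTemplate:
    """Deterministic schematic face in a 640x480 frame.

    Landmark groups follow the standard 66-point scheme: jaw contour
    1-17, eyebrows 18-27, nose 28-36, eyes 37-48 (left then right, six
    points each), mouth 49-66 (twelve outer, six inner).  Only the
    group semantics matter; the geometry is schematic, not
    anthropometric.
    """
    cx, cy = 320.0, 230.0
    pts = np.empty((N_LANDMARKS, 2))
    # jaw contour 1-17: lower half-ellipse (y-down image convention),
    # left temple to right temple
    t = np.linspace(np.pi, 0.0, 17)
    pts[0:17, 0] = cx - 110.0 * np.cos(t)
    pts[0:17, 1] = cy + 140.0 * np.sin(t)
    # eyebrows 18-22 (left) and 23-27 (right): shallow arcs above the eyes
    pts[17:22, 0] = np.linspace(215.0, 295.0, 5)
    pts[17:22, 1] = 170.0 - 8.0 * np.sin(np.linspace(0, np.pi, 5))
    pts[22:27, 0] = np.linspace(345.0, 425.0, 5)
    pts[22:27, 1] = 170.0 - 8.0 * np.sin(np.linspace(0, np.pi, 5))
    # nose 28-31 bridge, 32-36 nostril line
    pts[27:31, 0] = cx
    pts[27:31, 1] = np.linspace(200.0, 260.0, 4)
    pts[31:36, 0] = np.linspace(cx - 24.0, cx + 24.0, 5)
    pts[31:36, 1] = 275.0 + 5.0 * np.sin(np.linspace(0, np.pi, 5))
    # eyes 37-42 (left) and 43-48 (right): six-point hexagons around the
    # eye centers; inter-eye distance 120 px
    for base, ex in ((36, 260.0), (42, 380.0)):
        ang = np.linspace(0, 2 * np.pi, 7)[:6]
        pts[base:base + 6, 0] = ex + 18.0 * np.cos(ang)
        pts[base:base + 6, 1] = 200.0 + 9.0 * np.sin(ang)
    # mouth 49-60 outer ring, 61-66 inner ring
    ang = np.linspace(0, 2 * np.pi, 13)[:12]
    pts[48:60, 0] = cx + 36.0 * np.cos(ang)
    pts[48:60, 1] = 315.0 + 16.0 * np.sin(ang)
    ang = np.linspace(0, 2 * np.pi, 7)[:6]
    pts[60:66, 0] = cx + 20.0 * np.cos(ang)
    pts[60:66, 1] = 315.0 + 7.0 * np.sin(ang)
    return FaceTemplate(points=pts)


# ---------------------------------------------------------------------------
# Video and pair simulation
# ---------------------------------------------------------------------------

def _video_rng(config: SimConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *tags]))


def simulate_video(
    config: SimConfig,
    mobility: float,
    domain: str,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    target_id: int = 1,
    pair_id: int = 1,
    slot: int = 1,
) -> LandmarkVideo:
    """Generate one landmark video at the given expression mobility.

    ``mobility`` (pixels) scales the amplitude of every expression
    burst.  Frames in the first and last thirds get rigid jitter and
    landmark noise multiplied by ``config.boundary_surge``.
    """
    if mobility < 0:
        raise ValueError("mobility must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    template = make_template_face()
    n = config.n_frames(domain)
    coords = np.broadcast_to(template.points, (n, N_LANDMARKS, 2)).copy()

    # onset/offset surge applies to the first and last thirds
    surge = np.ones(n)
    lo, hi = n // 3, (2 * n) // 3
    surge[:lo] = config.boundary_surge
    surge[hi:] = config.boundary_surge

    # rigid per-frame translation
    jitter = rng.normal(0.0, config.rigid_jitter_sd, size=(n, 2))
    coords += (jitter * surge[:, None])[:, None, :]

    # expression bursts: outward radial displacement of a contiguous
    # landmark window under a raised-cosine temporal envelope
    center = template.center
    radial = template.points - center
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    dmin, dmax = config.burst_duration_range
    smin, smax = config.burst_landmark_span
    n_bursts = int(round(config.burst_rate_hz * config.durations[domain]))
    # stratified onsets: one burst per equal time slot, uniform within the
    # slot, so expression events cover the whole recording (including the
    # middle-third analysis window) in every realization
    slot_edges = np.linspace(0, n, n_bursts + 1)
    for b in range(n_bursts):
        dur = int(rng.integers(dmin, dmax + 1))
        onset = int(rng.integers(int(slot_edges[b]), max(int(slot_edges[b + 1]), int(slot_edges[b]) + 1)))
        frames = np.arange(onset, min(onset + dur, n))
        span = int(rng.integers(smin, smax + 1))
        lstart = int(rng.integers(0, N_LANDMARKS - span + 1))
        amp = mobility * rng.uniform(0.5, 1.5)
        phase = (np.arange(len(frames)) + 0.5) / dur
        envelope = amp * 0.5 * (1 - np.cos(2 * np.pi * phase))
        coords[np.ix_(frames, np.arange(lstart, lstart + span))] += (
            envelope[:, None, None] * radial[lstart:lstart + span]
        )

    # landmark-localization noise
    noise = rng.normal(0.0, config.landmark_noise_sd, size=(n, N_LANDMARKS, 2))
    coords += noise * surge[:, None, None]

    frames_out = tuple(
        LandmarkFrame(index=i, points=coords[i]) for i in range(n)
    )
    return LandmarkVideo(
        frames=frames_out,
        fps=config.fps,
        domain=domain,
        target_id=target_id,
        pair_id=pair_id,
        slot=slot,
    )


def simulate_pair(
    config: SimConfig,
    domain: str,
    preferred_slot: int,
    *,
    target_id: int = 1,
    pair_id: int = 1,
    rng: np.random.Generator | None = None,
) -> VideoPair:
    """Generate a labelled video pair with the preference-mobility link.

    Cartoons/paintings: the preferred video's mobility is base + gap.
    People/animals: the NON-preferred video's mobility is base + gap
    (faces move more at the less appealing animate stimulus), so the
    reversal rule is the correct decoder.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    if preferred_slot not in (1, 2):
        raise ValueError("preferred_slot must be 1 or 2")
    if rng is None:
        di = DOMAINS.index(domain)
        rng = _video_rng(config, di, target_id, pair_id)
    if domain in ("cartoons", "paintings"):
        hot_slot = preferred_slot
    else:
        hot_slot = 3 - preferred_slot
    videos = []
    for slot in (1, 2):
        mobility = config.mobility_base + (
            config.mobility_gap if slot == hot_slot else 0.0
        )
        videos.append(
            simulate_video(
                config,
                mobility,
                domain,
                rng=rng,
                target_id=target_id,
                pair_id=pair_id,
                slot=slot,
            )
        )
    return VideoPair(video1=videos[0], video2=videos[1], preferred=preferred_slot)


def simulate_pairs(
    config: SimConfig,
    *,
    domains: tuple[str, ...] = DOMAINS,
    n_targets: int | None = None,
    pairs_per_target: int | None = None,
) -> list[VideoPair]:
    """Realize the factorial design in memory.

    domains x targets x pairs, two videos each; the preferred slot is
    drawn uniformly per pair.  Fully reproducible from ``config.seed``.
    """
    n_targets = config.n_targets if n_targets is None else n_targets
    pairs_per_target = (
        config.pairs_per_target if pairs_per_target is None else pairs_per_target
    )
    out = []
    for domain in domains:
        di = DOMAINS.index(domain)
        for t in range(1, n_targets + 1):
            for p in range(1, pairs_per_target + 1):
                rng = _video_rng(config, di, t, p)
                preferred = int(rng.integers(1, 3))
                out.append(
                    simulate_pair(
                        config, domain, preferred, target_id=t, pair_id=p, rng=rng
                    )
                )
    return out


def simulate_dataset(
    config: SimConfig,
    out_dir: str | Path,
    *,
    domains: tuple[str, ...] = DOMAINS,
    n_targets: int | None = None,
    pairs_per_target: int | None = None,
) -> DatasetManifest:
    """Realize the design on disk: landmark CSVs plus a JSON manifest.

    With the default design (4 domains x 8 targets x 12 pairs x 2
    videos) this writes 768 videos.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = simulate_pairs(
        config,
        domains=domains,
        n_targets=n_targets,
        pairs_per_target=pairs_per_target,
    )
    records = []
    for pair in pairs:
        paths = {}
        for slot, video in ((1, pair.video1), (2, pair.video2)):
            rel = Path(pair.domain) / (
                f"t{pair.target_id:02d}_p{pair.pair_id:02d}_v{slot}.csv"
            )
            landmark_io.write_landmark_video(video, out_dir / rel)
            paths[slot] = str(rel)
        records.append(
            {
                "domain": pair.domain,
                "target_id": pair.target_id,
                "pair_id": pair.pair_id,
                "preferred": pair.preferred,
                "excluded": pair.excluded,
                "video1_path": paths[1],
                "video2_path": paths[2],
                "fps": config.fps,
            }
        )
    landmark_io.write_manifest(records, out_dir / "manifest.json")
    return DatasetManifest(records=records, pairs=pairs)
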