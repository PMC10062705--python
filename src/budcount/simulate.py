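"""Synthetic camera-scan scenes: ground-truth tracks, noisy detections, true counts.

The simulator emulates the data-collection geometry of a hand-held camera
tilted downward and carried at uniform walking speed (~0.15 m/s) along a crop
ridge: in image coordinates the scene scrolls downward at a constant pixel
rate, so every object's center traces an exactly linear trajectory in frame
index — the constant-velocity assumption the Kalman filter makes is true by
construction.  Objects (tea buds) are placed on the virtual strip by a
homogeneous Poisson process whose intensity reproduces a requested mean
number of visible instances per frame; each object appears when it scrolls
into the frame, translates downward, and leaves at the bottom.

At frame 0 the strip is populated only above the entering-area limit, so the
scene "scrolls in" the way a real walk-up does and every object passes
through the entering area before it can reach the counting baseline.  The
per-frame density reaches its stationary mean after the short burn-in it
takes the first objects to traverse the frame.

Detector imperfection is modelled separately and never alters the ground
truth: each true box is independently dropped (missed) with a configurable
probability, surviving boxes are jittered in center and size, and short-lived
false-positive boxes are injected at a Poisson rate per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Box, Detection, FrameDetections

__all__ = [
    "SceneConfig",
    "GroundTruthScene",
    "generate_scene",
    "corrupt_detections",
    "make_benchmark",
]

# Fixed sub-stream offsets so scene geometry, detection noise, and benchmark
# variation are independently reproducible from one master seed.
_STREAM_SCENE = 0
_STREAM_NOISE = 1
_STREAM_BENCH = 2


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one simulated video segment.

    Defaults mirror the field protocol the simulator emulates: 960x608-pixel
    frames, a mean of 14.6 object instances visible per frame, and a camera
    advance of 10 px/frame (a ~1.5 m strip traversed at walking speed over a
    ~300-frame clip).  Bud sizes are drawn from a truncated normal; the size
    distribution of real buds is not well characterised, so both moments are
    deliberately configurable.
    """

    image_width: float = 960.0
    image_height: float = 608.0
    n_frames: int = 300
    camera_speed: float = 10.0            # px/frame of downward scene flow
    mean_instances_per_frame: float = 14.6
    bud_width_mean: float = 45.0
    bud_width_sd: float = 10.0
    bud_height_mean: float = 60.0
    bud_height_sd: float = 12.0
    min_bud_size: float = 8.0
    miss_probability: float = 0.0
    false_positives_per_frame: float = 0.0
    center_jitter_sd: float = 0.0         # px
    size_jitter_sd: float = 0.0           # fraction of box size
    entering_fraction: float = 0.25
    baseline_fraction: float = 0.75
    seed: int = 0

    def violations(self) -> list[str]:
        problems = []
        if self.camera_speed <= 0:
            problems.append(f"camera_speed must be positive, got {self.camera_speed}")
        if not 0.0 <= self.miss_probability <= 1.0:
            problems.append(f"miss_probability must be in [0, 1], got {self.miss_probability}")
        if self.false_positives_per_frame < 0:
            problems.append("false_positives_per_frame must be non-negative")
        if self.center_jitter_sd < 0 or self.size_jitter_sd < 0:
            problems.append("jitter magnitudes must be non-negative")
        if not 0.0 < self.entering_fraction < self.baseline_fraction < 1.0:
            problems.append(
                "need 0 < entering_fraction < baseline_fraction < 1, got "
                f"{self.entering_fraction} and {self.baseline_fraction}"
            )
        if self.mean_instances_per_frame <= 0:
            problems.append("mean_instances_per_frame must be positive")
        if self.image_width <= 0 or self.image_height <= 0:
            problems.append("image dimensions must be positive")
        return problems

    def __post_init__(self) -> None:
        problems = self.violations()
        if problems:
            raise ValueError("; ".join(problems))

    @property
    def baseline_y(self) -> float:
        return self.baseline_fraction * self.image_height

    @property
    def entering_limit_y(self) -> float:
        return self.entering_fraction * self.image_height


@dataclass(frozen=True)
class GroundTruthScene:
    """Noise-free simulator output: per-frame true boxes and the true count."""

    frames: tuple[tuple[tuple[int, Box], ...], ...]  # frames[t] = ((object id, Box), ...)
    true_crossing_count: int
    n_objects: int
    config: SceneConfig


def generate_scene(cfg: SceneConfig) -> GroundTruthScene:
    """Generate one ground-truth scene, fully determined by ``cfg.seed``.

    The true crossing count is the number of objects whose center passes the
    counting baseline between two consecutive visible frames — the quantity a
    perfect cross-line counter would report.
    """
    if cfg.n_frames <= 0:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng([cfg.seed, _STREAM_SCENE])
    H, W, v = cfg.image_height, cfg.image_width, cfg.camera_speed

    # Linear intensity (objects per world-pixel of strip) that yields the
    # requested mean count of visible centers per frame at stationarity.
    density = cfg.mean_instances_per_frame / H
    y_lo = -v * (cfg.n_frames - 1)
    y_hi = cfg.entering_limit_y  # strip empty below the entering limit at t=0
    n_objects = int(rng.poisson(density * (y_hi - y_lo)))

    y0 = rng.uniform(y_lo, y_hi, size=n_objects)
    # Sizes are normal draws truncated two standard deviations below the
    # mean (never below min_bud_size): a pickable bud has a bounded minimum
    # physical size, so the far-left tail of the normal is unphysical.
    w_floor = max(cfg.min_bud_size, cfg.bud_width_mean - 2 * cfg.bud_width_sd)
    h_floor = max(cfg.min_bud_size, cfg.bud_height_mean - 2 * cfg.bud_height_sd)
    widths = np.clip(
        rng.normal(cfg.bud_width_mean, cfg.bud_width_sd, size=n_objects), w_floor, None
    )
    heights = np.clip(
        rng.normal(cfg.bud_height_mean, cfg.bud_height_sd, size=n_objects), h_floor, None
    )
    cx = rng.uniform(widths / 2, W - widths / 2)

    frames: list[tuple[tuple[int, Box], ...]] = []
    first_y = np.full(n_objects, np.nan)
    last_y = np.full(n_objects, np.nan)
    for t in range(cfg.n_frames):
        y = y0 + v * t
        visible = np.flatnonzero((y >= 0.0) & (y < H))
        entries = []
        for i in visible:
            if np.isnan(first_y[i]):
                first_y[i] = y[i]
            last_y[i] = y[i]
            entries.append(
                (int(i), Box.from_center(cx[i], y[i], widths[i], heights[i]))
            )
        frames.append(tuple(entries))

    seen = ~np.isnan(first_y)
    crossings = int(
        np.sum(seen & (first_y < cfg.baseline_y) & (last_y >= cfg.baseline_y))
    )
    return GroundTruthScene(
        frames=tuple(frames),
        true_crossing_count=crossings,
        n_objects=n_objects,
        config=cfg,
    )


def corrupt_detections(scene: GroundTruthScene, cfg: SceneConfig | None = None) -> list[FrameDetections]:
    """Turn a ground-truth scene into a noisy detection stream.

    Pure function of the scene and the noise parameters: each true box is
    dropped with ``miss_probability``, survivors get Gaussian center jitter
    and multiplicative size jitter, and uniformly placed single-frame false
    positives with low confidence are added at ``false_positives_per_frame``.
    With all noise parameters zero the detections reproduce the ground-truth
    boxes exactly.
    """
    cfg = cfg or scene.config
    rng = np.random.default_rng([cfg.seed, _STREAM_NOISE])
    H, W = cfg.image_height, cfg.image_width

    stream: list[FrameDetections] = []
    for t, entries in enumerate(scene.frames):
        dets: list[Detection] = []
        for _, box in entries:
            if cfg.miss_probability > 0 and rng.random() < cfg.miss_probability:
                continue
            if cfg.center_jitter_sd > 0 or cfg.size_jitter_sd > 0:
                cx, cy = box.center
                w, h = box.width, box.height
                if cfg.center_jitter_sd > 0:
                    cx += rng.normal(0.0, cfg.center_jitter_sd)
                    cy += rng.normal(0.0, cfg.center_jitter_sd)
                if cfg.size_jitter_sd > 0:
                    w *= max(0.2, 1.0 + rng.normal(0.0, cfg.size_jitter_sd))
                    h *= max(0.2, 1.0 + rng.normal(0.0, cfg.size_jitter_sd))
                det_box = Box.from_center(cx, cy, w, h)
            else:
                det_box = box  # bit-exact ground truth when jitter is off
            conf = float(rng.uniform(0.6, 0.98))
            dets.append(Detection(det_box, conf, t))
        if cfg.false_positives_per_frame > 0:
            for _ in range(int(rng.poisson(cfg.false_positives_per_frame))):
                w = rng.uniform(10.0, 60.0)
                h = rng.uniform(10.0, 60.0)
                fcx = rng.uniform(w / 2, W - w / 2)
                fcy = rng.uniform(h / 2, H - h / 2)
                conf = float(rng.uniform(0.1, 0.6))
                dets.append(Detection(Box.from_center(fcx, fcy, w, h), conf, t))
        stream.append(FrameDetections(t, dets))
    return stream


def make_benchmark(
    n_videos: int = 21,
    base_cfg: SceneConfig | None = None,
    seed: int = 0,
) -> list[tuple[list[FrameDetections], int]]:
    """A benchmark of independent seeded videos: (detection stream, true count) pairs.

    Mirrors an evaluation on a set of video segments cut from a longer field
    recording: each video gets its own derived seed plus mild (+-20%) length
    and density variation around the base configuration.
    """
    if n_videos < 1:
        raise ValueError("n_videos must be >= 1")
    base = base_cfg or SceneConfig()
    rng = np.random.default_rng([seed, _STREAM_BENCH])
    videos: list[tuple[list[FrameDetections], int]] = []
    for _ in range(n_videos):
        vid_seed = int(rng.integers(0, 2**31 - 1))
        length = int(round(base.n_frames * rng.uniform(0.8, 1.2)))
        density = base.mean_instances_per_frame * rng.uniform(0.8, 1.2)
        cfg = replace(
            base, seed=vid_seed, n_frames=length, mean_instances_per_frame=density
        )
        scene = generate_scene(cfg)
        videos.append((corrupt_detections(scene, cfg), scene.true_crossing_count))
    return videos
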