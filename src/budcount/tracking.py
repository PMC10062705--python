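"""Tracker lifecycle: prediction, association, update, birth, miss accounting, death.

Each tracked object carries a Kalman state plus three bookkeeping counters
borrowed from SORT-style trackers:

* ``misses`` — consecutive frames without a matched detection.  A track is
  discarded once ``misses`` reaches the miss threshold (``max_misses``); this
  absorbs detector dropouts shorter than the threshold while pruning tracks
  whose object has genuinely left the view.
* ``hits`` — cumulative matched frames.  A track's count event is only valid
  once ``hits`` strictly exceeds the validity threshold (``min_hits``),
  which rejects short-lived clutter tracks spawned by false positives.
* ``counted`` — set once, when the track's center crosses the counting
  baseline (see :mod:`budcount.counting`).

Per frame, the step is: predict every track forward; drop low-confidence
detections and detections still inside the entering area (objects near the
image edge are distorted and not yet tracked); associate predictions with the
surviving detections by Hungarian IoU matching; Kalman-update the matched
tracks; spawn a new track for every unmatched detection; increment ``misses``
for unmatched tracks, which coast on their prediction; and remove tracks
whose ``misses`` reached the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import kalman
from .association import iou_cost_matrix, match
from .core import Box, Detection, FrameDetections, box_to_measurement, measurement_to_box
from .kalman import KalmanState, NoiseModel

__all__ = ["Track", "TrackerConfig", "Tracker", "new_track"]


@dataclass
class TrackerConfig:
    """Tunable parameters of the tracker and counting zones.

    ``entering_fraction`` and ``baseline_fraction`` position the entering-area
    limit and the counting baseline as fractions of the image height (top of
    image = 0).  ``invert_flow`` flips the expected scene flow (and hence the
    counted crossing direction) from downward to upward for walks in the
    opposite direction.
    """

    iou_gate: float = 0.3
    max_misses: int = 5        # miss threshold: discard after this many lost frames
    min_hits: int = 3          # validity threshold: count only when hits exceed this
    min_confidence: float = 0.25
    entering_fraction: float = 0.25
    baseline_fraction: float = 0.75
    image_width: float = 960.0
    image_height: float = 608.0
    invert_flow: bool = False

    def violations(self) -> list[str]:
        """Every constraint violation, for all-at-once validation messages."""
        problems = []
        if not 0.0 < self.iou_gate < 1.0:
            problems.append(f"iou_gate must be in (0, 1), got {self.iou_gate}")
        if self.max_misses < 1:
            problems.append(f"max_misses must be >= 1, got {self.max_misses}")
        if self.min_hits < 1:
            problems.append(f"min_hits must be >= 1, got {self.min_hits}")
        if not 0.0 <= self.min_confidence <= 1.0:
            problems.append(f"min_confidence must be in [0, 1], got {self.min_confidence}")
        if not 0.0 < self.entering_fraction < self.baseline_fraction < 1.0:
            problems.append(
                "need 0 < entering_fraction < baseline_fraction < 1, got "
                f"{self.entering_fraction} and {self.baseline_fraction}"
            )
        if self.image_width <= 0 or self.image_height <= 0:
            problems.append("image dimensions must be positive")
        return problems

    def __post_init__(self) -> None:
        problems = self.violations()
        if problems:
            raise ValueError("; ".join(problems))

    @property
    def entering_limit_y(self) -> float:
        return self.entering_fraction * self.image_height

    @property
    def baseline_y(self) -> float:
        return self.baseline_fraction * self.image_height


@dataclass
class Track:
    """A persistent identity hypothesis for one object."""

    id: int
    state: KalmanState
    born_frame: int
    misses: int = 0
    hits: int = 1
    counted: bool = False
    prev_center: tuple[float, float] | None = None
    last_confidence: float = 0.0

    @property
    def box(self) -> Box:
        return measurement_to_box(self.state.measurement)

    @property
    def center(self) -> tuple[float, float]:
        return (float(self.state.mean[0]), float(self.state.mean[1]))


def new_track(
    d: Detection,
    next_id: int,
    born_frame: int,
    noise: NoiseModel | None = None,
) -> Track:
    """Spawn a fresh track from an unmatched detection.

    The birth state centers on the detection with zero velocity, so the
    track's box at birth equals the detection box exactly.
    """
    state = kalman.init_state(box_to_measurement(d.box), noise)
    return Track(
        id=next_id,
        state=state,
        born_frame=born_frame,
        misses=0,
        hits=1,
        counted=False,
        last_confidence=d.confidence,
    )


class Tracker:
    """Stateful per-frame tracker; feed frames in strictly increasing order."""

    def __init__(self, cfg: TrackerConfig | None = None, noise: NoiseModel | None = None):
        self.cfg = cfg or TrackerConfig()
        self.noise = noise or NoiseModel()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None

    def _in_entering_area(self, d: Detection) -> bool:
        _, cy = d.box.center
        if self.cfg.invert_flow:
            return cy >= self.cfg.image_height - self.cfg.entering_limit_y
        return cy < self.cfg.entering_limit_y

    def step(self, fd: FrameDetections) -> tuple[list[Track], list[Track]]:
        """Advance one frame; returns (live tracks, tracks that died this frame)."""
        if self._last_frame is not None and fd.frame <= self._last_frame:
            raise ValueError(
                f"frames must be strictly increasing: got {fd.frame} after {self._last_frame}"
            )
        self._last_frame = fd.frame
        cfg = self.cfg

        # Record last frame's center, then predict every track forward.
        for t in self.tracks:
            t.prev_center = t.center
            t.state = kalman.predict(t.state, self.noise)

        # Detections below the confidence floor or still in the entering area
        # are invisible to the tracker.
        usable = [
            d
            for d in fd.detections
            if d.confidence >= cfg.min_confidence and not self._in_entering_area(d)
        ]

        result = match(
            iou_cost_matrix([t.box for t in self.tracks], [d.box for d in usable]),
            cfg.iou_gate,
        )

        for ti, dj in result.matches:
            t = self.tracks[ti]
            d = usable[dj]
            t.state = kalman.update(t.state, box_to_measurement(d.box), self.noise)
            t.misses = 0
            t.hits += 1
            t.last_confidence = d.confidence

        for dj in result.unmatched_detections:
            self.tracks.append(new_track(usable[dj], self._next_id, fd.frame, self.noise))
            self._next_id += 1

        for ti in result.unmatched_tracks:
            self.tracks[ti].misses += 1

        live = [t for t in self.tracks if t.misses < cfg.max_misses]
        died = [t for t in self.tracks if t.misses >= cfg.max_misses]
        self.tracks = live
        return live, died


def step(
    tracks: list[Track],
    fd: FrameDetections,
    cfg: TrackerConfig,
    noise: NoiseModel | None = None,
    next_id: int | None = None,
) -> tuple[list[Track], list[Track]]:
    """One-shot functional wrapper around :class:`Tracker` for a single frame.

    ``next_id`` defaults to one past the largest existing id.
    """
    tracker = Tracker(cfg, noise)
    tracker.tracks = tracks
    tracker._next_id = next_id if next_id is not None else max((t.id for t in tracks), default=0) + 1
    return tracker.step(fd)
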