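"""Zone logic and cross-line counting.

The image is split by two horizontal lines into three regions: the *entering
area* at the top, where objects first appear distorted at the frame edge and
are neither tracked nor counted; the *counting area* in the middle, where
tracking happens; and the *counting baseline*, a fixed line near the bottom.
A count event fires the first time a valid track's center crosses the
baseline in the direction of scene flow, so each object is counted exactly
once no matter how long it stays in view.

Boundary conventions: zones are half-open (a center sitting exactly on the
entering limit is already in the counting area), and a crossing requires
strictly ``prev < baseline <= curr`` so a center parked exactly on the line
can never fire twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import pandas as pd

from .core import FrameDetections
from .kalman import NoiseModel
from .tracking import Track, Tracker, TrackerConfig

__all__ = [
    "Zone",
    "ZoneLayout",
    "Counter",
    "zone_of",
    "crossed",
    "count_step",
    "run_video",
    "VideoResult",
]


class Zone(str, Enum):
    ENTERING = "entering"
    COUNTING = "counting"
    BEYOND = "beyond"


@dataclass(frozen=True)
class ZoneLayout:
    """Pixel y-coordinates of the entering limit and the counting baseline."""

    entering_limit_y: float
    baseline_y: float
    image_height: float

    def __post_init__(self) -> None:
        if not 0.0 < self.entering_limit_y < self.baseline_y < self.image_height:
            raise ValueError(
                f"need 0 < entering limit ({self.entering_limit_y}) < baseline "
                f"({self.baseline_y}) < image height ({self.image_height})"
            )

    @classmethod
    def from_config(cls, cfg: TrackerConfig) -> "ZoneLayout":
        return cls(cfg.entering_limit_y, cfg.baseline_y, cfg.image_height)


@dataclass
class Counter:
    """Accumulates count events; one per track id, ever."""

    counted_ids: set[int] = field(default_factory=set)

    @property
    def total(self) -> int:
        return len(self.counted_ids)


def zone_of(center_y: float, layout: ZoneLayout) -> Zone:
    """Which region a center at image-row ``center_y`` falls into."""
    if center_y < layout.entering_limit_y:
        return Zone.ENTERING
    if center_y <= layout.baseline_y:
        return Zone.COUNTING
    return Zone.BEYOND


def crossed(prev_y: float, curr_y: float, baseline_y: float, invert: bool = False) -> bool:
    """True iff the center crossed the baseline along the flow direction.

    Default flow is downward in image coordinates (the scene scrolls toward
    the bottom as the camera advances); ``invert`` counts upward crossings
    instead.  Reverse-direction crossings never count.
    """
    if invert:
        return prev_y > baseline_y >= curr_y
    return prev_y < baseline_y <= curr_y


def count_step(
    tracks: Iterable[Track],
    counter: Counter,
    layout: ZoneLayout,
    cfg: TrackerConfig,
) -> Counter:
    """Fire count events for tracks crossing the baseline this frame.

    A crossing is a valid count only when the track's cumulative matched
    frames strictly exceed the validity threshold ``cfg.min_hits`` and the
    track has not been counted before.
    """
    baseline = layout.baseline_y
    if cfg.invert_flow:
        baseline = layout.image_height - layout.baseline_y
    for t in tracks:
        if t.counted or t.hits <= cfg.min_hits or t.prev_center is None:
            continue
        if crossed(t.prev_center[1], t.center[1], baseline, cfg.invert_flow):
            counter.counted_ids.add(t.id)
            t.counted = True
    return counter


@dataclass
class VideoResult:
    """Terminal count plus the full per-frame track and event logs."""

    count: int
    track_log: pd.DataFrame
    events: pd.DataFrame

    def __iter__(self):  # allows `count, log = run_video(...)`
        return iter((self.count, self.track_log))


_LOG_COLUMNS = ["frame", "id", "x1", "y1", "x2", "y2", "misses", "hits", "counted"]
_EVENT_COLUMNS = ["frame", "id", "event"]


def run_video(
    stream: Iterable[FrameDetections],
    cfg: TrackerConfig | None = None,
    noise: NoiseModel | None = None,
) -> VideoResult:
    """Run the full tracking + cross-line counting pipeline over one video.

    ``stream`` is an ordered sequence of per-frame detections with strictly
    increasing frame indices (an unordered stream raises).  Returns the final
    count together with a per-frame track log and an event log
    (born / matched / missed / died / counted rows).
    """
    cfg = cfg or TrackerConfig()
    layout = ZoneLayout.from_config(cfg)
    tracker = Tracker(cfg, noise)
    counter = Counter()

    log_rows: list[tuple] = []
    events: list[tuple[int, int, str]] = []

    for fd in stream:
        live, died = tracker.step(fd)
        before = set(counter.counted_ids)
        count_step(live, counter, layout, cfg)
        newly_counted = counter.counted_ids - before

        for t in died:
            events.append((fd.frame, t.id, "died"))
        for t in live:
            if t.born_frame == fd.frame:
                events.append((fd.frame, t.id, "born"))
            elif t.misses == 0:
                events.append((fd.frame, t.id, "matched"))
            else:
                events.append((fd.frame, t.id, "missed"))
            if t.id in newly_counted:
                events.append((fd.frame, t.id, "counted"))
            b = t.box
            log_rows.append(
                (fd.frame, t.id, b.x1, b.y1, b.x2, b.y2, t.misses, t.hits, t.counted)
            )

    return VideoResult(
        count=counter.total,
        track_log=pd.DataFrame(log_rows, columns=_LOG_COLUMNS),
        events=pd.DataFrame(events, columns=_EVENT_COLUMNS),
    )
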