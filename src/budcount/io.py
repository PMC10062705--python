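"""File formats and configuration.

Two detection-file dialects are supported:

* ``mot`` — MOT-Challenge-style CSV, one detection per row:
  ``frame, id, x, y, w, h, conf, ...`` with ``x, y`` the box top-left corner
  in pixels.  The id column is ignored on input (detections have no identity
  yet); trailing placeholder columns are tolerated.
* ``yolo_txt`` — one plain-text file per frame in a directory, rows
  ``class cx cy w h [conf]`` with coordinates normalised to [0, 1].  Image
  dimensions are required to denormalise; the frame index is the integer in
  the file's stem (``000012.txt`` -> frame 12).

All numeric parsing is strict: a malformed row raises a :class:`ParseError`
naming the file and line number rather than silently coercing.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import asdict, fields
from pathlib import Path

import pandas as pd
import yaml

from .core import Box, Detection, FrameDetections, group_by_frame
from .simulate import SceneConfig
from .tracking import TrackerConfig

__all__ = [
    "ParseError",
    "read_detections",
    "write_detections",
    "read_tracks",
    "write_tracks",
    "load_config",
]

DIALECTS = ("mot", "yolo_txt")


class ParseError(ValueError):
    """A detection/config file failed to parse; message names file and line."""


def _parse_float(token: str, path: Path, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: malformed {what} field {token!r}"
        ) from None


def _read_mot(path: Path) -> list[Detection]:
    dets: list[Detection] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 7:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 7 comma-separated fields, got {len(row)}"
                )
            frame_tok = row[0].strip()
            if not re.fullmatch(r"[+-]?\d+", frame_tok):
                raise ParseError(f"{path}:{lineno}: malformed frame index {row[0]!r}")
            frame = int(frame_tok)
            x, y, w, h, conf = (
                _parse_float(row[i], path, lineno, name)
                for i, name in zip(range(2, 7), ("x", "y", "w", "h", "conf"))
            )
            try:
                dets.append(Detection(Box.from_xywh(x, y, w, h), conf, frame))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return dets


_YOLO_FRAME_RE = re.compile(r"(\d+)")


def _read_yolo_dir(path: Path, image_width: float, image_height: float) -> list[Detection]:
    dets: list[Detection] = []
    txt_files = sorted(path.glob("*.txt"))
    if not txt_files:
        raise ParseError(f"{path}: no per-frame .txt files found")
    for f in txt_files:
        m = _YOLO_FRAME_RE.search(f.stem)
        if m is None:
            raise ParseError(f"{f}: cannot derive a frame index from the file name")
        frame = int(m.group(1))
        with open(f) as fh:
            for lineno, line in enumerate(fh, start=1):
                tokens = line.split()
                if not tokens:
                    continue
                if len(tokens) not in (5, 6):
                    raise ParseError(
                        f"{f}:{lineno}: expected 5 or 6 whitespace-separated fields, "
                        f"got {len(tokens)}"
                    )
                cx, cy, w, h = (
                    _parse_float(tok, f, lineno, name)
                    for tok, name in zip(tokens[1:5], ("cx", "cy", "w", "h"))
                )
                conf = (
                    _parse_float(tokens[5], f, lineno, "conf") if len(tokens) == 6 else 1.0
                )
                try:
                    box = Box.from_center(
                        cx * image_width, cy * image_height, w * image_width, h * image_height
                    )
                    dets.append(Detection(box, conf, frame))
                except ValueError as exc:
                    raise ParseError(f"{f}:{lineno}: {exc}") from None
    return dets


def read_detections(
    path: str | Path,
    dialect: str = "mot",
    image_width: float | None = None,
    image_height: float | None = None,
) -> list[FrameDetections]:
    """Read a detection stream, returned grouped per frame and frame-sorted."""
    path = Path(path)
    if dialect == "mot":
        dets = _read_mot(path)
    elif dialect == "yolo_txt":
        if image_width is None or image_height is None:
            raise ValueError("yolo_txt dialect requires image_width and image_height")
        dets = _read_yolo_dir(path, image_width, image_height)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    return group_by_frame(dets)


def write_detections(stream: list[FrameDetections], path: str | Path) -> None:
    """Write a detection stream as MOT-style CSV (id column -1)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for fd in stream:
            for d in fd.detections:
                b = d.box
                writer.writerow(
                    [fd.frame, -1, b.x1, b.y1, b.width, b.height, d.confidence, -1, -1, -1]
                )


_TRACK_COLUMNS = ["frame", "id", "x1", "y1", "x2", "y2", "misses", "hits", "counted"]


def write_tracks(track_log: pd.DataFrame, path: str | Path) -> None:
    """Write a track log as MOT-style CSV rows, sorted by (frame, id).

    Columns: frame, id, x, y, w, h, conf(=1), misses, hits, counted.
    """
    rows = track_log.sort_values(["frame", "id"], kind="mergesort")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for r in rows.itertuples(index=False):
            writer.writerow(
                [
                    int(r.frame), int(r.id),
                    r.x1, r.y1, r.x2 - r.x1, r.y2 - r.y1,
                    1.0, int(r.misses), int(r.hits), int(bool(r.counted)),
                ]
            )


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a track log written by :func:`write_tracks`."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 10:
                raise ParseError(f"{path}:{lineno}: expected 10 fields, got {len(row)}")
            frame, tid = int(row[0]), int(row[1])
            x, y, w, h = (_parse_float(row[i], path, lineno, "box") for i in range(2, 6))
            misses, hits, counted = int(row[7]), int(row[8]), bool(int(row[9]))
            rows.append((frame, tid, x, y, x + w, y + h, misses, hits, counted))
    return pd.DataFrame(rows, columns=_TRACK_COLUMNS)


_TRACKER_KEYS = {f.name for f in fields(TrackerConfig)}
_SCENE_KEYS = {f.name for f in fields(SceneConfig)}


def load_config(path: str | Path | None) -> tuple[TrackerConfig, SceneConfig]:
    """Load a flat key-value YAML config into tracker and scene configurations.

    Every key is optional and falls back to the documented default.  Keys are
    routed by name to :class:`TrackerConfig` and/or :class:`SceneConfig`
    (shared keys such as ``image_height`` apply to both).  Unknown keys emit
    a warning; invalid values raise one error listing every violation.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParseError(f"{path}: config must be a flat key-value mapping")
        raw = loaded

    unknown = sorted(set(raw) - _TRACKER_KEYS - _SCENE_KEYS)
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {', '.join(unknown)}", stacklevel=2)

    tracker_kwargs = {k: v for k, v in raw.items() if k in _TRACKER_KEYS}
    scene_kwargs = {k: v for k, v in raw.items() if k in _SCENE_KEYS}

    problems: list[str] = []
    tracker_cfg = scene_cfg = None
    try:
        tracker_cfg = TrackerConfig(**tracker_kwargs)
    except (ValueError, TypeError) as exc:
        problems.append(str(exc))
    try:
        scene_cfg = SceneConfig(**scene_kwargs)
    except (ValueError, TypeError) as exc:
        problems.append(str(exc))
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    return tracker_cfg, scene_cfg


def config_echo(cfg: TrackerConfig | SceneConfig) -> dict:
    """A plain-dict snapshot of a config, for sidecar metadata files."""
    return asdict(cfg)
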