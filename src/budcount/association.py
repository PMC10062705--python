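"""Frame-to-frame data association: IoU affinity plus optimal assignment.

Tracker-predicted boxes are paired with detected boxes by solving the
minimum-cost bipartite assignment problem on cost ``1 - IoU`` (Hungarian
algorithm).  Pairs whose IoU falls below a gate threshold are demoted to
unmatched on both sides, and pairs with zero IoU are masked out up front so
that disjoint boxes can never be forced together by the global optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import Box, iou

__all__ = ["AssociationResult", "iou_cost_matrix", "match"]

# Cost assigned to zero-IoU pairs: large enough that the optimiser always
# prefers leaving rows/columns unmatched over pairing disjoint boxes.
_INFEASIBLE = 1e6


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one association round.

    Every track index and detection index appears exactly once across
    ``matches``, ``unmatched_tracks`` and ``unmatched_detections``.
    """

    matches: tuple[tuple[int, int], ...] = ()
    unmatched_tracks: tuple[int, ...] = ()
    unmatched_detections: tuple[int, ...] = ()


def iou_cost_matrix(track_boxes: Sequence[Box], detections: Sequence[Box]) -> np.ndarray:
    """IoU affinity matrix: entry (i, j) = iou(track i, detection j)."""
    mat = np.zeros((len(track_boxes), len(detections)))
    for i, tb in enumerate(track_boxes):
        for j, db in enumerate(detections):
            mat[i, j] = iou(tb, db)
    return mat


def match(iou_matrix: np.ndarray, iou_gate: float = 0.3) -> AssociationResult:
    """Optimally assign tracks (rows) to detections (columns) by IoU.

    Maximises total assigned IoU (equivalently minimises total ``1 - IoU``),
    then demotes any assigned pair with IoU below ``iou_gate``.  Ties between
    equal-cost optima are broken toward the lexicographically smallest
    (track index, detection index) pairing.  Empty matrices are allowed and
    yield an all-unmatched result.
    """
    iou_matrix = np.asarray(iou_matrix, dtype=float)
    if iou_matrix.ndim != 2:
        raise ValueError("IoU matrix must be 2-D")
    if not 0.0 < iou_gate < 1.0:
        raise ValueError(f"iou_gate must be in (0, 1), got {iou_gate}")
    n_tracks, n_dets = iou_matrix.shape
    if n_tracks == 0 or n_dets == 0:
        return AssociationResult(
            unmatched_tracks=tuple(range(n_tracks)),
            unmatched_detections=tuple(range(n_dets)),
        )

    cost = 1.0 - iou_matrix
    cost[iou_matrix <= 0.0] = _INFEASIBLE
    # Deterministic tie-break: an index-ordered perturbation far below any
    # meaningful IoU difference steers equal-cost optima to the pairing that
    # is lexicographically smallest in (row, column).
    idx = np.arange(n_tracks)[:, None] * n_dets + np.arange(n_dets)[None, :]
    cost = cost + 1e-10 * idx / (n_tracks * n_dets)

    rows, cols = linear_sum_assignment(cost)

    matches: list[tuple[int, int]] = []
    unmatched_tracks = set(range(n_tracks))
    unmatched_dets = set(range(n_dets))
    for i, j in zip(rows, cols):
        if iou_matrix[i, j] >= iou_gate:
            matches.append((int(i), int(j)))
            unmatched_tracks.discard(int(i))
            unmatched_dets.discard(int(j))
    return AssociationResult(
        matches=tuple(sorted(matches)),
        unmatched_tracks=tuple(sorted(unmatched_tracks)),
        unmatched_detections=tuple(sorted(unmatched_dets)),
    )
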