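"""Elastic (non-linear) point manipulation.

A drag moves one activated anchor point and carries its unlocked
neighbours along with a displacement that decays linearly with distance
from the anchor and vanishes at the influence threshold T (default
1000 display pixels).  Locked points never move.
"""
from __future__ import annotations

import numpy as np

from .errors import StateError
from .model import DragEvent, PointSet, PointState

DEFAULT_THRESHOLD = 1000.0


def cycle_state(points: PointSet, point_id) -> PointState:
    """Advance one point through the click cycle idle→draggable→locked→idle.

    Returns the new state.  Other points are untouched.
    """
    i = points.index_of(point_id)
    new = PointState((int(points.state[i]) + 1) % 3)
    points.state[i] = new
    return new


def drag_displacement(x: np.ndarray, y: np.ndarray, event: DragEvent,
                      locked: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form displacement field of one drag event.

    D = √((x−x_a)² + (y−y_a)²); unlocked points with D < T move by
    (dx·(T−D)/T, dy·(T−D)/T); the anchor itself has D = 0 and moves by
    exactly (dx, dy).  Strictly D < T receives displacement (at D = T
    the factor is 0 anyway); points at D ≥ T and locked points get 0.
    """
    ax, ay = event.anchor_xy
    d = np.sqrt((x - ax) ** 2 + (y - ay) ** 2)
    factor = np.where((d < event.threshold) & ~locked,
                      (event.threshold - d) / event.threshold, 0.0)
    return event.dx * factor, event.dy * factor


def _locked_mask(ids: np.ndarray, locked_ids) -> np.ndarray:
    """Locked-id membership, compared as strings so that ids survive a
    CSV round trip (ints come back as strings)."""
    if not len(locked_ids):
        return np.zeros(len(ids), dtype=bool)
    return np.isin(ids.astype(str), np.asarray(list(locked_ids), dtype=str))


def apply_drag(points: PointSet, event: DragEvent,
               require_draggable: bool = True) -> PointSet:
    """Apply one drag event in place and return the point set.

    When ``require_draggable`` the anchor must be in the DRAGGABLE
    state (live-session rule); replay over the full dataset passes
    False since non-displayed points carry no interaction state.
    """
    if require_draggable:
        i = points.index_of(event.anchor_id)
        if points.state[i] == PointState.LOCKED:
            raise StateError(f"anchor {event.anchor_id!r} is locked")
        if points.state[i] != PointState.DRAGGABLE:
            raise StateError(
                f"anchor {event.anchor_id!r} must be draggable (one click)")
    locked = _locked_mask(points.ids, event.locked_ids)
    ddx, ddy = drag_displacement(points.x, points.y, event, locked)
    points.x = points.x + ddx
    points.y = points.y + ddy
    return points


def replay_drags(x: np.ndarray, y: np.ndarray, ids: np.ndarray,
                 events) -> tuple[np.ndarray, np.ndarray]:
    """Replay recorded drag events over arbitrary points, in order.

    Each event's field is evaluated against the event's snapshotted
    anchor position and threshold, so the result is well-defined for
    points that were never displayed.
    """
    for event in events:
        locked = _locked_mask(ids, event.locked_ids)
        ddx, ddy = drag_displacement(x, y, event, locked)
        x = x + ddx
        y = y + ddy
    return x, y
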