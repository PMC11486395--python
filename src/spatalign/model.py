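"""Core domain types for the registration engine.

Coordinates live in *display space*: one unit is one display pixel,
spanning ``display_scale`` micrometres.  The frame is y-up Cartesian;
image rasters are placed in the same frame with row 0 at the top edge,
so a point (x, y) falls on pixel column ``floor(x)`` and row
``height - 1 - floor(y)``.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


class PointState(enum.IntEnum):
    """Three-state click cycle of a data point.

    IDLE points are displayed but inert, DRAGGABLE points can anchor an
    elastic drag, LOCKED points stay in place under any drag.
    """

    IDLE = 0
    DRAGGABLE = 1
    LOCKED = 2


@dataclass
class PointSet:
    """Annotated 2-D observation coordinates with interaction state.

    Parameters
    ----------
    ids
        Unique opaque identifiers, one per observation.
    x, y
        Coordinates (display units once scaled; raw units on load).
    annotation
        Optional categorical label per observation (cluster / cell type).
    visible
        Cluster-selection mask; invisible points still receive every
        transform and are always exported.
    state
        Per-point :class:`PointState`.
    counts
        Optional genes × observations raw-count table whose columns are
        ``ids`` in order.
    """

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    annotation: Optional[np.ndarray] = None
    visible: np.ndarray = None  # type: ignore[assignment]
    state: np.ndarray = None  # type: ignore[assignment]
    counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        n = len(self.ids)
        if self.visible is None:
            self.visible = np.ones(n, dtype=bool)
        else:
            self.visible = np.asarray(self.visible, dtype=bool)
        if self.state is None:
            self.state = np.zeros(n, dtype=np.int8)
        else:
            self.state = np.asarray(self.state, dtype=np.int8)
        if self.annotation is not None:
            self.annotation = np.asarray(self.annotation)
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self) -> None:
        n = len(self.ids)
        if n == 0:
            raise ValidationError("point set must contain at least one observation")
        for name in ("x", "y", "visible", "state"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValidationError(f"{name} has {len(arr)} entries, expected {n}")
        if self.annotation is not None and len(self.annotation) != n:
            raise ValidationError("annotation length mismatch")
        if len(np.unique(self.ids)) != n:
            raise ValidationError("point ids must be unique")
        if self.counts is not None and list(self.counts.columns) != list(self.ids):
            raise ValidationError("counts columns must equal ids, in order")

    @property
    def n(self) -> int:
        return len(self.ids)

    def copy(self) -> "PointSet":
        return PointSet(
            ids=self.ids.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            annotation=None if self.annotation is None else self.annotation.copy(),
            visible=self.visible.copy(),
            state=self.state.copy(),
            counts=None if self.counts is None else self.counts.copy(),
        )

    def subset(self, indices: Sequence[int]) -> "PointSet":
        """Row-subset (used for display downsampling and filtering)."""
        idx = np.asarray(indices)
        return PointSet(
            ids=self.ids[idx],
            x=self.x[idx],
            y=self.y[idx],
            annotation=None if self.annotation is None else self.annotation[idx],
            visible=self.visible[idx],
            state=self.state[idx],
            counts=None if self.counts is None else self.counts.iloc[:, idx],
        )

    def index_of(self, point_id) -> int:
        hits = np.flatnonzero(self.ids == point_id)
        if len(hits) == 0:
            raise KeyError(f"unknown point id {point_id!r}")
        return int(hits[0])


@dataclass
class ImageRaster:
    """Microscopy image with a user-supplied physical pixel size.

    ``pixels`` is (height, width) or (height, width, channels) uint8;
    ``pixel_size`` is μm per pixel and must come from the user — it is
    never inferred from file metadata.
    """

    pixels: np.ndarray
    pixel_size: float
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValidationError("image must be 2-D or 2-D × channels")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be > 0")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def grayscale(self) -> np.ndarray:
        """Luma-weighted grayscale as float in [0, 1]."""
        px = self.pixels.astype(np.float64)
        if px.ndim == 3:
            px = px[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
        if px.max() > 1.0:
            px = px / 255.0
        return px


@dataclass(frozen=True)
class ScaleSpec:
    """The three μm-per-pixel scales tying raw inputs to display space."""

    data_scale: float
    image_scale: float
    display_scale: float

    def __post_init__(self) -> None:
        for name in ("data_scale", "image_scale", "display_scale"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")

    def with_display(self, display_scale: float) -> "ScaleSpec":
        return replace(self, display_scale=display_scale)


@dataclass
class RigidState:
    """Cumulative linear-manipulation summary shown to the user.

    ``theta_deg`` is the widget angle: incremented by rotations and
    negated by every flip.  ``center`` is the rotation/flip pivot,
    computed once at load and never mutated afterwards.
    """

    center: tuple[float, float]
    theta_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    flips_h: int = 0
    flips_v: int = 0


@dataclass(frozen=True)
class LogEntry:
    sequence: int
    op: str
    params: tuple[float, ...] = ()


@dataclass
class TransformLog:
    """Ordered, replayable record of linear manipulations.

    ``entries[0:cursor]`` replayed onto the original scaled coordinates
    reproduce the live coordinates exactly; entries beyond the cursor
    are redoable and are discarded by any new operation.
    """

    entries: list[LogEntry] = field(default_factory=list)
    cursor: int = 0

    def append(self, op: str, params: tuple[float, ...] = ()) -> LogEntry:
        del self.entries[self.cursor:]  # a new op kills the redo branch
        entry = LogEntry(sequence=len(self.entries), op=op, params=params)
        self.entries.append(entry)
        self.cursor = len(self.entries)
        return entry

    @property
    def applied(self) -> list[LogEntry]:
        return self.entries[: self.cursor]

    @property
    def can_undo(self) -> bool:
        return self.cursor > 0

    @property
    def can_redo(self) -> bool:
        return self.cursor < len(self.entries)


@dataclass(frozen=True)
class DragEvent:
    """One committed elastic manipulation.

    The anchor position is snapshotted at drag start so the event can be
    replayed over the full dataset; points in ``locked_ids`` are immune.
    """

    anchor_id: object
    anchor_xy: tuple[float, float]
    dx: float
    dy: float
    threshold: float
    locked_ids: tuple = ()

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValidationError("drag threshold must be > 0")
        if self.anchor_id in self.locked_ids:
            raise ValidationError("anchor cannot be locked")
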