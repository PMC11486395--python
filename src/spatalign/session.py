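"""Headless registration session.

Mirrors the interactive workflow without a GUI: load raw points and an
image, bring them to a common display scale, manipulate the displayed
(possibly downsampled) points with linear ops plus undo/redo, then —
once the linear phase is closed — apply elastic drags.  Export replays
the full log and drag record over *every* original observation, so the
output coordinates file always contains all data points.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from . import elastic, transforms
from .downsample import downsample as _downsample
from .errors import ModeError, StateError, ValidationError
from .model import (DragEvent, ImageRaster, PointSet, PointState, RigidState,
                    ScaleSpec, TransformLog)


class SpatalignWarning(UserWarning):
    """Non-fatal session conditions (empty undo stack, degenerate mask)."""


def replay_full(raw_points: PointSet, spec: ScaleSpec,
                center: tuple[float, float], entries,
                drag_events: Sequence[DragEvent]) -> PointSet:
    """Replay a recorded session over all original observations.

    Applies scaling to display space, then the applied linear log
    entries in order, then every drag event in order (each evaluated
    with its snapshotted anchor position and threshold).  Requires no
    live session state: the bundle is self-sufficient.
    """
    out = transforms.scale_points(raw_points, spec)
    x, y, _ = transforms.replay_entries(out.x, out.y, entries, center)
    x, y = elastic.replay_drags(x, y, out.ids, drag_events)
    out.x, out.y = x, y
    return out


class Session:
    """One registration of a point dataset to a microscopy image.

    Parameters
    ----------
    raw_points
        Observations in their native coordinate units.
    spec
        data/image/display μm-per-pixel scales.
    image
        Optional microscopy raster; rescaled to the display scale.
    center
        Optional explicit rotation/flip pivot in display units; by
        default the bounding-box center of the scaled full point set.
    """

    def __init__(self, raw_points: PointSet, spec: ScaleSpec,
                 image: Optional[ImageRaster] = None,
                 center: Optional[tuple[float, float]] = None) -> None:
        self.raw_points = raw_points
        self.spec = spec
        self._scaled_full = transforms.scale_points(raw_points, spec)
        self.image_raw = image
        self.image = transforms.scale_image(image, spec) if image else None
        self._initial_display_scale = spec.display_scale
        if center is None:
            center = transforms.compute_center(self._scaled_full)
        self.state = RigidState(center=center)
        self.log = TransformLog()
        self.drag_events: list[DragEvent] = []
        self._display_idx = np.arange(raw_points.n)
        self.display = self._scaled_full.copy()
        self._elastic_mode = False

    # -- display downsampling ----------------------------------------
    def downsample_display(self, target: int, seed: int) -> np.ndarray:
        """Reduce the displayed set; the full set is still exported."""
        if self.log.entries or self.drag_events:
            raise ModeError("downsample before manipulating, not after")
        self._display_idx = _downsample(self.raw_points, target, seed)
        self.display = self._scaled_full.subset(self._display_idx)
        return self._display_idx

    @property
    def display_indices(self) -> np.ndarray:
        return self._display_idx

    # -- linear phase -------------------------------------------------
    def _require_linear(self) -> None:
        if self._elastic_mode:
            raise ModeError("linear manipulations are frozen once the "
                            "elastic phase has begun")

    def rotate(self, theta_deg: float) -> None:
        self._require_linear()
        self.display.x, self.display.y = transforms.rotate_xy(
            self.display.x, self.display.y, theta_deg, self.state.center)
        self.state.theta_deg += theta_deg
        self.log.append("rotate", (theta_deg,))

    def translate(self, tx: float, ty: float) -> None:
        self._require_linear()
        self.display.x, self.display.y = transforms.translate_xy(
            self.display.x, self.display.y, tx, ty)
        self.state.tx += tx
        self.state.ty += ty
        self.log.append("translate", (tx, ty))

    def flip(self, axis: str) -> None:
        """Rotation-compensated mirror; negates the widget angle."""
        self._require_linear()
        if axis in ("v", "vertical", "vertical_plane"):
            axis_name, op = "vertical", "flip_v"
        elif axis in ("h", "horizontal", "horizontal_plane"):
            axis_name, op = "horizontal", "flip_h"
        else:
            raise ValidationError(f"unknown flip axis {axis!r}")
        self.display.x, self.display.y = transforms.flip_xy(
            self.display.x, self.display.y, axis_name,
            self.state.theta_deg, self.state.center)
        if op == "flip_v":
            self.state.flips_v += 1
        else:
            self.state.flips_h += 1
        self.state.theta_deg = -self.state.theta_deg
        self.log.append(op)

    def rescale(self, new_display_scale: float) -> None:
        """Change the common display scale; logged like any other op."""
        self._require_linear()
        if not new_display_scale > 0:
            raise ValidationError("display scale must be > 0")
        factor = self.spec.display_scale / new_display_scale
        self.display.x, self.display.y = transforms.scale_xy(
            self.display.x, self.display.y, factor)
        self.spec = self.spec.with_display(new_display_scale)
        if self.image_raw is not None:
            self.image = transforms.scale_image(self.image_raw, self.spec)
        self.log.append("scale", (factor,))

    def rotate_image(self, theta_deg: float) -> None:
        """Nearest-neighbor raster rotation; ignored by point replay."""
        self._require_linear()
        if self.image is None:
            raise ValidationError("no image loaded")
        self.image = transforms.rotate_image(self.image, theta_deg)
        self.log.append("image_rotate", (theta_deg,))

    # -- undo / redo ----------------------------------------------------
    def _replay_display(self) -> None:
        base = self._scaled_full.subset(self._display_idx)
        x, y, theta = transforms.replay_entries(
            base.x, base.y, self.log.applied, self.state.center)
        self.display.x, self.display.y = x, y
        self._resync_state(theta)

    def _resync_state(self, theta: float) -> None:
        self.state.theta_deg = theta
        tx = ty = 0.0
        fh = fv = 0
        for e in self.log.applied:
            if e.op == "translate":
                tx += e.params[0]
                ty += e.params[1]
            elif e.op == "flip_h":
                fh += 1
            elif e.op == "flip_v":
                fv += 1
        self.state.tx, self.state.ty = tx, ty
        self.state.flips_h, self.state.flips_v = fh, fv
        scale = self._initial_display_scale
        for e in self.log.applied:
            if e.op == "scale":
                scale = scale / e.params[0]
        if scale != self.spec.display_scale:
            self.spec = self.spec.with_display(scale)
            if self.image_raw is not None:
                self.image = transforms.scale_image(self.image_raw, self.spec)

    def undo(self) -> bool:
        self._require_linear()
        if not self.log.can_undo:
            warnings.warn("nothing to undo", SpatalignWarning)
            return False
        self.log.cursor -= 1
        self._replay_display()
        return True

    def redo(self) -> bool:
        self._require_linear()
        if not self.log.can_redo:
            warnings.warn("nothing to redo", SpatalignWarning)
            return False
        self.log.cursor += 1
        self._replay_display()
        return True

    # -- cluster selection ---------------------------------------------
    def set_cluster_visible(self, label, visible: bool) -> None:
        """Toggle display of one annotation group; transforms still apply."""
        if self.display.annotation is None:
            raise ValidationError("no annotation loaded")
        self.display.visible[self.display.annotation == label] = visible

    # -- elastic phase ---------------------------------------------------
    def begin_elastic(self) -> None:
        """Close the linear phase; drags become legal, linear ops freeze."""
        self._elastic_mode = True

    def cycle_state(self, point_id) -> PointState:
        return elastic.cycle_state(self.display, point_id)

    def drag(self, anchor_id, dx: float, dy: float,
             threshold: float = elastic.DEFAULT_THRESHOLD) -> DragEvent:
        """Commit one elastic drag of an activated point."""
        if not self._elastic_mode:
            raise ModeError("non-linear manipulations require the linear "
                            "phase to be closed (call begin_elastic first)")
        i = self.display.index_of(anchor_id)
        if self.display.state[i] == PointState.LOCKED:
            raise StateError(f"anchor {anchor_id!r} is locked")
        if self.display.state[i] != PointState.DRAGGABLE:
            raise StateError(f"anchor {anchor_id!r} must be draggable")
        locked = tuple(
            self.display.ids[self.display.state == PointState.LOCKED])
        event = DragEvent(
            anchor_id=anchor_id,
            anchor_xy=(float(self.display.x[i]), float(self.display.y[i])),
            dx=float(dx), dy=float(dy), threshold=float(threshold),
            locked_ids=locked)
        elastic.apply_drag(self.display, event)
        self.drag_events.append(event)
        return event

    def reset_elastic(self) -> None:
        """Strip all drags, keeping only the linear transformations."""
        self._replay_display()
        self.drag_events = []
        self.display.state[:] = PointState.IDLE

    # -- export -----------------------------------------------------------
    def replay_full(self) -> PointSet:
        """Registered coordinates for every original observation.

        Replays from the display scale at load; any later rescale is a
        logged ``scale`` entry and is re-applied by the replay itself.
        """
        spec0 = self.spec.with_display(self._initial_display_scale)
        return replay_full(self.raw_points, spec0, self.state.center,
                           self.log.applied, self.drag_events)


def initial_display_scale(final_display_scale: float, entries) -> float:
    """Recover the at-load display scale from a recorded log.

    Each logged ``scale`` entry stores the factor old/new, so the
    initial scale is the final one times the product of the factors.
    """
    scale = final_display_scale
    for e in entries:
        if e.op == "scale":
            scale = scale * e.params[0]
    return scale
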