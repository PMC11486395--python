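"""Linear (rigid) manipulations of points and images.

Every operation here is an elementary coordinate update applied in
sequence; replaying a log applies the same elementary updates in the
same order, which makes replay bit-consistent with the live session.

Angles are degrees, counterclockwise-positive in the y-up display frame.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
from PIL import Image

from .errors import NoDataError, ReplayError, ValidationError
from .model import ImageRaster, LogEntry, PointSet, ScaleSpec


def compute_center(points: PointSet) -> tuple[float, float]:
    """Center of the axis-aligned bounding box of *all* points.

    This is the pivot used by rotation and flips; it is computed once at
    load (visible and invisible points alike) and then held fixed so
    undo/redo are exact inverses.
    """
    if points.n == 0:
        raise NoDataError("no data loaded")
    return (
        (float(points.x.min()) + float(points.x.max())) / 2.0,
        (float(points.y.min()) + float(points.y.max())) / 2.0,
    )


# ---------------------------------------------------------------------
# elementary coordinate updates (shared by live ops and replay)
# ---------------------------------------------------------------------

def rotate_xy(x: np.ndarray, y: np.ndarray, theta_deg: float,
              center: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """x_n = (x−x_c)·cosθ − (y−y_c)·sinθ + x_c, and likewise for y."""
    xc, yc = center
    th = np.radians(theta_deg)
    c, s = np.cos(th), np.sin(th)
    dx, dy = x - xc, y - yc
    return dx * c - dy * s + xc, dx * s + dy * c + yc


def translate_xy(x: np.ndarray, y: np.ndarray, tx: float, ty: float):
    return x + tx, y + ty


def mirror_xy(x: np.ndarray, y: np.ndarray, axis: str,
              center: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Mirror about the axis through the pivot.

    ``vertical`` reflects x (left-right flip), ``horizontal`` reflects y
    (top-bottom flip).
    """
    xc, yc = center
    if axis == "vertical":
        return xc + (xc - x), y
    if axis == "horizontal":
        return x, yc + (yc - y)
    raise ValidationError(f"unknown flip axis {axis!r}")


def flip_xy(x: np.ndarray, y: np.ndarray, axis: str, theta_deg: float,
            center: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-compensated flip: three operations in order.

    (1) rotate by −θ about the pivot to undo any accumulated rotation,
    (2) mirror about the requested axis through the pivot,
    (3) rotate by −θ again, re-applying the rotation in the opposite
    direction.  The caller negates the widget angle to match.
    """
    x, y = rotate_xy(x, y, -theta_deg, center)
    x, y = mirror_xy(x, y, axis, center)
    x, y = rotate_xy(x, y, -theta_deg, center)
    return x, y


def scale_xy(x: np.ndarray, y: np.ndarray, factor: float):
    """Uniform scaling about the display-frame origin."""
    if not factor > 0:
        raise ValidationError("scale factor must be > 0")
    return x * factor, y * factor


# ---------------------------------------------------------------------
# bringing raw inputs to the common display scale
# ---------------------------------------------------------------------

def scale_points(points: PointSet, spec: ScaleSpec) -> PointSet:
    """Convert raw coordinates to display pixels.

    A raw coordinate c at ``data_scale`` μm/px spans c·data_scale μm,
    which occupies c·data_scale/display_scale display pixels — the
    μm-conserving form of the common-scale rule.
    """
    factor = spec.data_scale / spec.display_scale
    out = points.copy()
    out.x, out.y = scale_xy(out.x, out.y, factor)
    return out


def scale_image(image: ImageRaster, spec: ScaleSpec,
                resample: int = Image.BILINEAR) -> ImageRaster:
    """Resample the raster to the display scale, conserving μm extent."""
    factor = image.pixel_size / spec.display_scale
    if not factor > 0:
        raise ValidationError("scales must be strictly positive")
    new_w = max(1, round(image.width * factor))
    new_h = max(1, round(image.height * factor))
    if (new_w, new_h) == (image.width, image.height):
        pixels = image.pixels.copy()
    else:
        pil = Image.fromarray(image.pixels)
        pixels = np.asarray(pil.resize((new_w, new_h), resample=resample))
    return ImageRaster(pixels=pixels, pixel_size=spec.display_scale,
                       name=image.name)


def rotate_image(image: ImageRaster, theta_deg: float) -> ImageRaster:
    """Rotate the raster with nearest-neighbor resampling.

    Rotation is counterclockwise in the y-up frame; PIL's ``rotate`` is
    counterclockwise in row-major display, which coincides.
    """
    pil = Image.fromarray(image.pixels)
    rotated = pil.rotate(theta_deg, resample=Image.NEAREST,
                         expand=False, fillcolor=255)
    return ImageRaster(pixels=np.asarray(rotated),
                       pixel_size=image.pixel_size, name=image.name)


# ---------------------------------------------------------------------
# log replay
# ---------------------------------------------------------------------

POINT_OPS = {"rotate", "translate", "flip_h", "flip_v", "scale"}
IMAGE_OPS = {"image_rotate"}


def replay_entries(x: np.ndarray, y: np.ndarray, entries: Iterable[LogEntry],
                   center: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, float]:
    """Apply logged linear ops in order; returns coords and final angle.

    The accumulated angle is tracked because flips are conjugated
    through it and negate it.
    """
    theta = 0.0
    for e in entries:
        if e.op == "rotate":
            x, y = rotate_xy(x, y, e.params[0], center)
            theta += e.params[0]
        elif e.op == "translate":
            x, y = translate_xy(x, y, e.params[0], e.params[1])
        elif e.op == "flip_v":
            x, y = flip_xy(x, y, "vertical", theta, center)
            theta = -theta
        elif e.op == "flip_h":
            x, y = flip_xy(x, y, "horizontal", theta, center)
            theta = -theta
        elif e.op == "scale":
            x, y = scale_xy(x, y, e.params[0])
        elif e.op in IMAGE_OPS:
            continue  # image-only ops never touch point coordinates
        else:
            raise ReplayError(f"unknown op {e.op!r} in log")
    return x, y, theta
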