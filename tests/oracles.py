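"""Independent oracles used to cross-check the engine.

Everything here is implemented from first principles with 3×3
homogeneous matrices (or brute-force loops) and never calls the
engine's own transform code.
"""
from __future__ import annotations

import math

import numpy as np


def hom_translate(tx: float, ty: float) -> np.ndarray:
    m = np.eye(3)
    m[0, 2], m[1, 2] = tx, ty
    return m


def hom_rotate(theta_deg: float, center=(0.0, 0.0)) -> np.ndarray:
    th = math.radians(theta_deg)
    r = np.array([[math.cos(th), -math.sin(th), 0.0],
                  [math.sin(th), math.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    return hom_translate(*center) @ r @ hom_translate(-center[0], -center[1])


def hom_mirror(axis: str, center=(0.0, 0.0)) -> np.ndarray:
    m = np.eye(3)
    if axis == "vertical":
        m[0, 0] = -1.0
    elif axis == "horizontal":
        m[1, 1] = -1.0
    else:
        raise ValueError(axis)
    return hom_translate(*center) @ m @ hom_translate(-center[0], -center[1])


def hom_scale(factor: float) -> np.ndarray:
    return np.diag([factor, factor, 1.0])


def hom_flip(axis: str, theta_deg: float, center) -> np.ndarray:
    """The three-step rotation-compensated flip as a single matrix:
    rotate(−θ) then mirror then rotate(−θ), composed right-to-left."""
    r = hom_rotate(-theta_deg, center)
    return r @ hom_mirror(axis, center) @ r


def apply_hom(matrix: np.ndarray, x: np.ndarray, y: np.ndarray):
    pts = np.stack([x, y, np.ones_like(x)])
    out = matrix @ pts
    return out[0], out[1]


def compose_ops(ops, center) -> np.ndarray:
    """Ordered op list → single matrix, tracking the widget angle.

    ``ops`` are tuples ("rotate", θ) / ("translate", tx, ty) /
    ("flip", axis) / ("scale", factor).  Flips are conjugated through
    the accumulated angle and negate it, as the engine specifies.
    """
    m = np.eye(3)
    theta = 0.0
    for op in ops:
        if op[0] == "rotate":
            m = hom_rotate(op[1], center) @ m
            theta += op[1]
        elif op[0] == "translate":
            m = hom_translate(op[1], op[2]) @ m
        elif op[0] == "flip":
            m = hom_flip(op[1], theta, center) @ m
            theta = -theta
        elif op[0] == "scale":
            m = hom_scale(op[1]) @ m
        else:
            raise ValueError(op)
    return m


def brute_force_drag(x, y, anchor_xy, dx, dy, threshold, locked):
    """Pointwise loop evaluation of the linear-falloff drag field."""
    nx, ny = x.copy(), y.copy()
    for i in range(len(x)):
        if locked[i]:
            continue
        d = math.sqrt((x[i] - anchor_xy[0]) ** 2
                      + (y[i] - anchor_xy[1]) ** 2)
        if d < threshold:
            f = (threshold - d) / threshold
            nx[i] += dx * f
            ny[i] += dy * f
    return nx, ny


def largest_remainder_reference(sizes, target):
    """Independent largest-remainder rounding (sort-based)."""
    total = sum(sizes)
    exact = [s * target / total for s in sizes]
    floors = [math.floor(e) for e in exact]
    rem = target - sum(floors)
    order = sorted(range(len(sizes)),
                   key=lambda k: (-(exact[k] - floors[k]), k))
    for k in order[:rem]:
        floors[k] += 1
    return floors
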