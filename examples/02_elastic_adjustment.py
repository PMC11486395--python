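"""Elastic fine adjustment: threshold-bounded drag with linear falloff.

After the linear phase is closed, one activated point is dragged; its
unlocked neighbours follow with a displacement that decays linearly to
zero at the influence threshold.
"""
import numpy as np

import spatalign as sa

points, _ = sa.make_section(sa.FixtureSpec(seed=2))
session = sa.Session(points, sa.ScaleSpec(1.0, 1.0, 1.0))
session.begin_elastic()            # linear alignment is declared done

anchor = points.ids[0]
before = session.display.x.copy(), session.display.y.copy()
session.cycle_state(anchor)        # one click: point becomes draggable
event = session.drag(anchor, dx=20.0, dy=-15.0, threshold=100.0)

moved = np.hypot(session.display.x - before[0], session.display.y - before[1])
dist = np.hypot(before[0] - event.anchor_xy[0],
                before[1] - event.anchor_xy[1])
print(f"anchor displacement: {moved[0]:.1f} um (= |(20, -15)|)")
print(f"points inside threshold (D < {event.threshold:.0f}): "
      f"{(dist < event.threshold).sum()} of {points.n}")
print(f"max displacement of a non-anchor point: {moved[1:].max():.1f} um")
print(f"points beyond threshold moved: {(moved[dist >= 100.0] != 0).sum()}")
# Displacement is dx*(T-D)/T per axis: full at the anchor (D=0),
# linearly smaller with distance D, exactly zero from D >= T outward.
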