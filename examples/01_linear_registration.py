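"""Scripted linear registration of a synthetic section to its image.

Builds a seeded synthetic tissue section, loads it into a registration
session at a common display scale, applies a flip, a rotation and a
translation, and exports the registration bundle.
"""
import tempfile
from pathlib import Path

import spatalign as sa

points, image = sa.make_section(sa.FixtureSpec(seed=1))
spec = sa.ScaleSpec(data_scale=1.0, image_scale=1.0, display_scale=1.0)
session = sa.Session(points, spec, image=image)

session.flip("v")          # mirror about the vertical plane
session.rotate(30.0)       # degrees, counterclockwise
session.translate(25.0, -10.0)

out = Path(tempfile.mkdtemp()) / "bundle"
written = sa.write_registration_bundle(session, out)

state = session.state
print(f"widget angle after flip+rotate: {state.theta_deg:.1f} deg")
print(f"cumulative translation: ({state.tx:.1f}, {state.ty:.1f})")
print(f"flips (h, v): ({state.flips_h}, {state.flips_v})")
print(f"bundle files: {sorted(p.name for p in written.values())}")
# The widget angle is +30 (the flip negated the pre-flip angle of 0,
# then the rotation added 30).  The bundle alone — record, log, drag
# record — can re-register the raw coordinates with no session state.
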