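"""Display downsampling with full-data replay.

Only a stratified subsample is displayed (and manipulated) during an
interactive session, but export replays every recorded manipulation
over all original observations.
"""
import numpy as np

import spatalign as sa

rng = np.random.default_rng(0)
n = 20_000
points = sa.PointSet(ids=np.arange(n),
                     x=rng.uniform(0, 2000, n), y=rng.uniform(0, 2000, n),
                     annotation=rng.choice(["neuron", "glia", "vascular"],
                                           n, p=[0.6, 0.3, 0.1]))

session = sa.Session(points, sa.ScaleSpec(1.0, 1.0, 1.0))
idx = session.downsample_display(2000, seed=7)
for label in ("neuron", "glia", "vascular"):
    frac_full = (points.annotation == label).mean()
    frac_disp = (points.annotation[idx] == label).mean()
    print(f"{label:>9}: full {100 * frac_full:5.2f}%  "
          f"displayed {100 * frac_disp:5.2f}%")

session.rotate(12.0)
session.translate(40.0, -20.0)
full = session.replay_full()
print(f"displayed points: {len(idx)}, exported points: {full.n}")
# Cluster proportions are preserved by largest-remainder quotas
# D_i = round(F_i x N), and the exported table carries all 20,000
# observations through the same rotation and translation.
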