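"""Analyzing a tracked center-of-mass trajectory table.

Experimental cargo tracking produces delimited tables of time and position.
This script builds a synthetic table with three planted convergent episodes,
writes and re-reads it through the trajectory file format, and runs the mode
segmentation — the same pipeline real tracking exports would go through.
"""

import tempfile
from pathlib import Path

from antcargo.io import make_fixture_trajectory, read_trajectory, write_trajectory
from antcargo.modes import THRESHOLDS_1D, dwell_statistics, segment_modes

windows = [(20.0, 30.0), (50.0, 58.0), (80.0, 95.0)]
traj = make_fixture_trajectory(windows, T=120.0, seed=0)

path = Path(tempfile.gettempdir()) / "tracked_cargo.csv"
write_trajectory(path, traj)
back = read_trajectory(path, dim=1)
print(f"round-tripped {len(back)} samples through {path}")

segments = segment_modes(back, THRESHOLDS_1D)
conv = [s for s in segments if s.label == "convergent"]
print(f"planted {len(windows)} convergent episodes, recovered {len(conv)}:")
for seg in conv:
    print(f"  {seg.t_start:6.1f} .. {seg.t_end:6.1f} s ({seg.duration:.1f} s)")
dw = dwell_statistics(segments)
print(f"total convergent dwell {dw['convergent']['durations'].sum():.1f} s "
      f"of {back.t[-1]:.0f} s analyzed")
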