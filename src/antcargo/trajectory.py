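"""Trajectory container shared by the deterministic and stochastic simulators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Time series of cargo state snapshots.

    ``t`` is strictly increasing (event times or a uniform grid).  1D runs
    populate ``x`` and ``v``; 2D runs additionally populate ``y`` and ``vy``
    (``x``/``v`` then hold the along-wall component).  Count columns are
    present for stochastic runs.  ``meta`` records provenance: scheme, seed,
    parameters, sampling.
    """

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    y: np.ndarray | None = None
    vy: np.ndarray | None = None
    n_pullers: np.ndarray | None = None
    n_lifters: np.ndarray | None = None
    n_informed: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        for name in ("y", "vy", "n_pullers", "n_lifters", "n_informed"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))
        if self.t.ndim != 1 or len(self.t) != len(self.x) or len(self.t) != len(self.v):
            raise ValueError("t, x, v must be 1D arrays of equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def is_2d(self) -> bool:
        return self.y is not None

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t, "x": self.x}
        if self.is_2d:
            cols["y"] = self.y
        cols["v"] = self.v
        if self.vy is not None:
            cols["vy"] = self.vy
        for name in ("n_pullers", "n_lifters", "n_informed"):
            val = getattr(self, name)
            if val is not None:
                cols[name] = val
        return pd.DataFrame(cols)

    def resample(self, dt: float = 0.1) -> "Trajectory":
        """Linear-interpolation resampling onto a uniform grid of spacing dt.

        Event-time output of the stochastic simulators is piecewise-linear in
        position (constant velocity between events), so linear interpolation
        is exact for ``x``; interpolated velocities are the analysis-grade
        estimate used by the mode-segmentation thresholds.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.t) < 2:
            return self
        grid = np.arange(self.t[0], self.t[-1] + 0.5 * dt, dt)
        grid = grid[grid <= self.t[-1]]

        def interp(arr):
            return None if arr is None else np.interp(grid, self.t, arr)

        return Trajectory(
            t=grid,
            x=np.interp(grid, self.t, self.x),
            v=np.interp(grid, self.t, self.v),
            y=interp(self.y),
            vy=interp(self.vy),
            n_pullers=interp(self.n_pullers),
            n_lifters=interp(self.n_lifters),
            n_informed=interp(self.n_informed),
            meta={**self.meta, "resampled_dt": dt},
        )
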