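"""Trajectory file I/O, configuration documents, and synthetic fixtures.

Trajectories are stored as comma-delimited text with a commented JSON header
carrying provenance (dimensionality, scheme, seed, sampling step, parameter
digest) — the same shape as experimental tracking tables (time, position,
derived velocity), so real tracked center-of-mass data can be analyzed
through the same readers.

The fixture generator plants known convergent episodes inside an oscillatory
carrier signal, giving the mode-segmentation analysis a ground truth to be
tested against without any external data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .params import InvalidParameterError, PhysicalParams
from .trajectory import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "make_fixture_trajectory",
    "load_config",
    "CONFIG_KEYS",
]

_HEADER_PREFIX = "# antcargo-trajectory "

CONFIG_KEYS = frozenset(
    {
        "f0", "F_ind", "gamma", "n_tot", "G", "n_max", "k_c", "k_on", "k_off",
        "k_forget", "k_orient", "r", "opening_width", "eps", "scheme", "seed", "T",
    }
)


class TrajectoryParseError(ValueError):
    pass


def _meta_jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            out[k] = dataclasses.asdict(v)
        elif isinstance(v, (str, int, float, bool, type(None), list, dict)):
            out[k] = v
        else:
            out[k] = repr(v)
    return out


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write a trajectory as commented-header CSV (full double precision)."""
    path = Path(path)
    frame = traj.to_frame()
    header = {
        "dim": 2 if traj.is_2d else 1,
        "columns": list(frame.columns),
        "meta": _meta_jsonable(traj.meta),
    }
    with open(path, "w") as fh:
        fh.write(_HEADER_PREFIX + json.dumps(header) + "\n")
        fh.write(",".join(frame.columns) + "\n")
        np.savetxt(fh, frame.to_numpy(), delimiter=",", fmt="%.12g")


def read_trajectory(path: str | Path, dim: int | None = None) -> Trajectory:
    """Read a trajectory file; validates the header, monotone time, and
    (optionally) the expected dimensionality."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_HEADER_PREFIX):
            raise TrajectoryParseError(f"{path}:1: missing trajectory header")
        try:
            header = json.loads(first[len(_HEADER_PREFIX):])
        except json.JSONDecodeError as exc:
            raise TrajectoryParseError(f"{path}:1: malformed header: {exc}") from exc
        cols = fh.readline().strip().split(",")
        if cols != header.get("columns"):
            raise TrajectoryParseError(f"{path}:2: column row disagrees with header")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if dim is not None and header["dim"] != dim:
        raise TrajectoryParseError(
            f"{path}: file is {header['dim']}D but a {dim}D trajectory was requested"
        )
    named = {c: data[:, i] for i, c in enumerate(cols)}
    t = named["t"]
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise TrajectoryParseError(
            f"{path}: non-increasing time at data line {bad[0] + 2}"
        )
    return Trajectory(
        t=t,
        x=named["x"],
        v=named["v"],
        y=named.get("y"),
        vy=named.get("vy"),
        n_pullers=named.get("n_pullers"),
        n_lifters=named.get("n_lifters"),
        n_informed=named.get("n_informed"),
        meta=header.get("meta", {}),
    )


def make_fixture_trajectory(
    convergent_windows: list[tuple[float, float]],
    T: float = 100.0,
    dt: float = 0.1,
    seed: int = 0,
    noise: float = 0.01,
    osc_amplitude: float = 2.0,
    osc_period: float = 20.0,
) -> Trajectory:
    """Synthetic 1D trajectory with planted convergent episodes.

    Outside the requested windows the cargo performs a sinusoidal oscillation
    exceeding the 1D detection thresholds; inside them it sits at the origin
    with small-amplitude noise below the thresholds.  Windows must be
    non-overlapping and ordered.
    """
    last_end = -np.inf
    for a, b in convergent_windows:
        if b <= a:
            raise ValueError(f"window ({a}, {b}) has non-positive length")
        if a < last_end:
            raise ValueError("convergent windows overlap or are unordered")
        last_end = b
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, T + 0.5 * dt, dt)
    omega = 2.0 * np.pi / osc_period
    x = osc_amplitude * np.sin(omega * t)
    v = osc_amplitude * omega * np.cos(omega * t)
    for a, b in convergent_windows:
        inside = (t >= a) & (t <= b)
        x[inside] = noise * rng.standard_normal(inside.sum())
        v[inside] = noise * rng.standard_normal(inside.sum())
    return Trajectory(
        t=t, x=x, v=v,
        meta={"kind": "fixture", "seed": seed, "windows": list(map(list, convergent_windows)),
              "resampled_dt": dt},
    )


def load_config(path: str | Path) -> tuple[PhysicalParams, dict]:
    """Load a flat key-value parameter document (YAML mapping).

    Keys mirror the standard parameter-table names; unknown keys are an
    error.  ``eps``, ``scheme``, ``seed`` and ``T`` are run settings returned
    alongside in the second element.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise InvalidParameterError(f"{path}: config must be a flat mapping")
    unknown = set(doc) - CONFIG_KEYS
    if unknown:
        raise InvalidParameterError(f"{path}: unknown config keys {sorted(unknown)}")
    run_keys = {k: doc.pop(k) for k in ("eps", "scheme", "seed", "T") if k in doc}
    return PhysicalParams(**doc), run_keys
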