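"""State-snapshot and V_m-movie persistence.

Snapshots are columnar CSV keyed by the model's state layout (one row per
voxel for tissue states); movies are stacked raw float32 frames with a
JSON sidecar header carrying the grid geometry and sampling period.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cell_models import IonicModel
from .monodomain_solver import VmMovie

__all__ = ["save_states", "load_states", "save_movie", "load_movie"]


def save_states(path, model: IonicModel, states: np.ndarray) -> None:
    """Write a single-cell state vector or (n_voxel, n_state) tissue state
    array as CSV with a state_layout header."""
    states = np.atleast_2d(np.asarray(states, dtype=np.float64))
    if states.shape[1] != model.n_state:
        raise ValueError(
            f"state width {states.shape[1]} != {model.n_state} "
            f"for {model.key}"
        )
    header = ",".join(
        f"{n} [{u}]" for n, u in zip(model.state_names, model.state_units)
    )
    np.savetxt(path, states, delimiter=",", header=header, comments="# ")


def load_states(path, model: IonicModel) -> np.ndarray:
    """Read a snapshot written by :func:`save_states`; validates the state
    layout against the model."""
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip()
    names = [c.split(" [")[0].strip() for c in header.split(",")]
    if tuple(names) != model.state_names:
        raise ValueError(
            f"state layout in {path} does not match {model.key}: {names}"
        )
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return arr[0] if arr.shape[0] == 1 else arr


def save_movie(path, movie: VmMovie) -> None:
    """Write movie frames as raw little-endian float32 with a JSON sidecar
    (``<path>.json``) describing dims, dx and the frame interval."""
    path = Path(path)
    data = np.ascontiguousarray(movie.data, dtype="<f4")
    data.tofile(path)
    sidecar = {
        "shape": list(data.shape),
        "dtype": "<f4",
        "dt_ms": movie.dt,
        "dx_mm": movie.dx,
        "t0_ms": movie.t0,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_movie(path) -> VmMovie:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
    return VmMovie(
        data=data, dt=meta["dt_ms"], dx=meta["dx_mm"], t0=meta["t0_ms"]
    )
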