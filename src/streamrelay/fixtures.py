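"""Synthetic track generator for testing the metrics pipeline.

The generator produces non-interacting walkers obeying exactly the angle
dynamics of :mod:`streamrelay.agents` under a fixed unit gradient along
``+y``: constant unit speed, tangentially projected orientation relaxation
with time constant ``T`` and noise ``sigma``, no field coupling, no
boundaries.  It emulates the trajectories of mutant cells that cannot relay
the signal (the ``beta = 0`` limit) in an ideal linear gradient - which is
precisely the population the analytic angle law describes - and is the
ground-truth fixture for the autocorrelation fit and variance metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import agents

__all__ = ["make_fixture_ou_tracks"]


def make_fixture_ou_tracks(T: float, sigma: float, n_cells: int,
                           n_frames: int, dt: float, seed,
                           burn_in_frames: int | None = None) -> pd.DataFrame:
    """Tracks of independent unit-speed walkers in a uniform gradient.

    One integration step per recorded frame (frame interval ``dt``).  Cells
    start at ``y = 0`` spaced unit distance apart in ``x``, oriented along
    ``+y``; ``burn_in_frames`` unrecorded steps (default ``ceil(5 T / dt)``)
    bring the orientation process to stationarity first, so with
    ``sigma = 0`` tracks are perfectly straight and otherwise the recorded
    angles sample the stationary law.  Deterministic for a fixed seed.
    """
    if min(T, dt) <= 0 or n_cells < 1 or n_frames < 1 or sigma < 0:
        raise ValueError("T, dt must be > 0; n_cells, n_frames >= 1; "
                         "sigma >= 0")
    rng = np.random.default_rng(seed)
    if burn_in_frames is None:
        burn_in_frames = int(np.ceil(5.0 * T / dt)) if sigma > 0 else 0
    ghat = np.tile([0.0, 1.0], (n_cells, 1))
    ori = ghat.copy()
    pos = np.column_stack([np.arange(n_cells, dtype=float),
                           np.zeros(n_cells)])
    for _ in range(burn_in_frames):
        ori = agents.step_orientation(ori, ghat, T, sigma, dt, rng)
    ids = np.arange(n_cells, dtype=np.int64)
    rec = {"cell_id": [], "frame": [], "t": [], "x": [], "y": [],
           "theta": []}
    for frame in range(n_frames):
        rec["cell_id"].append(ids)
        rec["frame"].append(np.full(n_cells, frame, dtype=np.int64))
        rec["t"].append(np.full(n_cells, frame * dt))
        rec["x"].append(pos[:, 0].copy())
        rec["y"].append(pos[:, 1].copy())
        rec["theta"].append(np.arctan2(ori[:, 0], ori[:, 1]))
        ori = agents.step_orientation(ori, ghat, T, sigma, dt, rng)
        pos = agents.step_position(pos, ori, dt)
    df = pd.DataFrame({k: np.concatenate(v) for k, v in rec.items()})
    return df.sort_values(["cell_id", "frame"],
                          kind="stable").reset_index(drop=True)
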