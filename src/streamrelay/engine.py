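"""Simulation loop and phase-diagram parameter sweeps.

One run couples the two model components with a single shared time step:
the chemoattractant field receives the cells' secretion and is advanced by
one explicit diffusion step, then every cell reads the local gradient
direction, updates its orientation (noise + soft repulsion included) and
takes a unit-speed step, and finally the boundary rules and the Poisson
injection at the entry wall are applied.  Operator order within a step is
field first, then agents; the difference from any other ordering is O(dt).

The field starts from the pre-established linear gradient ``c = y`` and the
chamber starts empty; the population builds up from injection.  All
randomness flows from one ``numpy`` Generator per run, so a run is
bit-reproducible given its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import agents, metrics
from .degradation import make_profile
from .field import ScalarField, deposit_sources, ftcs_step, gradient_at
from .params import DimensionlessParams, check_stability

__all__ = ["SimulationResult", "PhaseDiagram", "run", "sweep",
           "aggregate_runs"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class SimulationResult:
    """Everything one run produces.

    ``tracks`` is the long-format trajectory table (``cell_id, frame, t, x,
    y, theta``; ``theta`` the orientation angle from ``+y``), sorted by
    ``(cell_id, frame)`` with contiguous frames per cell.  ``snapshots`` are
    ``(t, values)`` pairs of the field grid.  ``events`` records per-step
    injections and removals (only steps with activity).  ``summary`` is the
    run's :class:`~streamrelay.metrics.RegimeSummary` (``None`` when no
    tracks were recorded).
    """

    tracks: pd.DataFrame
    snapshots: list[tuple[float, np.ndarray]]
    params: DimensionlessParams
    seed: int | None
    summary: metrics.RegimeSummary | None
    events: pd.DataFrame
    n_injected: int
    n_removed: int


def run(dp: DimensionlessParams, seed,
        thresholds: metrics.RegimeThresholds | None = None,
        keep_tracks: bool = True) -> SimulationResult:
    """Simulate one run of the model.

    ``seed`` is an integer or ``numpy.random.SeedSequence``.  Raises on a
    stability violation before stepping and aborts with a diagnostic if the
    field or any position turns non-finite.  ``keep_tracks=False`` drops the
    track table after summarizing (used by large sweeps).
    """
    if not check_stability(dp):
        raise ValueError(
            f"unstable numerics: dt = {dp.dt} violates h^2/(4 D) = "
            f"{dp.h**2 / (4 * dp.D) if dp.D > 0 else np.inf} "
            f"or dt*kmax = {dp.dt * dp.kmax} > 1")
    rng = np.random.default_rng(seed)
    seed_echo = seed if isinstance(seed, (int, np.integer)) else None

    fld = ScalarField.linear(dp.W, dp.h)
    kprof = make_profile(dp.deg_kind, dp.kmax, fld.y_nodes)
    n_steps = int(round(dp.t_end / dp.dt))
    snap_steps = set()
    if dp.n_snapshots > 0:
        snap_steps = set(np.unique(np.linspace(
            1, n_steps, min(dp.n_snapshots, n_steps)).round().astype(int)))
    log.info("run: %d steps, dt=%g, grid %dx%d, beta=%g kmax=%g (%s), "
             "stability ok", n_steps, dp.dt, fld.nx, fld.ny, dp.beta,
             dp.kmax, dp.deg_kind)

    pos = np.empty((0, 2))
    ori = np.empty((0, 2))
    ids = np.empty(0, dtype=np.int64)
    next_id = 0
    n_injected = n_removed = 0
    rec: dict[str, list[np.ndarray]] = {k: [] for k in
                                        ("cell_id", "frame", "t", "x", "y",
                                         "theta")}
    events: list[tuple[int, int, int]] = []
    snapshots: list[tuple[float, np.ndarray]] = []

    for step in range(n_steps):
        if len(pos):
            deposit_sources(fld, pos, dp.beta, dp.dt)
        ftcs_step(fld, kprof, dp.D, dp.dt)
        if len(pos):
            g = gradient_at(fld, pos)
            drive = agents.unit_gradient(g)
            if dp.f0 > 0:
                drive = drive + agents.repulsion_all(pos, dp.f0, dp.R,
                                                     dp.W, rng)
            ori = agents.step_orientation(ori, drive, dp.T, dp.sigma,
                                          dp.dt, rng)
            pos = agents.step_position(pos, ori, dp.dt)
            pos, ori, keep = agents.apply_boundaries(pos, ori, dp.W)
            removed = int((~keep).sum())
            if removed:
                n_removed += removed
                pos, ori, ids = pos[keep], ori[keep], ids[keep]
        else:
            removed = 0
        new_pos, new_ori = agents.inject_cells(dp.J, dp.W, dp.dt, rng,
                                               dp.init_angle_halfwidth)
        if len(new_pos):
            pos = np.vstack([pos, new_pos])
            ori = np.vstack([ori, new_ori])
            ids = np.concatenate([ids, next_id
                                  + np.arange(len(new_pos), dtype=np.int64)])
            next_id += len(new_pos)
            n_injected += len(new_pos)
        if removed or len(new_pos):
            events.append((step, len(new_pos), removed))

        done = step + 1
        if done % dp.record_stride == 0 and len(pos):
            rec["cell_id"].append(ids.copy())
            frame = done // dp.record_stride
            rec["frame"].append(np.full(len(ids), frame, dtype=np.int64))
            rec["t"].append(np.full(len(ids), done * dp.dt))
            rec["x"].append(pos[:, 0].copy())
            rec["y"].append(pos[:, 1].copy())
            rec["theta"].append(np.arctan2(ori[:, 0], ori[:, 1]))
        if done in snap_steps:
            snapshots.append((done * dp.dt, fld.values.copy()))
        if done % 1000 == 0:
            if not np.isfinite(fld.values).all() or \
                    (len(pos) and not np.isfinite(pos).all()):
                raise RuntimeError(
                    f"non-finite field or position at step {done} "
                    f"(t = {done * dp.dt:g}); aborting")
            log.debug("step %d/%d: %d cells, field max %.3g",
                      done, n_steps, len(pos), fld.values.max())

    tracks = pd.DataFrame({k: np.concatenate(v) if v else np.empty(0)
                           for k, v in rec.items()})
    summary = None
    if len(tracks):
        tracks = tracks.sort_values(["cell_id", "frame"],
                                    kind="stable").reset_index(drop=True)
        try:
            summary = metrics.summarize(tracks, thresholds)
        except ValueError as e:
            log.warning("run too short to summarize: %s", e)
    ev = pd.DataFrame(events, columns=["step", "injected", "removed"])
    log.info("run done: %d injected, %d removed, %d active; label=%s",
             n_injected, n_removed, len(pos),
             summary.label if summary else "n/a")
    return SimulationResult(
        tracks=tracks if keep_tracks else tracks.iloc[0:0],
        snapshots=snapshots, params=dp, seed=seed_echo, summary=summary,
        events=ev, n_injected=n_injected, n_removed=n_removed)


@dataclasses.dataclass
class PhaseDiagram:
    """Sweep of the secretion/degradation plane.

    ``runs`` holds one row per realization (``beta, kdeg, rep, u_bar,
    rho_max, label``); ``table`` aggregates over the ``n_reps`` independent
    seeds per grid point (mean, standard error of the mean with
    ``sd/sqrt(n_reps)``, and the label of the mean point).
    """

    beta_values: np.ndarray
    kdeg_values: np.ndarray
    n_reps: int
    runs: pd.DataFrame
    table: pd.DataFrame


def aggregate_runs(runs: pd.DataFrame,
                   thresholds: metrics.RegimeThresholds | None = None,
                   ) -> pd.DataFrame:
    """Average per-realization metrics over reps at each grid point."""
    rows = []
    for (b, k), grp in runs.groupby(["beta", "kdeg"], sort=True):
        u = grp["u_bar"].to_numpy(dtype=float)
        r = grp["rho_max"].to_numpy(dtype=float)
        n = len(grp)
        sem = float(u.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append((b, k, float(u.mean()), sem, float(r.mean()), n,
                     metrics.classify_regime(float(u.mean()),
                                             float(r.mean()), thresholds)))
    return pd.DataFrame(rows, columns=["beta", "kdeg", "u_mean", "u_sem",
                                       "rho_max_mean", "n_reps", "label"])


def sweep(beta_values, kdeg_values, n_reps: int,
          base: DimensionlessParams, seed,
          thresholds: metrics.RegimeThresholds | None = None) -> PhaseDiagram:
    """Run the (secretion x degradation) grid with independent seeds.

    The master ``seed`` spawns one child ``SeedSequence`` per realization in
    a fixed order (beta outer, kdeg inner, then rep), so any sub-grid of a
    sweep is reproducible.  A failing run is re-raised tagged with its grid
    point.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    beta_values = np.atleast_1d(np.asarray(beta_values, dtype=float))
    kdeg_values = np.atleast_1d(np.asarray(kdeg_values, dtype=float))
    ss = np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    children = iter(ss.spawn(len(beta_values) * len(kdeg_values) * n_reps))
    rows = []
    for b in beta_values:
        for k in kdeg_values:
            for rep in range(n_reps):
                child = next(children)
                dp = dataclasses.replace(base, beta=float(b), kmax=float(k))
                try:
                    res = run(dp, child, thresholds, keep_tracks=False)
                except Exception as e:
                    raise RuntimeError(
                        f"sweep run failed at beta={b:g}, kdeg={k:g}, "
                        f"rep={rep}") from e
                if res.summary is None:
                    raise RuntimeError(
                        f"no tracks recorded at beta={b:g}, kdeg={k:g}, "
                        f"rep={rep}; lengthen the run or lower record_stride")
                rows.append((float(b), float(k), rep, res.summary.u_final,
                             res.summary.rho_max, res.summary.label))
    runs = pd.DataFrame(rows, columns=["beta", "kdeg", "rep", "u_bar",
                                       "rho_max", "label"])
    return PhaseDiagram(beta_values=beta_values, kdeg_values=kdeg_values,
                        n_reps=n_reps, runs=runs,
                        table=aggregate_runs(runs, thresholds))
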