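"""Trajectory statistics and regime classification.

Input is a long-format track table (``cell_id, frame, t, x, y``, uniform
frame interval) produced either by the simulator or by an external tracking
pipeline.  From it this module computes

* motion angles: the angle ``theta`` of a displacement vector with respect
  to the imposed gradient direction ``+y``;
* the time autocorrelation of the motion direction with an exponential fit
  ``A exp(-tau/T) + B``, whose time constant estimates the orientation
  response time;
* the variance of ``theta`` versus distance from the entry wall;
* the normalized mean progression ``u`` (average velocity component along
  the gradient in units of the cell speed) and the normalized cell density
  profile ``rho(y)`` (chamber average 1);
* a classification of a run into the three observed regimes, uncorrelated
  motion / streaming / clumping, from ``(u_final, rho_max)``.

Two autocorrelation variants are available.  The default,
``quantity="vector"``, correlates the motion directions themselves,
``C(tau) = <u_hat(t) . u_hat(t+tau)> = <cos(theta(t) - theta(t+tau))>``;
its exponential decay time equals the orientation relaxation time.  The
variant ``quantity="cos_theta"`` correlates the gradient-direction cosines,
``C(tau) = <cos theta(t) cos theta(t+tau)>``; being even in the angles it
relaxes roughly twice as fast and is provided for comparison only.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import typing

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RegimeThresholds", "RegimeSummary", "ExpFit",
    "motion_angles", "angle_autocorrelation", "fit_exponential",
    "angle_variance_vs_y", "mean_progression", "MeanProgression",
    "density_profile", "classify_regime", "summarize",
]

log = logging.getLogger(__name__)

TRACK_COLUMNS = ("cell_id", "frame", "t", "x", "y")


def _check_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing column(s) {missing}")
    return tracks.sort_values(["cell_id", "frame"], kind="stable")


def _frame_interval(tracks: pd.DataFrame) -> float:
    """Time per frame, from consecutive rows of the same cell."""
    g = tracks.groupby("cell_id")
    dt = g["t"].diff() / g["frame"].diff()
    dt = dt.dropna()
    if dt.empty:
        raise ValueError("need at least two frames for one cell")
    return float(dt.median())


def motion_angles(tracks: pd.DataFrame, lag_frames: int = 1,
                  eps_move: float | None = None,
                  width: float | None = None) -> pd.DataFrame:
    """Displacement angles relative to the gradient direction ``+y``.

    For every track row with a row ``lag_frames`` later, the displacement
    ``(dx, dy)`` gives ``theta = atan2(dx, dy)`` in ``(-pi, pi]``, tagged
    with the time and position of the displacement's start.  When ``width``
    is given, ``dx`` is taken minimum-image in the periodic direction.
    Displacements shorter than ``eps_move`` (default: 10% of the distance a
    model cell covers in the lag) are dropped; the count is reported in
    ``result.attrs["n_dropped"]`` (the slow-cell filter applied to
    experimental tracks).  Tracks shorter than the lag contribute nothing.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    tr = _check_tracks(tracks)
    if tr.empty:
        out = tr.copy()
        out["theta"] = np.empty(0)
        out.attrs["n_dropped"] = 0
        return out
    g = tr.groupby("cell_id")
    x2 = g["x"].shift(-lag_frames)
    y2 = g["y"].shift(-lag_frames)
    f2 = g["frame"].shift(-lag_frames)
    ok = (f2 - tr["frame"]) == lag_frames  # contiguity across the lag
    dx = (x2 - tr["x"])[ok]
    dy = (y2 - tr["y"])[ok]
    if width is not None:
        dx = dx - width * np.round(dx / width)
    if eps_move is None:
        eps_move = 0.1 * lag_frames * _frame_interval(tr)
    norm = np.hypot(dx, dy)
    moved = norm >= eps_move
    out = tr.loc[dx.index[moved],
                 ["cell_id", "frame", "t", "x", "y"]].copy()
    out["theta"] = np.arctan2(dx[moved], dy[moved])
    out.attrs["n_dropped"] = int((~moved).sum())
    if out.attrs["n_dropped"]:
        log.info("motion_angles: dropped %d displacement(s) below "
                 "eps_move = %g", out.attrs["n_dropped"], eps_move)
    return out.reset_index(drop=True)


def _angle_matrix(angles: pd.DataFrame,
                  region: tuple[float, float] | None) -> np.ndarray:
    """Per-cell angle series on the common frame grid, NaN where absent."""
    a = angles
    if region is not None:
        lo, hi = region
        a = a[(a["y"] >= lo) & (a["y"] <= hi)]
    if a.empty:
        raise ValueError("no angle samples in the requested region")
    mat = a.pivot_table(index="cell_id", columns="frame", values="theta",
                        aggfunc="first")
    f = mat.columns.to_numpy()
    full = np.full((mat.shape[0], int(f.max() - f.min()) + 1), np.nan)
    full[:, (f - f.min()).astype(int)] = mat.to_numpy()
    return full


def angle_autocorrelation(angles: pd.DataFrame,
                          region: tuple[float, float] | None = (0.5, 1.0),
                          max_lag_frames: int | None = None,
                          quantity: str = "vector") -> pd.DataFrame:
    """Time autocorrelation ``C(tau)`` of the motion direction.

    ``angles`` is the output of :func:`motion_angles`.  Averaging runs over
    cells and start times, restricted to samples with ``y`` in ``region``
    (default: the exit-side half of the chamber, which removes the
    orientation bias imprinted at cell entry; pass ``None`` for no
    restriction).  ``quantity`` selects the correlated observable (see
    module docstring).  Returns a table with columns ``lag`` (frames),
    ``tau`` (time), ``C`` and ``n_pairs``.
    """
    if quantity not in ("vector", "cos_theta"):
        raise ValueError("quantity must be 'vector' or 'cos_theta'")
    dt_frame = _frame_interval(angles)
    mat = _angle_matrix(angles, region)
    n_frames = mat.shape[1]
    if max_lag_frames is None:
        max_lag_frames = max(1, (n_frames - 1) // 2)
    max_lag_frames = min(max_lag_frames, n_frames - 1)
    rows = []
    for lag in range(0, max_lag_frames + 1):
        a = mat[:, : n_frames - lag if lag else n_frames]
        b = mat[:, lag:]
        if quantity == "vector":
            prod = np.cos(a - b)
        else:
            prod = np.cos(a) * np.cos(b)
        n = int(np.isfinite(prod).sum())
        c = float(np.nanmean(prod)) if n else np.nan
        rows.append((lag, lag * dt_frame, c, n))
    out = pd.DataFrame(rows, columns=["lag", "tau", "C", "n_pairs"])
    if out["n_pairs"].iloc[1:].eq(0).all() and len(out) > 1:
        raise ValueError("no valid sample pairs at any positive lag")
    return out


class ExpFit(typing.NamedTuple):
    """Result of the exponential autocorrelation fit."""

    A: float
    T: float
    B: float


def fit_exponential(ctable, C=None, mode: str = "plateau") -> ExpFit:
    """Least-squares fit of ``C(tau) = A exp(-tau/T) + B``.

    Accepts the table from :func:`angle_autocorrelation` or two arrays
    ``(tau, C)``.  ``mode="plateau"`` (default) fits the offset ``B`` as a
    free parameter - drift toward the gradient keeps the correlation from
    decaying to zero; ``mode="paper"`` pins ``B = 0``, the bare form
    ``A exp(-tau/T)`` conventionally reported for experimental tracks.  A
    non-decaying input is reported with the sentinel ``T = inf``.
    """
    if mode not in ("plateau", "paper"):
        raise ValueError("mode must be 'plateau' or 'paper'")
    if C is None:
        tau = np.asarray(ctable["tau"], dtype=float)
        Cv = np.asarray(ctable["C"], dtype=float)
    else:
        tau = np.asarray(ctable, dtype=float)
        Cv = np.asarray(C, dtype=float)
    keep = np.isfinite(Cv)
    tau, Cv = tau[keep], Cv[keep]
    if len(Cv) < 4:
        raise ValueError("need at least 4 lag points to fit")
    if np.ptp(Cv) < 1e-12:
        log.warning("autocorrelation is constant; reporting T = inf")
        return ExpFit(0.0, math.inf, float(Cv.mean()))
    b0 = float(Cv[-1]) if mode == "plateau" else 0.0
    a0 = float(Cv[0] - b0)
    t0 = float(tau[-1] - tau[0]) / 3.0 or 1.0
    span = float(tau[-1] - tau[0])
    try:
        if mode == "plateau":
            popt, _ = curve_fit(
                lambda t, A, T, B: A * np.exp(-t / T) + B,
                tau, Cv, p0=[a0, t0, b0],
                bounds=([-np.inf, 1e-12 * max(span, 1.0), -np.inf],
                        [np.inf, np.inf, np.inf]), maxfev=20000)
            A, T, B = (float(v) for v in popt)
        else:
            popt, _ = curve_fit(
                lambda t, A, T: A * np.exp(-t / T),
                tau, Cv, p0=[a0 if a0 else 1.0, t0],
                bounds=([-np.inf, 1e-12 * max(span, 1.0)],
                        [np.inf, np.inf]), maxfev=20000)
            A, T = (float(v) for v in popt)
            B = 0.0
    except RuntimeError:
        log.warning("exponential fit did not converge; reporting T = inf")
        return ExpFit(float(Cv[0] - b0), math.inf, b0)
    if T > 1e6 * span:
        log.warning("no decay on the sampled lags; reporting T = inf")
        return ExpFit(A, math.inf, B)
    return ExpFit(A, T, B)


def angle_variance_vs_y(angles: pd.DataFrame, y_bins: int = 10,
                        min_count: int = 10) -> pd.DataFrame:
    """Variance of the motion angle per distance bin from the entry wall.

    Angles are principal values in ``(-pi, pi]``; near-aligned motion keeps
    them far from the wrap point, so the ordinary sample variance is used.
    Bins with fewer than ``min_count`` samples report NaN and are flagged.
    Returns columns ``y_mid``, ``var``, ``n``.
    """
    edges = np.linspace(0.0, 1.0, y_bins + 1)
    idx = np.clip(np.digitize(angles["y"], edges) - 1, 0, y_bins - 1)
    rows = []
    for b in range(y_bins):
        th = angles["theta"].to_numpy()[idx == b]
        n = len(th)
        if n >= max(min_count, 2):
            v = float(np.var(th, ddof=1))
        else:
            v = math.nan
            if n:
                log.info("variance bin %d under-filled (%d < %d)",
                         b, n, min_count)
        rows.append(((edges[b] + edges[b + 1]) / 2, v, n))
    return pd.DataFrame(rows, columns=["y_mid", "var", "n"])


@dataclasses.dataclass(frozen=True)
class MeanProgression:
    """Normalized mean progression, resolved in space and time."""

    by_y: pd.DataFrame      # columns y_mid, u, n (final-window average)
    by_time: pd.DataFrame   # columns t_mid, u, n
    u_final: float          # last-quarter chamber average


def _velocity_samples(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-step gradient-direction velocities from consecutive frames."""
    tr = _check_tracks(tracks)
    g = tr.groupby("cell_id")
    dy = g["y"].shift(-1) - tr["y"]
    dt = g["t"].shift(-1) - tr["t"]
    ok = ((g["frame"].shift(-1) - tr["frame"]) == 1) & (dt > 0)
    out = pd.DataFrame({
        "vy": (dy / dt)[ok],
        "t_mid": (tr["t"] + dt / 2)[ok],
        "y_mid": (tr["y"] + dy / 2)[ok],
    })
    return out.reset_index(drop=True)


def mean_progression(tracks: pd.DataFrame, y_bins: int = 10,
                     n_time_windows: int = 4, final_frac: float = 0.25,
                     region: tuple[float, float] = (0.25, 1.0),
                     ) -> MeanProgression:
    """Normalized mean progression ``u = <v_y> / v0`` (model speed 1).

    Velocities are per-frame displacement components along the gradient.
    ``by_time`` and ``u_final`` average over cells in ``region`` (default:
    the chamber with the entry quarter excluded, since cells enter aligned
    with the gradient and would bias the average toward 1 regardless of the
    collective state; pass ``(0, 1)`` for the whole chamber).  ``by_time``
    uses ``n_time_windows`` equal windows; ``by_y`` (which is not region-
    restricted) and ``u_final`` average over the trailing ``final_frac`` of
    the simulated time, the settled regime.  Empty windows or bins yield
    NaN.
    """
    v_all = _velocity_samples(tracks)
    if v_all.empty:
        raise ValueError("no displacement samples in the track table")
    lo, hi = region
    v = v_all[(v_all["y_mid"] >= lo) & (v_all["y_mid"] <= hi)]
    if v.empty:
        raise ValueError(f"no displacement samples in region {region}")
    t0, t1 = float(v_all["t_mid"].min()), float(v_all["t_mid"].max())
    t_edges = np.linspace(t0, t1, n_time_windows + 1)
    ti = np.clip(np.digitize(v["t_mid"], t_edges) - 1, 0, n_time_windows - 1)
    by_time = pd.DataFrame({
        "t_mid": (t_edges[:-1] + t_edges[1:]) / 2,
        "u": [float(v["vy"][ti == w].mean()) if (ti == w).any() else math.nan
              for w in range(n_time_windows)],
        "n": [int((ti == w).sum()) for w in range(n_time_windows)],
    })
    t_cut = t1 - final_frac * (t1 - t0)
    vf_all = v_all[v_all["t_mid"] >= t_cut]
    vf = v[v["t_mid"] >= t_cut]
    y_edges = np.linspace(0.0, 1.0, y_bins + 1)
    yi = np.clip(np.digitize(vf_all["y_mid"], y_edges) - 1, 0, y_bins - 1)
    by_y = pd.DataFrame({
        "y_mid": (y_edges[:-1] + y_edges[1:]) / 2,
        "u": [float(vf_all["vy"][yi == b].mean()) if (yi == b).any()
              else math.nan for b in range(y_bins)],
        "n": [int((yi == b).sum()) for b in range(y_bins)],
    })
    u_final = float(vf["vy"].mean()) if len(vf) else math.nan
    return MeanProgression(by_y=by_y, by_time=by_time, u_final=u_final)


def density_profile(tracks: pd.DataFrame, y_bins: int = 10,
                    final_frac: float | None = None,
                    region: tuple[float, float] = (0.0, 1.0),
                    ) -> tuple[pd.DataFrame, float]:
    """Normalized cell-density profile across the chamber.

    Bin counts are averaged over the sampled frames and divided by the
    chamber-wide mean, so the profile averages to exactly 1.  ``rho_max`` is
    the profile maximum over bins whose centre lies in ``region`` (default
    the whole chamber: aggregates form low in the chamber when degradation
    is fast and just below the exit when it is slow).  ``final_frac``
    restricts the frames to the trailing fraction of the run.  Raises if no
    positions are available.
    """
    tr = _check_tracks(tracks)
    if final_frac is not None and not tr.empty:
        t1, t0 = float(tr["t"].max()), float(tr["t"].min())
        tr = tr[tr["t"] >= t1 - final_frac * (t1 - t0)]
    if tr.empty:
        raise ValueError("no cell positions to bin")
    edges = np.linspace(0.0, 1.0, y_bins + 1)
    yi = np.clip(np.digitize(tr["y"], edges) - 1, 0, y_bins - 1)
    counts = np.bincount(yi, minlength=y_bins).astype(float)
    rho = counts * y_bins / counts.sum()
    mids = (edges[:-1] + edges[1:]) / 2
    profile = pd.DataFrame({"y_mid": mids, "rho": rho})
    lo, hi = region
    sel = (mids >= lo) & (mids <= hi)
    if not sel.any():
        raise ValueError("region contains no density bins")
    return profile, float(rho[sel].max())


@dataclasses.dataclass(frozen=True)
class RegimeThresholds:
    """Decision boundaries in the ``(u_final, rho_max)`` plane.

    Runs with high progression and flat density are uncorrelated motion;
    low progression with a strong density peak is clumping; everything in
    between is streaming.  The defaults are repository choices validated on
    the canned regime presets.
    """

    u_lo: float = 0.2
    u_hi: float = 0.6
    rho_lo: float = 2.0
    rho_hi: float = 4.0


def classify_regime(u_final: float, rho_max: float,
                    thresholds: RegimeThresholds | None = None) -> str:
    """Label a run ``uncorrelated`` / ``streaming`` / ``clumping``."""
    if u_final is None or rho_max is None \
            or not (math.isfinite(u_final) and math.isfinite(rho_max)):
        raise ValueError("u_final and rho_max must be finite")
    th = thresholds or RegimeThresholds()
    if u_final <= th.u_lo and rho_max >= th.rho_hi:
        return "clumping"
    if u_final >= th.u_hi and rho_max <= th.rho_lo:
        return "uncorrelated"
    return "streaming"


@dataclasses.dataclass(frozen=True)
class RegimeSummary:
    """Per-run collective-motion metrics feeding the phase diagram."""

    u_by_y: pd.DataFrame
    u_by_time: pd.DataFrame
    u_final: float
    rho_profile: pd.DataFrame
    rho_max: float
    label: str


def summarize(tracks: pd.DataFrame, thresholds: RegimeThresholds | None = None,
              y_bins: int = 10, final_frac: float = 0.25,
              u_region: tuple[float, float] = (0.25, 1.0)) -> RegimeSummary:
    """Mean progression + density profile + regime label for one run."""
    prog = mean_progression(tracks, y_bins=y_bins, final_frac=final_frac,
                            region=u_region)
    rho, rho_max = density_profile(tracks, y_bins=y_bins,
                                   final_frac=final_frac)
    label = classify_regime(prog.u_final, rho_max, thresholds)
    return RegimeSummary(u_by_y=prog.by_y, u_by_time=prog.by_time,
                         u_final=prog.u_final, rho_profile=rho,
                         rho_max=rho_max, label=label)
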