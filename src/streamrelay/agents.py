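"""Equations of motion for the self-propelled soft-disk cells.

Each cell carries a position ``r`` and a unit orientation vector ``n`` and
moves at constant unit speed, ``dr/dt = n``.  The orientation relaxes with
time constant ``T`` toward the signal vector

    p = g_hat + xi + F,

where ``g_hat`` is the unit vector along the local chemoattractant gradient
(direction only - the response is independent of the signal level), ``xi`` is
white noise of amplitude ``sigma``, and ``F`` is a soft two-body repulsion
that decreases linearly with centre distance and vanishes beyond one cell
diameter.  Because ``n`` must stay on the unit circle, the relaxation acts
through the tangential projector ``(I - n n^T)`` and ``n`` is renormalized
after every step; the equivalent angle dynamics is

    d(theta) = -(1/T) |g + F| sin(delta) dt + (sigma/T) dW,

with ``delta`` the angle between ``n`` and the deterministic drive.  The
discrete noise realization is ``xi = (sigma/sqrt(dt)) eta`` with ``eta`` a
standard-normal 2-vector, which makes the law of the trajectories independent
of ``dt`` (for ``dt`` well below ``T``).

Functions here are vectorized over cells: positions and orientations are
``(N, 2)`` arrays.  The :class:`Cell` dataclass is a per-agent record used
for bookkeeping and tests.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

__all__ = ["Cell", "unit_gradient", "repulsion", "repulsion_all",
           "step_orientation", "step_position", "inject_cells",
           "apply_boundaries"]

log = logging.getLogger(__name__)

_COINCIDENT = 1e-12


@dataclasses.dataclass
class Cell:
    """One agent: id, position, unit orientation, entry time."""

    id: int
    position: np.ndarray
    orientation: np.ndarray
    t_entry: float


def unit_gradient(g: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Normalize gradient vector(s); zero vector when ``|g| <= tol``.

    A vanishing gradient carries no directional cue, so the chemotactic term
    is switched off rather than amplified.
    """
    g = np.asarray(g, dtype=float)
    norm = np.linalg.norm(g, axis=-1, keepdims=True)
    safe = np.where(norm > 0, norm, 1.0)
    return np.where(norm > tol, g / safe, 0.0)


def _min_image_dx(dx: np.ndarray, width: float) -> np.ndarray:
    return dx - width * np.round(dx / width)


def repulsion(position: np.ndarray, neighbor_positions: np.ndarray,
              f0: float, R: float, width: float,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Soft-disk repulsion on one cell from the given neighbours.

    Neighbours with centre distance ``d < 2R`` push the cell along the
    centre-to-centre direction with magnitude ``f0 (1 - d/(2R))`` (linear
    soft contact); distances use the minimum image in the periodic ``x``
    direction.  Exactly coincident centres push along a uniformly random
    direction drawn from ``rng``.
    """
    position = np.asarray(position, dtype=float)
    nbrs = np.atleast_2d(np.asarray(neighbor_positions, dtype=float))
    if nbrs.size == 0 or f0 == 0.0:
        return np.zeros(2)
    delta = position[None, :] - nbrs
    delta[:, 0] = _min_image_dx(delta[:, 0], width)
    d = np.hypot(delta[:, 0], delta[:, 1])
    force = np.zeros(2)
    for k in range(len(nbrs)):
        if d[k] >= 2.0 * R:
            continue
        if d[k] < _COINCIDENT:
            if rng is None:
                raise ValueError("coincident centres need an rng "
                                 "for the direction tie-break")
            phi = rng.uniform(0.0, 2.0 * math.pi)
            force += f0 * np.array([math.cos(phi), math.sin(phi)])
        else:
            force += f0 * (1.0 - d[k] / (2.0 * R)) * delta[k] / d[k]
    return force


def repulsion_all(positions: np.ndarray, f0: float, R: float, width: float,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Pairwise repulsion on every cell (exhaustive ``O(N^2)`` sum).

    Newton's third law holds exactly: the force from ``j`` on ``i`` is the
    negative of the force from ``i`` on ``j``, including the random-direction
    tie-break for coincident pairs (one direction drawn per pair).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(pos)
    if n < 2 or f0 == 0.0:
        return np.zeros((n, 2))
    dx = pos[:, 0, None] - pos[None, :, 0]
    half = 0.5 * width
    dx[dx > half] -= width
    dx[dx < -half] += width
    dy = pos[:, 1, None] - pos[None, :, 1]
    d2 = dx * dx
    d2 += dy * dy
    np.fill_diagonal(d2, np.inf)
    ii, jj = np.nonzero(d2 < (2.0 * R) ** 2)  # row-major: deterministic sums
    d = np.sqrt(d2[ii, jj])
    coincident = np.zeros_like(d2, dtype=bool)
    coincident[ii[d < _COINCIDENT], jj[d < _COINCIDENT]] = True
    close = d >= _COINCIDENT
    ii_c, jj_c, d_c = ii[close], jj[close], d[close]
    w = f0 * (1.0 - d_c / (2.0 * R)) / d_c
    fx = np.bincount(ii_c, weights=w * dx[ii_c, jj_c], minlength=n)
    fy = np.bincount(ii_c, weights=w * dy[ii_c, jj_c], minlength=n)
    if np.any(coincident):
        if rng is None:
            raise ValueError("coincident centres need an rng "
                             "for the direction tie-break")
        ii, jj = np.nonzero(np.triu(coincident, k=1))
        for a, b in zip(ii, jj):  # rare; fixed iteration order for seeding
            phi = rng.uniform(0.0, 2.0 * math.pi)
            ux, uy = math.cos(phi), math.sin(phi)
            fx[a] += f0 * ux
            fy[a] += f0 * uy
            fx[b] -= f0 * ux
            fy[b] -= f0 * uy
    return np.column_stack([fx, fy])


def step_orientation(n: np.ndarray, drive: np.ndarray, T: float,
                     sigma: float, dt: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Euler-Maruyama update of the unit orientation vector(s).

    ``drive`` is the deterministic part of the signal vector (``g_hat + F``).
    The update is

        n <- n + (dt/T) P (drive) + (sqrt(dt) sigma / T) P eta,

    with ``P = I - n n^T`` the tangential projector and ``eta`` i.i.d.
    standard normal, followed by renormalization.  In the pathological case
    ``|n| = 0`` after the update, a uniformly random unit vector is drawn.
    """
    if dt > T / 10:
        log.warning("dt = %g exceeds T/10 = %g; orientation dynamics "
                    "may be poorly resolved", dt, T / 10)
    n = np.atleast_2d(np.asarray(n, dtype=float))
    drive = np.atleast_2d(np.asarray(drive, dtype=float))
    eta = rng.standard_normal(n.shape)

    def project(v):
        return v - (n * v).sum(axis=1, keepdims=True) * n

    out = (n + (dt / T) * project(drive)
           + (math.sqrt(dt) * sigma / T) * project(eta))
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    bad = norm[:, 0] == 0.0
    if np.any(bad):
        log.warning("degenerate orientation for %d cell(s); redrawing",
                    int(bad.sum()))
        phi = rng.uniform(0.0, 2.0 * math.pi, size=int(bad.sum()))
        out[bad] = np.column_stack([np.cos(phi), np.sin(phi)])
        norm[bad] = 1.0
    return out / norm


def step_position(positions: np.ndarray, n: np.ndarray, dt: float) -> np.ndarray:
    """Constant-unit-speed advection: ``r <- r + n dt``."""
    return np.asarray(positions, dtype=float) + np.asarray(n, dtype=float) * dt


def inject_cells(J: float, W: float, dt: float, rng: np.random.Generator,
                 init_angle_halfwidth: float = 0.0,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Draw this step's entrants at the ``y = 0`` wall.

    The count is Poisson with mean ``J W dt`` (the configured uniform flux);
    positions are uniform in ``x``; each orientation makes an angle with the
    ``+y`` axis drawn uniformly from ``[-alpha, alpha]`` with
    ``alpha = init_angle_halfwidth`` (``alpha = 0`` gives every entrant
    ``n = (0, 1)``).  Returns ``(positions, orientations)``.
    """
    if J < 0:
        raise ValueError("J must be >= 0")
    count = int(rng.poisson(J * W * dt)) if J > 0 else 0
    if count == 0:
        return np.empty((0, 2)), np.empty((0, 2))
    x = rng.uniform(0.0, W, size=count)
    pos = np.column_stack([x, np.zeros(count)])
    if init_angle_halfwidth > 0:
        phi = rng.uniform(-init_angle_halfwidth, init_angle_halfwidth,
                          size=count)
    else:
        phi = np.zeros(count)
    ori = np.column_stack([np.sin(phi), np.cos(phi)])
    return pos, ori


def apply_boundaries(positions: np.ndarray, orientations: np.ndarray,
                     W: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chamber boundary rules applied after a position step.

    ``x`` wraps modulo ``W`` (periodic lateral walls); cells reaching
    ``y >= 1`` exit into the reservoir and are flagged for removal; cells
    dipping below the entry wall are reflected (``y <- -y``, upward
    orientation component).  Returns ``(positions, orientations, keep)``
    where ``keep`` is a boolean mask of the surviving cells; positions and
    orientations are modified copies including the removed rows.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float)).copy()
    ori = np.atleast_2d(np.asarray(orientations, dtype=float)).copy()
    if pos.size == 0:
        return pos, ori, np.zeros(0, dtype=bool)
    pos[:, 0] = np.mod(pos[:, 0], W)
    below = pos[:, 1] < 0
    pos[below, 1] *= -1.0
    ori[below, 1] = np.abs(ori[below, 1])
    keep = pos[:, 1] < 1.0
    return pos, ori, keep
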