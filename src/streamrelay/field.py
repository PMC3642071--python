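"""Explicit finite-difference solver for the chemoattractant field.

The dimensionless cAMP concentration ``c(x, y, t)`` obeys

    dc/dt = D lap(c) - k(y) c + beta sum_i delta2(r - r_i),

on ``[0, W) x [0, 1]`` with Dirichlet walls ``c(y=0) = 0`` (cell entry side)
and ``c(y=1) = 1`` (reservoir side), periodic in ``x``.  The equation is
advanced by forward-time centred-space (FTCS) Euler steps on a square grid of
spacing ``h``; each cell deposits its secreted mass onto the nearest grid
node (a Kronecker-delta discretization of the 2-D Dirac delta, normalization
``1/h^2``).

Node ``(i, j)`` sits at ``(i h, j h)`` with ``j = 0`` the entry wall.  Arrays
are indexed ``values[i, j]``.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .degradation import DegradationProfile

__all__ = ["ScalarField", "deposit_sources", "ftcs_step", "gradient_at",
           "steady_uniform_deg_profile"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ScalarField:
    """Chemoattractant concentration on a regular grid.

    ``values`` has shape ``(Nx, Ny)`` with ``Nx = round(W/h)`` columns
    (periodic in ``x``, so ``x = W`` is identified with ``x = 0``) and
    ``Ny = round(1/h) + 1`` rows spanning ``y in [0, 1]``.  ``bc_lo`` and
    ``bc_hi`` are the Dirichlet values pinned at ``j = 0`` and ``j = Ny-1``
    after every step.  ``periodic_y=True`` turns the domain into a fully
    periodic torus (no Dirichlet walls), used for conservation checks.
    """

    values: np.ndarray
    h: float
    width: float
    bc_lo: float = 0.0
    bc_hi: float = 1.0
    periodic_y: bool = False

    @property
    def nx(self) -> int:
        return self.values.shape[0]

    @property
    def ny(self) -> int:
        return self.values.shape[1]

    @property
    def y_nodes(self) -> np.ndarray:
        if self.periodic_y:
            return np.arange(self.ny) * self.h
        return np.linspace(0.0, 1.0, self.ny)

    @classmethod
    def linear(cls, width: float, h: float) -> "ScalarField":
        """The pre-established linear gradient ``c = y`` (no cells yet)."""
        nx = int(round(width / h))
        ny = int(round(1.0 / h)) + 1
        if abs(nx * h - width) > 1e-9 * width:
            raise ValueError(f"W = {width} is not a multiple of h = {h}")
        if abs((ny - 1) * h - 1.0) > 1e-9:
            raise ValueError(f"1/h must be an integer, got h = {h}")
        vals = np.tile(np.linspace(0.0, 1.0, ny), (nx, 1))
        return cls(values=vals, h=h, width=width)

    @classmethod
    def zeros(cls, width: float, h: float, **kw) -> "ScalarField":
        nx = int(round(width / h))
        ny = nx if kw.get("periodic_y") else int(round(1.0 / h)) + 1
        return cls(values=np.zeros((nx, ny)), h=h, width=width, **kw)

    def total_mass(self) -> float:
        """Integral of the field over the domain, ``sum(c) h^2``."""
        return float(self.values.sum() * self.h**2)


def deposit_sources(field: ScalarField, positions: np.ndarray, beta: float,
                    dt: float) -> ScalarField:
    """Add the cells' secretion to the field (in place; returns the field).

    Each cell at ``(x, y)`` adds ``beta dt / h^2`` to the grid node nearest
    to it (ties round half to even, as numpy does); the added total mass is
    exactly ``n_cells * beta * dt``.  Positions must lie inside
    ``[0, W) x [0, 1]``.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0 or beta == 0.0:
        return field
    x, y = positions[:, 0], positions[:, 1]
    ymax = field.ny * field.h if field.periodic_y else 1.0
    if np.any((x < 0) | (x >= field.width) | (y < 0) | (y > ymax)):
        raise ValueError("source position outside the chamber")
    i = np.rint(x / field.h).astype(np.intp) % field.nx
    j = np.rint(y / field.h).astype(np.intp)
    if field.periodic_y:
        j %= field.ny
    np.add.at(field.values, (i, j), beta * dt / field.h**2)
    return field


def ftcs_step(field: ScalarField, kprofile: DegradationProfile, D: float,
              dt: float) -> ScalarField:
    """One forward-time centred-space update (in place; returns the field).

    Interior nodes receive ``c += dt (D lap5(c) - k(y) c)`` with the 5-point
    Laplacian (periodic wrap in ``x``), after which the Dirichlet rows are
    re-pinned.  Negative values (possible only through round-off) are clipped
    to zero.  Raises if the stability bound ``dt <= h^2/(4D)`` is violated.
    """
    h = field.h
    if D > 0 and dt > h * h / (4.0 * D) * (1 + 1e-12):
        raise ValueError(
            f"FTCS unstable: dt = {dt} > h^2/(4 D) = {h * h / (4 * D)}")
    c = field.values
    k = kprofile.values
    if k.shape != (field.ny,):
        raise ValueError("degradation profile does not match the grid")
    if field.periodic_y:
        lap = (np.roll(c, -1, axis=0) + np.roll(c, 1, axis=0)
               + np.roll(c, -1, axis=1) + np.roll(c, 1, axis=1)
               - 4.0 * c) / (h * h)
        c += dt * (D * lap - k[None, :] * c)
    else:
        core = c[:, 1:-1]
        lap = c[:, 2:] + c[:, :-2]
        lap[1:-1] += c[2:, 1:-1]
        lap[1:-1] += c[:-2, 1:-1]
        lap[0] += c[1, 1:-1]
        lap[0] += c[-1, 1:-1]
        lap[-1] += c[-2, 1:-1]
        lap[-1] += c[0, 1:-1]
        lap -= 4.0 * core
        lap *= dt * D / (h * h)
        lap -= (dt * k[None, 1:-1]) * core
        core += lap
        c[:, 0] = field.bc_lo
        c[:, -1] = field.bc_hi
    worst = float(c.min())
    if worst < 0:
        if worst < -1e-12:
            log.warning("clipped negative field values (min %.3e)", worst)
        np.clip(c, 0.0, None, out=c)
    return field


def _node_gradients(field: ScalarField, ii: np.ndarray, jj: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient at the given nodes (gathered, not full
    grid): periodic in ``i``, one-sided at the ``j`` walls."""
    c, h, nx, ny = field.values, field.h, field.nx, field.ny
    gx = (c[(ii + 1) % nx, jj] - c[(ii - 1) % nx, jj]) / (2.0 * h)
    jp = np.minimum(jj + 1, ny - 1)
    jm = np.maximum(jj - 1, 0)
    gy = (c[ii, jp] - c[ii, jm]) / ((jp - jm) * h)
    return gx, gy


def gradient_at(field: ScalarField, positions: np.ndarray) -> np.ndarray:
    """Raw (unnormalized) field gradient at off-grid point(s).

    Nodal gradients are formed by central differences (periodic in ``x``,
    one-sided at the ``y`` walls) and interpolated bilinearly, giving a
    continuous, O(h^2)-accurate gradient everywhere in the chamber.
    """
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 1
    p = np.atleast_2d(pos)
    h, nx, ny = field.h, field.nx, field.ny
    fx = np.mod(p[:, 0], field.width) / h
    fy = np.clip(p[:, 1], 0.0, 1.0) / h
    i0 = np.floor(fx).astype(np.intp) % nx
    j0 = np.minimum(np.floor(fy).astype(np.intp), ny - 2)
    tx = fx - np.floor(fx)
    ty = fy - j0
    i1 = (i0 + 1) % nx
    j1 = j0 + 1
    gx00, gy00 = _node_gradients(field, i0, j0)
    gx10, gy10 = _node_gradients(field, i1, j0)
    gx01, gy01 = _node_gradients(field, i0, j1)
    gx11, gy11 = _node_gradients(field, i1, j1)
    w00 = (1 - tx) * (1 - ty)
    w10 = tx * (1 - ty)
    w01 = (1 - tx) * ty
    w11 = tx * ty
    out = np.empty_like(p)
    out[:, 0] = w00 * gx00 + w10 * gx10 + w01 * gx01 + w11 * gx11
    out[:, 1] = w00 * gy00 + w10 * gy10 + w01 * gy01 + w11 * gy11
    return out[0] if single else out


def steady_uniform_deg_profile(kconst: float, D: float, y) -> np.ndarray:
    """Exact source-free steady state with uniform degradation.

    Solves ``D c'' = k c`` with ``c(0) = 0``, ``c(1) = 1``:
    ``c(y) = sinh(lam y)/sinh(lam)`` with ``lam = sqrt(k/D)`` (the linear
    profile ``c = y`` when ``k = 0``).  Used as a validation oracle for the
    FTCS solver.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    if kconst < 0:
        raise ValueError("kconst must be >= 0")
    y = np.asarray(y, dtype=float)
    if kconst == 0:
        return y.copy()
    lam = math.sqrt(kconst / D)
    # sinh(lam y)/sinh(lam) in overflow-safe form
    num = np.exp(lam * (y - 1.0)) - np.exp(-lam * (y + 1.0))
    den = 1.0 - math.exp(-2.0 * lam)
    return num / den
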