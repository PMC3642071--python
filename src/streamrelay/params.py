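"""Physical and dimensionless parameter sets for the gradient-chamber model.

The chamber is a rectangle of length ``L`` (along the imposed chemoattractant
gradient) and width ``W`` (periodic direction).  All simulation code works in
chamber units, obtained by rescaling lengths by ``L``, times by ``L / v0``
(``v0`` the constant cell speed) and concentrations by the reservoir
concentration ``c0``.  In these units the chamber is ``[0, W_hat) x [0, 1]``,
cells move at unit speed, and the imposed boundary conditions on the
chemoattractant are ``c_hat = 0`` at the entry wall (``y_hat = 0``) and
``c_hat = 1`` at the reservoir wall (``y_hat = 1``).

The dimensionless groups are

====================  =========================================
``D_hat = D/(v0 L)``  chemoattractant diffusivity
``beta = a/(v0 L c0)``  secretion rate per cell (signal relay)
``k_hat = k_max L/v0``  peak degradation rate
``T_hat = T v0/L``    orientation relaxation (response) time
``sigma_hat = sigma sqrt(L/v0)``  angular white-noise amplitude
``f0``                repulsion strength (already dimensionless)
``J_hat = J L^2/v0``  cell injection flux per unit dimensionless
                      time and width
====================  =========================================
"""

from __future__ import annotations

import dataclasses
import math

__all__ = [
    "PhysicalParams",
    "DimensionlessParams",
    "nondimensionalize",
    "redimensionalize",
    "check_stability",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclasses.dataclass(frozen=True)
class PhysicalParams:
    """Model parameters in laboratory units (micrometres and minutes).

    Attributes
    ----------
    cell_radius:
        Soft-disk cell radius ``R`` (um).
    speed:
        Constant self-propulsion speed ``v0`` (um/min).
    diffusivity:
        Chemoattractant (cAMP) diffusivity ``D`` (um^2/min).
    response_time:
        Orientation relaxation time ``T`` (min).
    noise:
        White-noise amplitude ``sigma`` (min^-1/2); see
        :func:`streamrelay.agents.step_orientation` for the exact contract.
    repulsion:
        Dimensionless soft-disk repulsion strength ``f0``.
    secretion:
        cAMP secretion rate ``a`` per cell (amount/min).
    kdeg_max:
        Peak cAMP degradation rate ``k_max`` (1/min).
    c0:
        Reservoir cAMP concentration (amount/um^2; the field is a surface
        density in the thin chamber).
    injection_flux:
        Cell injection flux ``J`` at the entry wall (cells/(min um)).
    length, width:
        Chamber length ``L`` and width ``W`` (um).
    """

    cell_radius: float
    speed: float
    diffusivity: float
    response_time: float
    noise: float
    repulsion: float
    secretion: float
    kdeg_max: float
    c0: float
    injection_flux: float
    length: float
    width: float

    def __post_init__(self) -> None:
        for name in ("cell_radius", "speed", "diffusivity", "response_time",
                     "c0", "length", "width"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        for name in ("noise", "repulsion", "secretion", "kdeg_max",
                     "injection_flux"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")


@dataclasses.dataclass(frozen=True)
class DimensionlessParams:
    """Complete dimensionless parameter set plus numerical controls.

    Model parameters are in chamber units (see module docstring).  The
    numerical controls are the grid spacing ``h`` and time step ``dt`` shared
    by the field solver and the agents, the total simulated time ``t_end``,
    and output cadences.
    """

    D: float
    beta: float
    kmax: float
    sigma: float
    T: float
    f0: float
    J: float
    W: float
    R: float
    # numerics
    h: float
    dt: float
    t_end: float
    n_snapshots: int = 5
    record_stride: int = 100
    init_angle_halfwidth: float = 0.0
    deg_kind: str = "parabolic"

    def __post_init__(self) -> None:
        for name in ("D", "beta", "kmax", "sigma", "J",
                     "init_angle_halfwidth"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("T", "f0", "W", "R", "h", "dt", "t_end"):
            _require(getattr(self, name) > 0 or (name == "f0" and self.f0 >= 0),
                     f"{name} must be positive")
        _require(0 < self.h < self.W, "grid spacing h must satisfy 0 < h < W")
        _require(self.R < self.W / 2, "cell radius R must be < W/2")
        _require(self.deg_kind in ("parabolic", "uniform", "zero"),
                 f"unknown degradation kind {self.deg_kind!r}")
        _require(self.n_snapshots >= 0, "n_snapshots must be >= 0")
        _require(self.record_stride >= 1, "record_stride must be >= 1")


def nondimensionalize(p: PhysicalParams, *, h: float, dt: float,
                      t_end: float, **numerics) -> DimensionlessParams:
    """Map laboratory-unit parameters to chamber units.

    ``h``, ``dt`` and ``t_end`` are supplied directly in chamber units (they
    are numerical choices, not physical quantities).  Extra keyword arguments
    are passed through to :class:`DimensionlessParams`.
    """
    L, v0, c0 = p.length, p.speed, p.c0
    return DimensionlessParams(
        D=p.diffusivity / (v0 * L),
        beta=p.secretion / (v0 * L * c0),
        kmax=p.kdeg_max * L / v0,
        sigma=p.noise * math.sqrt(L / v0),
        T=p.response_time * v0 / L,
        f0=p.repulsion,
        J=p.injection_flux * L**2 / v0,
        W=p.width / L,
        R=p.cell_radius / L,
        h=h, dt=dt, t_end=t_end, **numerics,
    )


def redimensionalize(dp: DimensionlessParams, *, length: float, speed: float,
                     c0: float) -> PhysicalParams:
    """Invert :func:`nondimensionalize` given the three reference scales."""
    _require(length > 0 and speed > 0 and c0 > 0,
             "length, speed and c0 must be > 0")
    L, v0 = length, speed
    return PhysicalParams(
        cell_radius=dp.R * L,
        speed=v0,
        diffusivity=dp.D * v0 * L,
        response_time=dp.T * L / v0,
        noise=dp.sigma / math.sqrt(L / v0),
        repulsion=dp.f0,
        secretion=dp.beta * v0 * L * c0,
        kdeg_max=dp.kmax * v0 / L,
        c0=c0,
        injection_flux=dp.J * v0 / L**2,
        length=L,
        width=dp.W * L,
    )


def check_stability(dp: DimensionlessParams) -> bool:
    """Explicit-scheme stability predicate.

    True iff the forward-time centred-space diffusion bound
    ``dt <= h^2 / (4 D)`` holds (trivially true when ``D = 0``) and, when
    degradation is active, the decay term is non-oscillatory:
    ``dt * kmax <= 1``.
    """
    ok = True
    if dp.D > 0:
        ok = ok and dp.dt <= dp.h**2 / (4.0 * dp.D)
    if dp.kmax > 0:
        ok = ok and dp.dt * dp.kmax <= 1.0
    return ok
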