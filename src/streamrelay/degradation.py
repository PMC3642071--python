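"""Spatial profile of the chemoattractant degradation rate.

Degradation of extracellular cAMP is carried out by the phosphodiesterase
PDE1 secreted by the cells themselves.  In the thin gradient chamber the
enzyme reaches a steady, laterally homogeneous density that vanishes at both
reservoirs (the enzyme escapes into the much deeper wells) and obeys a
time-independent 1-D diffusion equation with a uniform source.  The solution
is a parabola in the across-chamber coordinate ``y``; the degradation rate is
taken proportional to it:

    k(y) = 4 k_max y (1 - y),        0 <= y <= 1,

normalized so the peak value at mid-chamber is ``k_max``.  A spatially
uniform variant carrying the same total amount of enzyme, ``k = (2/3) k_max``,
is provided for comparison, and ``zero`` models mutants that cannot secrete
the enzyme.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["DegradationProfile", "parabolic", "uniform_equivalent",
           "make_profile"]

KINDS = ("parabolic", "uniform", "zero")


def parabolic(kmax: float, y):
    """Parabolic degradation rate ``4 kmax y (1 - y)`` at position(s) ``y``.

    Zero at both walls, peak ``kmax`` at mid-chamber.  ``y`` outside
    ``[0, 1]`` raises.
    """
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    out = 4.0 * kmax * y * (1.0 - y)
    return out if out.ndim else float(out)


def uniform_equivalent(kmax: float) -> float:
    """Constant rate with the same integral over ``y`` as the parabola.

    ``int_0^1 4 kmax y(1-y) dy = (2/3) kmax``, i.e. the total amount of
    degrading enzyme in the chamber is matched.
    """
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    return (2.0 / 3.0) * kmax


@dataclasses.dataclass(frozen=True)
class DegradationProfile:
    """Degradation rate tabulated on the ``Ny`` grid rows of the field.

    Static in time; built once per run.
    """

    kind: str
    kmax: float
    values: np.ndarray  # shape (Ny,)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if np.any(self.values < 0):
            raise ValueError("degradation rates must be >= 0")


def make_profile(kind: str, kmax: float, y_nodes: np.ndarray) -> DegradationProfile:
    """Tabulate a degradation profile of the given kind at the grid rows."""
    y_nodes = np.asarray(y_nodes, dtype=float)
    if kind == "parabolic":
        values = np.asarray(parabolic(kmax, y_nodes), dtype=float)
    elif kind == "uniform":
        values = np.full_like(y_nodes, uniform_equivalent(kmax))
    elif kind == "zero":
        values = np.zeros_like(y_nodes)
    else:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    return DegradationProfile(kind=kind, kmax=kmax, values=values)
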