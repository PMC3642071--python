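"""Closed-form results for non-interacting cells in a uniform gradient.

With secretion and repulsion switched off, the orientation angle ``theta``
(measured from the gradient direction ``+y``) obeys the scalar SDE

    d(theta) = -(1/T) sin(theta) dt + (sigma/T) dW.

Its stationary Fokker-Planck solution is the von Mises density

    p(theta) ~ exp(kappa cos(theta)),    kappa = 2 T / sigma^2,

whose mean resultant length ``R = I1(kappa)/I0(kappa)`` equals the mean
progression of a population of non-interacting cells, and whose small-angle
variance is ``Var(theta) ~ 1/kappa = sigma^2/(2 T)``.  These expressions are
tied to the noise contract of :mod:`streamrelay.agents` (they are verified
against a brute-force Euler-Maruyama simulation in the test suite) and serve
both as oracles for the simulator and to calibrate ``sigma`` from a measured
angle variance.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import special, stats

__all__ = ["AngleLaw", "stationary_angle_density", "mean_progression_oracle",
           "calibrate_noise"]


@dataclasses.dataclass(frozen=True)
class AngleLaw:
    """Stationary orientation-angle law, a von Mises distribution.

    ``kappa = inf`` encodes the noiseless degenerate case (all mass at
    ``theta = 0``).
    """

    kappa: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def var_small_angle(self) -> float:
        """Small-angle (large kappa) variance ``1/kappa``."""
        return 0.0 if math.isinf(self.kappa) else 1.0 / self.kappa

    @property
    def mean_resultant(self) -> float:
        """``R = I1(kappa)/I0(kappa)``, the expected progression."""
        return mean_progression_oracle(self.kappa)

    def pdf(self, theta) -> np.ndarray:
        if math.isinf(self.kappa):
            raise ValueError("degenerate law (sigma = 0) has no density")
        return stats.vonmises.pdf(theta, self.kappa)

    def cdf(self, theta) -> np.ndarray:
        if math.isinf(self.kappa):
            raise ValueError("degenerate law (sigma = 0) has no density")
        return stats.vonmises.cdf(theta, self.kappa)


def stationary_angle_density(sigma: float, T: float) -> AngleLaw:
    """Stationary angle law for noise ``sigma`` and response time ``T``."""
    if sigma < 0 or T <= 0:
        raise ValueError("need sigma >= 0 and T > 0")
    if sigma == 0.0:
        return AngleLaw(kappa=math.inf)
    return AngleLaw(kappa=2.0 * T / sigma**2)


def mean_progression_oracle(kappa: float) -> float:
    """Mean resultant length ``I1(kappa)/I0(kappa)`` of the von Mises law.

    Equals the stationary mean progression (population-average velocity
    component along the gradient, in units of the cell speed) of
    non-interacting cells.  Computed with exponentially scaled Bessel
    functions, stable for any ``kappa >= 0``.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if math.isinf(kappa):
        return 1.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def calibrate_noise(angle_variance: float, T: float) -> float:
    """Invert the small-angle variance relation for the noise amplitude.

    ``sigma = sqrt(2 T Var(theta))``.  Warns when the implied concentration
    ``kappa = 1/Var`` is below 5, where the small-angle inversion is a poor
    approximation of the full von Mises variance.
    """
    if angle_variance <= 0 or T <= 0:
        raise ValueError("need angle_variance > 0 and T > 0")
    kappa = 1.0 / angle_variance
    if kappa < 5.0:
        warnings.warn(
            f"implied kappa = {kappa:.3g} < 5: the small-angle inversion "
            "is unreliable at this noise level", stacklevel=2)
    return math.sqrt(2.0 * T * angle_variance)
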