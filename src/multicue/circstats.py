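"""Circular-statistics primitives for von Mises distributions.

Angles cross the API in degrees, wrapped to (-180, 180]; internally the
module works in radians.  A von Mises distribution ``M(theta; mu, kappa)``
with density proportional to ``exp[kappa * cos(theta - mu)]`` is treated
interchangeably as a two-dimensional vector ``kappa * (cos mu, sin mu)``:
products of densities correspond to vector sums, which is the algebra that
underlies optimal integration of circular cues.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "KAPPA_CAP",
    "VonMises",
    "CircVector",
    "wrap_deg",
    "vm_pdf",
    "resultant_length",
    "inv_resultant",
    "vm_product",
    "vm_ratio",
    "circ_estimate",
]

#: Concentrations above this are treated as a point mass; ``circ_estimate``
#: saturates here when all samples coincide (the true kappa diverges).
KAPPA_CAP = 1e8

# Resultant lengths closer to 1 than A(KAPPA_CAP) are indistinguishable
# from a point mass at double precision.
_R_CAP = None  # computed lazily

_TWO_PI = 2.0 * math.pi


def wrap_deg(angle):
    """Wrap angles in degrees to the interval (-180, 180]."""
    wrapped = np.asarray(angle, dtype=float) % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # map -180 (from exact multiples of 360 shifted) onto +180
    wrapped = np.where(wrapped <= -180.0, wrapped + 360.0, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class VonMises:
    """A von Mises distribution on the circle.

    Parameters
    ----------
    mu : float
        Mean direction in degrees, wrapped to (-180, 180].  Meaningless
        when ``kappa == 0``; see ``mu_defined``.
    kappa : float
        Concentration (dimensionless, >= 0).  ``kappa == 0`` denotes the
        uniform circular distribution.
    mu_defined : bool
        False for the uniform distribution (zero resultant vector), where
        the mean direction carries no information.  Downstream code must
        branch on this flag explicitly instead of meeting a NaN.
    """

    mu: float
    kappa: float
    mu_defined: bool = True

    def __post_init__(self):
        if not math.isfinite(self.kappa) or self.kappa < 0:
            raise ValueError(f"kappa must be finite and >= 0, got {self.kappa}")
        object.__setattr__(self, "mu", wrap_deg(self.mu))
        if self.kappa == 0.0:
            object.__setattr__(self, "mu_defined", False)

    @classmethod
    def uniform(cls) -> "VonMises":
        return cls(mu=0.0, kappa=0.0)

    def to_vector(self) -> "CircVector":
        mu_rad = math.radians(self.mu)
        return CircVector(self.kappa * math.cos(mu_rad),
                          self.kappa * math.sin(mu_rad))


@dataclass(frozen=True)
class CircVector:
    """Cartesian embedding ``kappa * (cos mu, sin mu)`` of a von Mises
    distribution; vector addition implements density multiplication."""

    x: float
    y: float

    @property
    def length(self) -> float:
        return math.hypot(self.x, self.y)

    def __add__(self, other: "CircVector") -> "CircVector":
        return CircVector(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "CircVector") -> "CircVector":
        return CircVector(self.x - other.x, self.y - other.y)

    def to_vonmises(self, tol: float = 0.0) -> VonMises:
        """Convert back to distribution parameters.

        A (near-)zero resultant maps to the uniform distribution with the
        undefined-mean flag set.
        """
        kappa = self.length
        if kappa <= tol or kappa == 0.0:
            return VonMises.uniform()
        return VonMises(math.degrees(math.atan2(self.y, self.x)), kappa)


def vm_pdf(theta, d: VonMises):
    """Von Mises density at ``theta`` (degrees), per *radian*.

    ``kappa == 0`` returns the uniform density ``1 / (2 pi)``.  Computed
    with exponentially scaled Bessel functions so large kappa does not
    overflow.
    """
    theta = np.asarray(theta, dtype=float)
    if d.kappa == 0.0:
        out = np.full(theta.shape, 1.0 / _TWO_PI)
        return float(out) if out.ndim == 0 else out
    delta = np.radians(theta - d.mu)
    # exp(k cos d) / (2 pi I0(k)) = exp(k (cos d - 1)) / (2 pi i0e(k))
    dens = np.exp(d.kappa * (np.cos(delta) - 1.0)) / (
        _TWO_PI * special.i0e(d.kappa))
    return float(dens) if dens.ndim == 0 else dens


def resultant_length(kappa):
    """Mean resultant length ``A(kappa) = I1(kappa) / I0(kappa)``.

    The first trigonometric moment of a von Mises distribution; strictly
    increasing from A(0)=0 to 1 as kappa -> infinity.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    out = np.where(kappa > 0,
                   special.i1e(kappa) / np.where(kappa > 0, special.i0e(kappa), 1.0),
                   0.0)
    return float(out) if out.ndim == 0 else out


def _r_cap() -> float:
    global _R_CAP
    if _R_CAP is None:
        _R_CAP = resultant_length(KAPPA_CAP)
    return _R_CAP


def inv_resultant(r: float) -> float:
    """Inverse of :func:`resultant_length` on [0, 1).

    No closed form exists; solved by bracketed root finding to 1e-10.
    Resultants beyond ``A(KAPPA_CAP)`` saturate at ``KAPPA_CAP``.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError(f"resultant length must lie in [0, 1), got {r}")
    if r == 0.0:
        return 0.0
    if r >= _r_cap():
        return KAPPA_CAP
    # Banerjee-style starting guess, then bracket and polish.
    guess = r * (2.0 - r * r) / (1.0 - r * r)
    lo, hi = guess / 4.0 + 1e-12, max(4.0 * guess, 1e-6)
    while resultant_length(hi) < r:
        hi *= 4.0
    while resultant_length(lo) > r:
        lo /= 4.0
    return float(optimize.brentq(lambda k: resultant_length(k) - r, lo, hi,
                                 xtol=1e-10, rtol=4 * np.finfo(float).eps))


def vm_product(d1: VonMises, d2: VonMises) -> VonMises:
    """Product of two von Mises densities, renormalized.

    Equals the vector sum of the two distributions' embeddings: the
    resulting mean/concentration satisfy
    ``kappa e^{j mu} = kappa1 e^{j mu1} + kappa2 e^{j mu2}``.
    (Near-)exact cancellation — resultant below 1e-12 of the summed
    concentrations — returns the uniform distribution (flagged).
    """
    return (d1.to_vector() + d2.to_vector()).to_vonmises(
        tol=1e-12 * (d1.kappa + d2.kappa))


def vm_ratio(d1: VonMises, d2: VonMises) -> VonMises:
    """Ratio of two von Mises densities, renormalized.

    Using ``-cos(t) = cos(t - pi)``, dividing by ``M(mu2, kappa2)`` is the
    same as multiplying by ``M(mu2 + 180deg, kappa2)``, i.e. a vector
    difference.  This is the disparity measure between two circular
    estimates.
    """
    return vm_product(d1, VonMises(d2.mu + 180.0, d2.kappa))


def circ_estimate(samples) -> VonMises:
    """Estimate a von Mises distribution from angular samples (degrees).

    The mean is the argument of the sample resultant vector and the
    concentration is ``inv_resultant`` of its length — the moment
    estimators for circular data.  Degenerate all-identical samples
    saturate at ``KAPPA_CAP``; zero resultant yields the uniform
    distribution with the undefined-mean flag.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    z = np.exp(1j * np.radians(samples)).mean()
    r = float(np.abs(z))
    if r == 0.0:
        return VonMises.uniform()
    r = min(r, np.nextafter(1.0, 0.0))
    return VonMises(math.degrees(math.atan2(z.imag, z.real)), inv_resultant(r))
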