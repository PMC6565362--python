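"""Population-vector readout and Bayesian-optimality predictions.

The position of an activity bump is read out as the angle of the complex
population vector ``z = arg[sum_theta r(theta) e^{j theta}]``.  Over a
stationary stretch of simulation the bump position samples the posterior
encoded by the population: its circular mean and concentration (via the
inverse mean-resultant-length map) are the network's estimate.  The
optimality predictions are pure vector algebra on the single-cue
estimates — the sum for integration by congruent neurons, the difference
(or equivalently the sum of opposite-neuron estimates) for the cue
disparity carried by opposite neurons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from multicue.circstats import (
    VonMises,
    circ_estimate,
    vm_product,
    wrap_deg,
)

__all__ = [
    "UndefinedAngleError",
    "PopulationEstimate",
    "population_vector",
    "estimate_distribution",
    "predict_integration",
    "predict_disparity",
    "predict_disparity_from_congruent",
    "recover_direct_cue",
    "recovery_r2",
]


class UndefinedAngleError(ValueError):
    """The population vector has (numerically) zero resultant."""


@dataclass(frozen=True)
class PopulationEstimate:
    """Decoded distribution of a bump-position time series.

    ``mean`` (degrees) and ``kappa`` are the circular moment estimates;
    ``mean_se`` is a batch-means standard error of the mean, accounting
    for the autocorrelation of the bump position over time.  ``source``
    optionally records (module, neuron type, cue condition).
    """

    mean: float
    kappa: float
    n_samples: int
    mean_se: float = float("nan")
    mean_defined: bool = True
    source: Optional[tuple] = None

    def as_vonmises(self) -> VonMises:
        if not self.mean_defined:
            return VonMises.uniform()
        return VonMises(self.mean, self.kappa)


def population_vector(rates, theta_deg, tol: float = 1e-9):
    """Bump position(s) from firing rates on the ring, in degrees.

    ``rates`` is (n,) or (samples, n); ``theta_deg`` the preferred
    directions.  Raises :class:`UndefinedAngleError` when the resultant of
    any sample is below ``tol`` times the summed rate (all-zero or uniform
    profiles carry no direction).
    """
    rates = np.asarray(rates, dtype=float)
    phase = np.exp(1j * np.radians(np.asarray(theta_deg, dtype=float)))
    z = rates @ phase
    total = rates.sum(axis=-1)
    bad = np.abs(z) <= tol * np.maximum(total, tol)
    if np.any(bad):
        raise UndefinedAngleError("population vector undefined: zero or "
                                  "uniform rate profile")
    ang = np.degrees(np.angle(z))
    return float(ang) if np.ndim(ang) == 0 else ang


def estimate_distribution(z_series, n_batches: int = 20,
                          source: Optional[tuple] = None,
                          ) -> PopulationEstimate:
    """Circular mean / concentration of a bump-position series (degrees).

    Delegates to :func:`multicue.circstats.circ_estimate`; the standard
    error of the mean comes from batch means (the series is split into
    ``n_batches`` contiguous blocks whose circular means are treated as
    independent), which is robust to the ~tau autocorrelation of the bump.
    """
    z = np.asarray(z_series, dtype=float)
    if z.size < 100:
        raise ValueError("need at least 100 samples for a stable estimate")
    d = circ_estimate(z)
    nb = min(n_batches, z.size // 5)
    blocks = np.array_split(z, nb)
    bmeans = []
    for b in blocks:
        zb = np.exp(1j * np.radians(b)).mean()
        bmeans.append(math.degrees(math.atan2(zb.imag, zb.real)))
    dev = wrap_deg(np.asarray(bmeans) - d.mu)
    se = float(np.std(dev, ddof=1) / math.sqrt(nb))
    return PopulationEstimate(mean=d.mu, kappa=d.kappa, n_samples=z.size,
                              mean_se=se, mean_defined=d.mu_defined,
                              source=source)


def _combine(v, n_samples, se, source) -> PopulationEstimate:
    d = v.to_vonmises()
    return PopulationEstimate(mean=d.mu, kappa=d.kappa, n_samples=n_samples,
                              mean_se=se, mean_defined=d.mu_defined,
                              source=source)


def predict_integration(e1: PopulationEstimate, e2: PopulationEstimate,
                        ) -> PopulationEstimate:
    """Predicted combined-cue estimate of congruent neurons.

    Vector sum of the same group's single-cue estimates:
    ``kappa~ e^{j z~} = sum_l kappa(z|x_l) e^{j <z|x_l>}``.
    """
    d = vm_product(e1.as_vonmises(), e2.as_vonmises())
    se = math.hypot(e1.mean_se, e2.mean_se)
    return _combine(d.to_vector(), min(e1.n_samples, e2.n_samples), se,
                    ("prediction", "integration"))


def predict_disparity(e1: PopulationEstimate, e2: PopulationEstimate,
                      ) -> PopulationEstimate:
    """Predicted combined-cue estimate of *opposite* neurons, from the
    opposite neurons' own single-cue estimates (vector sum).

    Because the opposite group's indirect-cue estimate is already rotated
    by 180 degrees, summing it with the direct-cue estimate equals the
    vector *difference* of the congruent single-cue estimates; see
    :func:`predict_disparity_from_congruent` for that equivalent form.
    """
    d = vm_product(e1.as_vonmises(), e2.as_vonmises())
    se = math.hypot(e1.mean_se, e2.mean_se)
    return _combine(d.to_vector(), min(e1.n_samples, e2.n_samples), se,
                    ("prediction", "disparity"))


def predict_disparity_from_congruent(e_direct: PopulationEstimate,
                                     e_indirect: PopulationEstimate,
                                     ) -> PopulationEstimate:
    """Disparity prediction as the vector difference of the congruent
    group's single-cue estimates."""
    v = e_direct.as_vonmises().to_vector() - e_indirect.as_vonmises().to_vector()
    se = math.hypot(e_direct.mean_se, e_indirect.mean_se)
    return _combine(v, min(e_direct.n_samples, e_indirect.n_samples), se,
                    ("prediction", "disparity"))


def recover_direct_cue(rc: np.ndarray, ro: np.ndarray, theta_deg,
                       ) -> np.ndarray:
    """Recovered direct-cue estimate per time step, in degrees.

    ``s1(t)|x1 = arg[(sum rc) e^{j zc} + (sum ro) e^{j zo}]``: the summed
    firing rate of each group weights its population-vector angle, because
    the summed rate encodes the concentration of the represented
    distribution.  ``rc``/``ro`` are (samples, n) congruent/opposite rates
    of the same module.  Steps with exact cancellation yield NaN.
    """
    rc = np.atleast_2d(np.asarray(rc, dtype=float))
    ro = np.atleast_2d(np.asarray(ro, dtype=float))
    phase = np.exp(1j * np.radians(np.asarray(theta_deg, dtype=float)))
    zc = rc @ phase
    zo = ro @ phase
    wc = rc.sum(axis=-1)
    wo = ro.sum(axis=-1)
    v = wc * np.exp(1j * np.angle(zc)) + wo * np.exp(1j * np.angle(zo))
    out = np.degrees(np.angle(v))
    out[np.abs(v) <= 1e-12 * (wc + wo)] = np.nan
    return out if out.size > 1 else float(out[0])


def recovery_r2(recovered, reference) -> float:
    """Coefficient of determination of recovered vs reference angles.

    Residuals are wrapped to (-180, 180] about the identity line before
    squaring, and the total sum of squares is taken about the circular
    mean of the reference; both series are in degrees.
    """
    recovered = np.asarray(recovered, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if recovered.shape != reference.shape or recovered.size < 3:
        raise ValueError("need equally sized series of length >= 3")
    resid = wrap_deg(recovered - reference)
    zbar = np.exp(1j * np.radians(reference)).mean()
    ref_mean = math.degrees(math.atan2(zbar.imag, zbar.real))
    dev = wrap_deg(reference - ref_mean)
    ss_tot = float(np.sum(dev ** 2))
    if ss_tot == 0.0:
        raise ValueError("reference angles are all identical")
    return 1.0 - float(np.sum(resid ** 2)) / ss_tot
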