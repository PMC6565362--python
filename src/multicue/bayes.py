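"""Von Mises Bayesian model of cue integration and segregation.

Two stimulus features ``s1, s2`` generate two noisy cues ``x1, x2`` with
von Mises likelihoods ``M(x_m; s_m, kappa_m)``; a prior
``p(s1, s2) ~ M(s1 - s2; 0, kappa_s)`` encodes that the features tend to
coincide.  Marginalizing gives the integrated posterior

    p(s1 | x1, x2) ~ M(s1; x1, kappa_1) * M(s1; x2, kappa_2s),

where the indirect cue acts through an effective concentration
``kappa_2s`` defined by ``A(kappa_2s) = A(kappa_2) A(kappa_s)`` (the
convolution of the likelihood with the prior is matched to a von Mises by
equating mean resultant lengths).  The disparity distribution
``p_d(s1 | x1, x2) ~ p(s1|x1) / p(s1|x2)`` measures how much the two cues
disagree; in vector form integration is the sum and disparity the
difference of the two single-cue vectors, so the single-cue posterior is
recoverable from the pair — the half-sum of the two vectors.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

from multicue.circstats import (
    VonMises,
    inv_resultant,
    resultant_length,
    vm_product,
    vm_ratio,
    wrap_deg,
)

__all__ = [
    "INF_KAPPA",
    "CuePair",
    "effective_kappa",
    "posterior_integrated",
    "posterior_disparity",
    "recover_single_cue",
    "info_loss_fraction",
]

#: Sentinel concentration standing for "infinitely reliable" (kappa -> inf);
#: its mean resultant length is clamped to 1 so limits need no special cases.
INF_KAPPA = 1e12


@dataclass(frozen=True)
class CuePair:
    """One pair of cues: directions, likelihood concentrations, prior.

    ``x1, x2`` in degrees (wrapped to (-180, 180]); ``kappa1, kappa2`` are
    the likelihood concentrations of the direct and indirect cue;
    ``kappa_s`` the prior concentration coupling the two features.
    Concentrations at or above :data:`INF_KAPPA` are treated as infinite.
    """

    x1: float
    x2: float
    kappa1: float
    kappa2: float
    kappa_s: float

    def __post_init__(self):
        for name in ("kappa1", "kappa2", "kappa_s"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        object.__setattr__(self, "x1", wrap_deg(self.x1))
        object.__setattr__(self, "x2", wrap_deg(self.x2))


def _clamped_resultant(kappa: float) -> float:
    return 1.0 if kappa >= INF_KAPPA else resultant_length(kappa)


@functools.lru_cache(maxsize=4096)
def effective_kappa(kappa2: float, kappa_s: float) -> float:
    """Effective concentration of the indirect cue after the prior.

    Solves ``A(kappa_2s) = A(kappa_2) A(kappa_s)``.  Always bounded by
    ``min(kappa2, kappa_s)``: passing through a soft prior can only lose
    concentration.  In the sharp limit this reduces to the familiar
    Gaussian rule ``1/kappa_2s ~ 1/kappa_2 + 1/kappa_s``.
    """
    if kappa2 < 0 or kappa_s < 0:
        raise ValueError("concentrations must be >= 0")
    if kappa2 >= INF_KAPPA:
        return kappa_s if kappa_s < INF_KAPPA else INF_KAPPA
    if kappa_s >= INF_KAPPA:
        return kappa2
    target = _clamped_resultant(kappa2) * _clamped_resultant(kappa_s)
    if target == 0.0:
        return 0.0
    return inv_resultant(target)


def posterior_integrated(c: CuePair) -> VonMises:
    """Integrated posterior of s1 given both cues (vector sum)."""
    k2s = effective_kappa(c.kappa2, c.kappa_s)
    return vm_product(VonMises(c.x1, _finite(c.kappa1)),
                      VonMises(c.x2, k2s))


def posterior_disparity(c: CuePair) -> VonMises:
    """Disparity distribution of s1 given both cues (vector difference)."""
    k2s = effective_kappa(c.kappa2, c.kappa_s)
    return vm_ratio(VonMises(c.x1, _finite(c.kappa1)),
                    VonMises(c.x2, k2s))


def _finite(kappa: float) -> float:
    # VonMises validates finiteness; the sentinel itself is finite.
    return min(kappa, INF_KAPPA)


def recover_single_cue(integrated: VonMises, disparity: VonMises) -> VonMises:
    """Recover the single-(direct-)cue posterior from the pair.

    ``ln p(s1|x1) = [ln p(s1|x1,x2) + ln p_d(s1|x1,x2)] / 2``: the
    indirect-cue vectors cancel between the sum and the difference, so the
    recovered distribution is exactly ``M(x1, kappa1)`` when both inputs
    come from the same cue pair.
    """
    v = integrated.to_vector() + disparity.to_vector()
    from multicue.circstats import CircVector

    return CircVector(v.x / 2.0, v.y / 2.0).to_vonmises()


def info_loss_fraction(kappa1: float, kappa2: float, kappa_s: float) -> float:
    """Fraction of direct-cue Fisher information lost by integrating.

    In the sharp (Gaussian) approximation the posterior retains
    ``kappa1 (kappa2^-1 + kappa_s^-1) / (kappa1^-1 + kappa2^-1 + kappa_s^-1)``
    of the likelihood information ``kappa1`` about cue 1, so the lost
    fraction is ``kappa1^-1 / (kappa1^-1 + kappa2^-1 + kappa_s^-1)``.
    Increases with the prior concentration kappa_s; reaches 1 under full
    integration (kappa2, kappa_s -> inf).
    """
    for name, v in (("kappa1", kappa1), ("kappa2", kappa2), ("kappa_s", kappa_s)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    inv1 = 0.0 if kappa1 >= INF_KAPPA else 1.0 / kappa1
    inv2 = 0.0 if kappa2 >= INF_KAPPA else 1.0 / kappa2
    invs = 0.0 if kappa_s >= INF_KAPPA else 1.0 / kappa_s
    denom = inv1 + inv2 + invs
    if denom == 0.0:
        # all three infinitely sharp: the limit of the ratio is 1/3
        return 1.0 / 3.0
    return inv1 / denom
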