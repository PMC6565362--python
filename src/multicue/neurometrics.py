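"""Tuning curves, ROC discrimination and neurometric thresholds.

Characterizes single neurons of the network: tuning under each cueing
condition (congruent cells prefer the same direction under either cue,
opposite cells differ by 180 degrees, jittered reciprocal connections
produce intermediate cells), trial-by-trial rate distributions across cue
disparities, ideal-observer ROC analysis of those distributions, and
cumulative-Gaussian fits whose standard deviation is the neuronal
discrimination threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from multicue.circstats import wrap_deg
from multicue.decode import population_vector
from multicue.netsim import CueStimulus, NetworkParams, simulate

__all__ = [
    "TuningCurve",
    "NeurometricCurve",
    "measure_tuning",
    "preferred_direction",
    "preferred_directions",
    "pref_diff_histogram",
    "trial_rates",
    "disparity_trials",
    "disparity_rate_curves",
    "roc_fraction",
    "fit_neurometric",
    "predict_combined_threshold",
    "decision_boundary",
]

_CONDITIONS = ("cue1", "cue2", "both")


@dataclass(frozen=True)
class TuningCurve:
    """Mean (and SD over time) firing rate of one neuron vs probe angle."""

    probes: np.ndarray          # degrees, sorted as swept
    mean_rate: np.ndarray       # Hz
    sd_rate: np.ndarray         # Hz
    neuron: tuple               # (module, 'c'|'o', index)
    condition: str


@dataclass(frozen=True)
class NeurometricCurve:
    """ROC fractions vs probe plus the cumulative-Gaussian fit.

    ``threshold`` is the fitted sigma — the ideal-observer discrimination
    threshold.  ``converged`` is False when the fit failed or sigma is
    unidentifiable (e.g. all fractions at 0.5); then sigma is NaN.
    """

    probes: np.ndarray
    fractions: np.ndarray
    mu: float
    sigma: float
    converged: bool
    residual: float = float("nan")

    @property
    def threshold(self) -> float:
        return self.sigma


def _cues_for(condition: str, probe: float, alpha1: float, alpha2: float,
              probe2: Optional[float] = None):
    """Cue list for a probe; under 'both' the cues are congruent unless a
    separate probe2 is given."""
    if condition == "cue1":
        return [CueStimulus(probe, alpha1, module=1)]
    if condition == "cue2":
        return [CueStimulus(probe, alpha2, module=2)]
    if condition == "both":
        x2 = probe if probe2 is None else probe2
        return [CueStimulus(probe, alpha1, module=1),
                CueStimulus(x2, alpha2, module=2)]
    raise ValueError(f"unknown condition {condition!r}; use one of {_CONDITIONS}")


def measure_tuning(p: NetworkParams, condition: str, probes,
                   alpha1: float, alpha2: float, duration: float = 100.0,
                   burn_in: float = 30.0, seed: Optional[int] = None,
                   probes2=None):
    """Simulate a probe sweep; return per-probe mean and SD rates for *all*
    neurons, shape (n_probes, 2, 2, n).

    One long equilibrium trial per probe, time-averaged — every neuron's
    tuning curve falls out of the same sweep.  ``probes2`` (same length)
    moves cue 2 independently for bimodal protocols.
    """
    probes = np.asarray(probes, dtype=float)
    mean = np.empty((probes.size, 2, 2, p.n))
    sd = np.empty_like(mean)
    base_seed = p.seed if seed is None else seed
    for i, probe in enumerate(probes):
        probe2 = None if probes2 is None else float(np.asarray(probes2)[i])
        cues = _cues_for(condition, float(probe), alpha1, alpha2, probe2)
        trace = simulate(cues, p, duration=duration, burn_in=burn_in,
                         seed=base_seed + 7919 * i)
        mean[i] = trace.r.mean(axis=0, dtype=np.float64)
        sd[i] = trace.r.std(axis=0, dtype=np.float64)
    return mean, sd


def tuning_curve(mean, sd, probes, module: int, ntype: str, index: int,
                 condition: str = "") -> TuningCurve:
    """Slice one neuron's curve out of a :func:`measure_tuning` sweep."""
    g = {"c": 0, "o": 1}[ntype]
    return TuningCurve(probes=np.asarray(probes, dtype=float),
                       mean_rate=mean[:, module - 1, g, index],
                       sd_rate=sd[:, module - 1, g, index],
                       neuron=(module, ntype, index), condition=condition)


def preferred_direction(curve: TuningCurve) -> float:
    """Preferred direction as the rate-weighted circular mean of the
    probes; raises for a flat curve (undefined direction)."""
    return float(population_vector(curve.mean_rate, curve.probes))


def preferred_directions(mean_rates: np.ndarray, probes) -> np.ndarray:
    """Vectorized preferred directions for every neuron in a sweep.

    ``mean_rates`` is (n_probes, 2, 2, n); returns (2, 2, n) angles in
    degrees (NaN where the curve is flat to numerical precision).
    """
    probes = np.asarray(probes, dtype=float)
    phase = np.exp(1j * np.radians(probes))
    z = np.tensordot(phase, mean_rates, axes=(0, 0))
    total = mean_rates.sum(axis=0)
    out = np.degrees(np.angle(z))
    out[np.abs(z) <= 1e-9 * np.maximum(total, 1e-9)] = np.nan
    return out


def pref_diff_histogram(p: NetworkParams, probes=None, alpha1: float = 0.35,
                        alpha2: float = 0.35, duration: float = 100.0,
                        burn_in: float = 30.0, seed: Optional[int] = None,
                        bins=None) -> pd.DataFrame:
    """Cross-cue preferred-direction differences of every neuron.

    Runs one probe sweep under each single cue and measures, per neuron,
    the absolute circular difference between its two preferred directions
    (0 for ideal congruent cells, 180 for ideal opposite cells, in between
    for intermediate cells created by reciprocal-connection jitter).
    Returns a tidy frame (module, type, index, pref_cue1, pref_cue2,
    diff).  Raw differences are always returned; binning is the caller's
    reporting choice.
    """
    if probes is None:
        probes = np.arange(-165.0, 181.0, 15.0)
    mean1, _ = measure_tuning(p, "cue1", probes, alpha1, alpha2,
                              duration=duration, burn_in=burn_in, seed=seed)
    mean2, _ = measure_tuning(p, "cue2", probes, alpha1, alpha2,
                              duration=duration, burn_in=burn_in,
                              seed=None if seed is None else seed + 1)
    pref1 = preferred_directions(mean1, probes)
    pref2 = preferred_directions(mean2, probes)
    rows = []
    for m in range(2):
        for g, ntype in enumerate("co"):
            for idx in range(p.n):
                d = abs(wrap_deg(pref1[m, g, idx] - pref2[m, g, idx]))
                rows.append({"module": m + 1, "type": ntype, "nidx": idx,
                             "pref_cue1": pref1[m, g, idx],
                             "pref_cue2": pref2[m, g, idx], "diff": d})
    return pd.DataFrame(rows)


def trial_rates(p: NetworkParams, cues, n_trials: int = 30,
                trial_len: float = 10.0, burn_in: float = 30.0,
                seed: Optional[int] = None) -> np.ndarray:
    """Per-trial time-averaged rates, shape (n_trials, 2, 2, n).

    Trials are contiguous equilibrium segments of one long run (the state
    is stationary after burn-in, so segments are exchangeable with
    independently seeded trials while paying the burn-in only once).
    """
    trace = simulate(cues, p, duration=n_trials * trial_len, burn_in=burn_in,
                     seed=seed)
    per_trial = trace.n_samples // n_trials
    r = trace.r[: per_trial * n_trials].astype(np.float64)
    return r.reshape(n_trials, per_trial, 2, 2, p.n).mean(axis=1)


def disparity_trials(p: NetworkParams, disparities, n_trials: int = 30,
                     alpha1: float = 0.25, alpha2: float = 0.8,
                     center: float = 0.0, trial_len: float = 10.0,
                     burn_in: float = 30.0, seed: Optional[int] = None,
                     neurons: Optional[Sequence[tuple]] = None,
                     ) -> pd.DataFrame:
    """Trial-rate table across cue disparities with fixed cue center.

    For each disparity d the cues are ``x1 = center + d/2`` and
    ``x2 = center - d/2`` (so x1 + x2 = 0 for the default center), both
    cues on.  Returns a tidy frame (disparity, trial, module, type, nidx,
    rate) for the selected neurons (default: the module-1 congruent and
    opposite neurons preferring 90 degrees w.r.t. cue 1).
    """
    disparities = np.asarray(disparities, dtype=float)
    if neurons is None:
        idx90 = int(np.argmin(np.abs(wrap_deg(p.theta_deg - 90.0))))
        neurons = [(1, "c", idx90), (1, "o", idx90)]
    gmap = {"c": 0, "o": 1}
    base_seed = p.seed if seed is None else seed
    rows = []
    for i, d in enumerate(disparities):
        cues = [CueStimulus(center + d / 2.0, alpha1, module=1),
                CueStimulus(center - d / 2.0, alpha2, module=2)]
        rates = trial_rates(p, cues, n_trials=n_trials, trial_len=trial_len,
                            burn_in=burn_in, seed=base_seed + 104729 * i)
        for trial in range(n_trials):
            for (m, ntype, idx) in neurons:
                rows.append({"disparity": d, "trial": trial, "module": m,
                             "type": ntype, "nidx": idx,
                             "rate": rates[trial, m - 1, gmap[ntype], idx]})
    return pd.DataFrame(rows)


def disparity_rate_curves(p: NetworkParams, disparities, alpha: float = 0.7,
                          duration: float = 100.0, burn_in: float = 30.0,
                          seed: Optional[int] = None, statistic: str = "peak",
                          ) -> pd.DataFrame:
    """Population rate of module-1 congruent/opposite groups vs disparity.

    Cues at ``+-d/2`` with equal intensity; the rate statistic is the peak
    of the temporally averaged population profile (``statistic='peak'``,
    the bump height, which encodes the concentration of the represented
    distribution) or the population mean (``'mean'``).  Congruent rates
    fall and opposite rates rise with disparity; their crossing is the
    integration-vs-segregation decision boundary.
    """
    if statistic not in ("peak", "mean"):
        raise ValueError("statistic must be 'peak' or 'mean'")
    disparities = np.asarray(disparities, dtype=float)
    base_seed = p.seed if seed is None else seed
    rows = []
    for i, d in enumerate(disparities):
        cues = [CueStimulus(d / 2.0, alpha, module=1),
                CueStimulus(-d / 2.0, alpha, module=2)]
        trace = simulate(cues, p, duration=duration, burn_in=burn_in,
                         seed=base_seed + 7919 * i)
        for g, ntype in enumerate("co"):
            profile = trace.r[:, 0, g, :].mean(axis=0, dtype=np.float64)
            value = profile.max() if statistic == "peak" else profile.mean()
            rows.append({"disparity": d, "type": ntype, "rate": value})
    return pd.DataFrame(rows)


def roc_fraction(dist_a, dist_b) -> float:
    """Area under the ROC of two empirical rate distributions.

    The probability that a random draw from ``dist_a`` exceeds one from
    ``dist_b``, ties counted half — the ideal observer's fraction of
    correct discriminations.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 trials per distribution")
    diff = a[:, None] - b[None, :]
    return float((np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0))
                 / diff.size)


def _cum_gauss(x, mu, sigma):
    return stats.norm.cdf((x - mu) / sigma)


def fit_neurometric(probes, fractions, sigma_bounds=(1e-6, 1e4),
                    ) -> NeurometricCurve:
    """Least-squares cumulative-Gaussian fit of a neurometric function.

    Fits ``Phi((x - mu) / sigma)`` with sigma > 0; the fitted sigma is the
    discrimination threshold.  Needs >= 4 points spanning both sides of
    0.5.  Degenerate data (all fractions equal) or a non-converging fit
    returns a flagged result with NaN sigma instead of raising.
    """
    x = np.asarray(probes, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if not (y.min() < 0.5 < y.max() or np.any(y == 0.5)):
        raise ValueError("fractions must span both sides of 0.5")
    if np.ptp(y) < 1e-9:
        return NeurometricCurve(x, y, mu=float("nan"), sigma=float("nan"),
                                converged=False)
    span = max(np.ptp(x), 1.0)
    starts = [(x[np.argmin(np.abs(y - 0.5))], span / 4.0),
              (0.0, span / 10.0), (0.0, span)]
    best = None
    for mu0, s0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _cum_gauss, x, y, p0=[mu0, s0],
                bounds=([-2 * span, sigma_bounds[0]], [2 * span, sigma_bounds[1]]),
                maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum((y - _cum_gauss(x, *popt)) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
        if resid < 1e-3:
            break
    if best is None:
        return NeurometricCurve(x, y, mu=float("nan"), sigma=float("nan"),
                                converged=False)
    (mu, sigma), resid = best
    return NeurometricCurve(x, y, mu=float(mu), sigma=float(sigma),
                            converged=True, residual=resid)


def neurometric_from_trials(table: pd.DataFrame, neuron: tuple,
                            pairing: str = "antisymmetric",
                            ) -> NeurometricCurve:
    """Build and fit the neurometric function of one neuron from a
    :func:`disparity_trials` table.

    ``pairing='antisymmetric'`` compares, at each probe d, the trial-rate
    distribution at +d against the one at -d (the cue-disparity task: was
    x1 > x2?).  ``pairing='reference'`` compares each probe against the
    distribution at probe 0 (the heading task against a 0-degree
    reference).  If the neuron's rate decreases with the probe the
    fractions are flipped (the ideal observer is free to read the
    anti-neuron).
    """
    m, ntype, idx = neuron
    sub = table[(table.module == m) & (table.type == ntype)
                & (table.nidx == idx)]
    by_d = {d: g.rate.to_numpy() for d, g in sub.groupby("disparity")}
    probes = np.array(sorted(by_d))
    fracs = []
    for d in probes:
        if pairing == "antisymmetric":
            other = by_d.get(-d)
            if other is None:
                raise ValueError(f"probe grid not symmetric: missing {-d}")
            fracs.append(0.5 if d == 0 else roc_fraction(by_d[d], other))
        elif pairing == "reference":
            ref = by_d.get(0.0)
            if ref is None:
                raise ValueError("reference pairing needs a probe at 0")
            fracs.append(0.5 if d == 0 else roc_fraction(by_d[d], ref))
        else:
            raise ValueError("pairing must be 'antisymmetric' or 'reference'")
    fracs = np.asarray(fracs)
    slope = np.polyfit(probes, fracs, 1)[0]
    if slope < 0:
        fracs = 1.0 - fracs
    return fit_neurometric(probes, fracs)


def predict_combined_threshold(sigma1: float, sigma2: float) -> float:
    """Optimal combined-cue threshold ``sigma1 sigma2 / sqrt(s1^2 + s2^2)``;
    never larger than the better single cue."""
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("thresholds must be > 0")
    return sigma1 * sigma2 / math.hypot(sigma1, sigma2)


def decision_boundary(disparities, rate_c, rate_o, w_cong: float = 1.0,
                      w_oppo: float = 1.0) -> float:
    """Disparity at which weighted congruent and opposite rates cross.

    Finds the zero of ``w_cong * r_c(d) - w_oppo * r_o(d)`` by linear
    interpolation on the sampled curves; ``r_c`` decreasing and ``r_o``
    increasing over (0, 180) guarantee a unique crossing, which moves
    right as ``w_cong / w_oppo`` grows.
    """
    d = np.asarray(disparities, dtype=float)
    f = w_cong * np.asarray(rate_c, dtype=float) - \
        w_oppo * np.asarray(rate_o, dtype=float)
    order = np.argsort(d)
    d, f = d[order], f[order]
    sign_change = np.nonzero(np.diff(np.signbit(f)))[0]
    if sign_change.size == 0:
        raise ValueError("curves do not cross on the sampled disparity range")
    i = int(sign_change[0])
    return float(d[i] + (d[i + 1] - d[i]) * f[i] / (f[i] - f[i + 1]))
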