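"""Decentralized two-module continuous attractor network.

Two reciprocally coupled modules (think MSTd and VIP) each hold two groups
of rate neurons — congruent and opposite — on a ring of preferred
directions theta in (-180, 180].  Within a group, neurons are recurrently
connected with a von Mises profile of width ``a``; across modules,
congruent groups are connected congruently and opposite groups with a 180
degree offset, which is what makes opposite tuning (and hence cue
disparity coding) emerge.  Firing rates follow divisive normalization
``r = [u]_+^2 / (1 + omega D)`` with inhibition pools partially shared
(``J_int``) between the two groups of a module.  Each module receives a
noisy feedforward drive for its own (direct) cue with multiplicative noise
of Fano factor ``F``; the cue noise is common to the congruent and
opposite group of a module while background noise is private per group.
Dynamics are integrated with the Euler–Maruyama scheme.

Discretization convention: the model equations are written with plain
sums over N = 180 neurons.  All population sums here carry a density
weight ``180 / N`` so that behaviour is invariant to the grid size; at the
default N = 180 the weight is exactly 1.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import special

from multicue.circstats import wrap_deg

__all__ = [
    "N_REF",
    "DEFAULT_J_C",
    "NetworkParams",
    "CueStimulus",
    "Epoch",
    "Kernels",
    "NetworkTrace",
    "SimulationDiverged",
    "u0_scale",
    "build_kernels",
    "feedforward_drive",
    "divisive_normalize",
    "step",
    "simulate",
    "estimate_critical_strength",
]

#: Reference grid density: the parameter values (omega, J's) are quoted for
#: a ring of 180 neurons per full circle.
N_REF = 180

#: Critical recurrent strength for a single module (both groups bumped, no
#: reciprocal input) to hold a persistent bump after the drive is removed,
#: at the default a=3, omega=3e-4, J_int=0.5.  Computed empirically with
#: :func:`estimate_critical_strength` (hold=400 tau); there is no usable
#: closed form.
DEFAULT_J_C = 0.01258

_TYPE_INDEX = {"c": 0, "o": 1}


class SimulationDiverged(RuntimeError):
    """Raised when the state stops being finite during integration."""


@dataclass(frozen=True)
class NetworkParams:
    """Structural and input constants of the two-module network.

    ``j_rc`` and ``j_rp`` are *relative*: the recurrent strength is
    ``j_rc * j_c`` and the reciprocal strength ``j_rp * j_rc * j_c``, so
    ``j_rp < 1`` keeps reciprocal weaker than recurrent coupling.  Cue
    intensities are given in units of :func:`u0_scale`.
    """

    n: int = 180                    # neurons per group
    a: float = 3.0                  # connection width (~40 deg tuning)
    omega: float = 3e-4             # divisive-normalization magnitude
    j_int: float = 0.5              # inhibition-pool sharing in (0, 1]
    j_rc: float = 0.3               # recurrent strength, fraction of j_c
    j_rp: float = 0.5               # reciprocal strength, fraction of j_rc
    j_c: float = DEFAULT_J_C        # critical recurrent strength
    i_b: float = 1.0                # background input mean
    fano: float = 0.5               # Fano factor of input noise
    tau: float = 1.0                # synaptic time constant
    dt: float = 0.01                # Euler step, in units of tau
    jitter: float = 0.0             # reciprocal jitter half-width g (0 = off)
    seed: int = 0                   # master RNG seed

    def __post_init__(self):
        if self.n < 8:
            raise ValueError("need n >= 8 neurons per group")
        if not (0 < self.dt <= 0.1 * self.tau):
            raise ValueError("require 0 < dt <= 0.1 tau")
        if self.a <= 0 or self.omega <= 0:
            raise ValueError("a and omega must be > 0")
        if not (0 < self.j_int <= 1):
            raise ValueError("j_int must lie in (0, 1]")
        if self.j_c <= 0:
            raise ValueError("j_c must be configured > 0")
        if not (0 <= self.j_rp < 1):
            raise ValueError("reciprocal strength must stay below recurrent "
                             "strength (0 <= j_rp < 1)")
        if self.jitter < 0 or self.fano < 0:
            raise ValueError("jitter and fano must be >= 0")

    # --- derived quantities -------------------------------------------------

    @property
    def theta_deg(self) -> np.ndarray:
        """Preferred directions: -180 + i*360/n for i = 1..n, i.e. (-180, 180]."""
        n = self.n
        return -180.0 + np.arange(1, n + 1) * (360.0 / n)

    @property
    def theta_rad(self) -> np.ndarray:
        return np.radians(self.theta_deg)

    @property
    def grid_weight(self) -> float:
        return N_REF / self.n

    @property
    def J_rc(self) -> float:
        """Absolute recurrent strength."""
        return self.j_rc * self.j_c

    @property
    def J_rp(self) -> float:
        """Absolute reciprocal strength."""
        return self.j_rp * self.J_rc

    @property
    def u0(self) -> float:
        return u0_scale(self)

    def rng_streams(self, seed: Optional[int] = None) -> dict:
        """Named, independent RNG streams from one master seed.

        Separate streams for the two cue-noise fields, the four background
        noises and the connection jitter, so toggling one noise source
        does not shift the draws of the others.
        """
        ss = np.random.SeedSequence(self.seed if seed is None else seed)
        names = ["cue1", "cue2", "bg_1c", "bg_1o", "bg_2c", "bg_2o", "jitter"]
        children = ss.spawn(len(names))
        return {name: np.random.default_rng(child)
                for name, child in zip(names, children)}


def u0_scale(p: NetworkParams) -> float:
    """Synaptic bump height a group can hold at the critical coupling.

    ``U0 = J_c e^{a/2} / [2 pi omega (1 + J_int) I0(a/2)]``; the natural
    unit for feedforward intensities alpha.
    """
    return p.j_c * math.exp(p.a / 2.0) / (
        2.0 * math.pi * p.omega * (1.0 + p.j_int) * special.i0(p.a / 2.0))


@dataclass(frozen=True)
class CueStimulus:
    """One cue: direction (deg), intensity alpha in units of U0, module."""

    direction: float
    alpha: float
    module: Literal[1, 2]
    on: bool = True

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.module not in (1, 2):
            raise ValueError("module must be 1 or 2")
        object.__setattr__(self, "direction", wrap_deg(self.direction))


@dataclass(frozen=True)
class Epoch:
    """A stretch of simulated time with a fixed set of cues."""

    duration: float
    cues: tuple = ()

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("epoch duration must be > 0")
        object.__setattr__(self, "cues", tuple(self.cues))


@dataclass(frozen=True)
class Kernels:
    """Connection matrices.

    ``w_rc`` is the within-group recurrent kernel (shared by all four
    groups).  ``w_rp_c[d]`` / ``w_rp_o[d]`` are the reciprocal kernels for
    congruent / opposite groups, with d = 0 the projection into module 1
    (from module 2) and d = 1 the reverse; the opposite kernel is the
    congruent one with the source ring rotated by 180 degrees.  Jitter, if
    enabled, perturbs each reciprocal entry multiplicatively.
    """

    w_rc: np.ndarray
    w_rp_c: np.ndarray   # shape (2, n, n)
    w_rp_o: np.ndarray   # shape (2, n, n)


def _profile(p: NetworkParams) -> np.ndarray:
    """Von Mises connection profile exp[a cos(dtheta)] / (2 pi I0(a)),
    times the grid-density weight."""
    th = p.theta_rad
    dtheta = th[:, None] - th[None, :]
    return (np.exp(p.a * np.cos(dtheta)) / (2.0 * math.pi * special.i0(p.a))
            * p.grid_weight)


def build_kernels(p: NetworkParams, rng: Optional[np.random.Generator] = None,
                  ) -> Kernels:
    """Construct recurrent and reciprocal connection matrices.

    With jitter off the matrices are circulant; with jitter ``g > 0`` every
    reciprocal connection receives an independent *additive* random
    component ``eta ~ Uniform(-g, g)`` times the kernel's peak value
    (clipped at zero), drawn from the dedicated jitter stream.  An additive
    component is what creates intermediate-tuned neurons: it can relocate
    the peak of a neuron's reciprocal input profile, whereas perturbations
    proportional to the profile itself leave the peak in place and average
    out under the activity bump.
    """
    base = _profile(p)
    w_rc = p.J_rc * base
    w_rp_c = np.broadcast_to(p.J_rp * base, (2, p.n, p.n)).copy()
    # opposite kernel: source preferred direction shifted by 180 deg
    shift = p.n // 2 if p.n % 2 == 0 else None
    if shift is not None:
        w_rp_o_base = np.roll(p.J_rp * base, shift, axis=1)
    else:
        th = p.theta_rad
        dtheta = th[:, None] - th[None, :] + math.pi
        w_rp_o_base = (p.J_rp * np.exp(p.a * np.cos(dtheta))
                       / (2.0 * math.pi * special.i0(p.a)) * p.grid_weight)
    w_rp_o = np.broadcast_to(w_rp_o_base, (2, p.n, p.n)).copy()
    if p.jitter > 0:
        if rng is None:
            rng = p.rng_streams()["jitter"]
        peak = p.J_rp * math.exp(p.a) / (2.0 * math.pi * special.i0(p.a)) \
            * p.grid_weight
        for w in (w_rp_c, w_rp_o):
            eta = rng.uniform(-p.jitter, p.jitter, size=w.shape)
            np.clip(w + peak * eta, 0.0, None, out=w)
    return Kernels(w_rc=w_rc, w_rp_c=w_rp_c, w_rp_o=w_rp_o)


def _mean_cue_profile(stim: CueStimulus, p: NetworkParams) -> np.ndarray:
    """Noise-free cue drive alpha * exp[a (cos(theta - x) - 1) / 2]."""
    if not stim.on or stim.alpha == 0.0:
        return np.zeros(p.n)
    delta = p.theta_rad - math.radians(stim.direction)
    return stim.alpha * p.u0 * np.exp(p.a * (np.cos(delta) - 1.0) / 2.0)


def feedforward_drive(stim: Optional[CueStimulus], p: NetworkParams,
                      rng: np.random.Generator, n_steps: int,
                      rng_bg: Optional[np.random.Generator] = None,
                      ) -> np.ndarray:
    """Sample the feedforward input of one neuron group for ``n_steps``.

    Returns an ``(n_steps, n)`` array: cue profile plus background mean
    plus multiplicative noise.  Noise standard deviation per Euler step is
    ``sqrt(F * mean / dt)`` so that the input integrated over time has
    variance-to-mean ratio F (delta-correlated noise under the
    Euler–Maruyama convention).  ``rng`` drives the cue-associated noise
    (shared between the congruent and opposite group of a module);
    ``rng_bg`` the group-private background noise (defaults to ``rng``).
    """
    if rng_bg is None:
        rng_bg = rng
    mean_cue = (_mean_cue_profile(stim, p) if stim is not None
                else np.zeros(p.n))
    sd_cue = np.sqrt(p.fano * mean_cue / p.dt)
    sd_bg = math.sqrt(p.fano * p.i_b / p.dt)
    out = np.empty((n_steps, p.n))
    for t in range(n_steps):
        out[t] = (mean_cue + sd_cue * rng.standard_normal(p.n)
                  + p.i_b + sd_bg * rng_bg.standard_normal(p.n))
    return out


def divisive_normalize(u: np.ndarray, p: NetworkParams):
    """Firing rates ``r = [u]_+^2 / (1 + omega D)`` and pool activities D.

    ``u`` has shape (2, 2, n) — (module, type, neuron).  The pool of each
    group sums its own rectified-squared input plus ``j_int`` times the
    other group's, coupling congruent and opposite neurons competitively.
    """
    up2 = np.square(np.clip(u, 0.0, None))
    own = up2.sum(axis=-1) * p.grid_weight          # (2, 2)
    d = own + p.j_int * own[:, ::-1]
    r = up2 / (1.0 + p.omega * d[..., None])
    return r, d


def _recurrent_input(r: np.ndarray, k: Kernels) -> np.ndarray:
    """Recurrent plus reciprocal drive for all four groups."""
    rec = r @ k.w_rc.T                                   # (2, 2, n)
    rec[0, 0] += k.w_rp_c[0] @ r[1, 0]
    rec[1, 0] += k.w_rp_c[1] @ r[0, 0]
    rec[0, 1] += k.w_rp_o[0] @ r[1, 1]
    rec[1, 1] += k.w_rp_o[1] @ r[0, 1]
    return rec


def step(u: np.ndarray, kernels: Kernels, drive: np.ndarray,
         p: NetworkParams) -> np.ndarray:
    """One Euler update of the synaptic inputs.

    ``tau du/dt = -u + W_rc r + W_rp r_other + I`` with ``drive`` the full
    feedforward input (noise included) of shape (2, 2, n).  Congruent
    groups couple through the congruent reciprocal kernel, opposite groups
    through the offset one; there is no cross-type reciprocal coupling.
    """
    r, _ = divisive_normalize(u, p)
    du = (-u + _recurrent_input(r, kernels) + drive) * (p.dt / p.tau)
    u_new = u + du
    if not np.all(np.isfinite(u_new)):
        raise SimulationDiverged(
            "non-finite synaptic input; reduce dt or connection strengths")
    return u_new


@dataclass
class NetworkTrace:
    """Sampled time series of one simulation.

    ``r`` (and optionally ``u``) have shape (samples, 2, 2, n) in float32;
    indices are (module, type) with type 0 = congruent, 1 = opposite.
    ``meta`` carries everything needed to reproduce the run bit for bit.
    """

    times: np.ndarray
    r: np.ndarray
    u: Optional[np.ndarray]
    params: NetworkParams
    epochs: tuple
    stride: int
    seed: int

    @property
    def n_samples(self) -> int:
        return self.r.shape[0]

    def rates(self, module: int, ntype: str) -> np.ndarray:
        """Rate series (samples, n) of one group; ntype 'c' or 'o'."""
        return self.r[:, module - 1, _TYPE_INDEX[ntype], :]

    def mean_rates(self, module: int, ntype: str) -> np.ndarray:
        return self.rates(module, ntype).mean(axis=0, dtype=np.float64)

    def synaptic(self, module: int, ntype: str) -> np.ndarray:
        if self.u is None:
            raise ValueError("synaptic inputs were not recorded")
        return self.u[:, module - 1, _TYPE_INDEX[ntype], :]


def _epoch_drives(cues: Sequence[CueStimulus], p: NetworkParams):
    """Precompute per-module mean cue profiles and noise SDs for an epoch."""
    mean_cue = np.zeros((2, p.n))
    for stim in cues:
        if stim.on:
            mean_cue[stim.module - 1] += _mean_cue_profile(stim, p)
    sd_cue = np.sqrt(p.fano * mean_cue / p.dt)
    sd_bg = math.sqrt(p.fano * p.i_b / p.dt)
    return mean_cue, sd_cue, sd_bg


def simulate(epochs: Sequence[Epoch] | Sequence[CueStimulus], p: NetworkParams,
             duration: Optional[float] = None, burn_in: float = 50.0,
             stride: int = 1, record_u: bool = False,
             seed: Optional[int] = None, kernels: Optional[Kernels] = None,
             ) -> NetworkTrace:
    """Integrate the network and return post-burn-in samples.

    ``epochs`` is either a list of :class:`Epoch` or, together with
    ``duration``, a bare list of :class:`CueStimulus` for a single
    constant condition.  The burn-in (default 50 tau, long enough to reach
    the stochastic equilibrium) runs under the first epoch's cues and is
    discarded.  Identical seeds give identical traces.
    """
    if duration is not None:
        epochs = [Epoch(duration=duration, cues=tuple(epochs))]
    epochs = [e if isinstance(e, Epoch) else Epoch(**e) for e in epochs]
    if not epochs:
        raise ValueError("need at least one epoch")
    streams = p.rng_streams(seed)
    if kernels is None:
        kernels = build_kernels(p, rng=streams["jitter"])
    rng_cue = (streams["cue1"], streams["cue2"])
    rng_bg = ((streams["bg_1c"], streams["bg_1o"]),
              (streams["bg_2c"], streams["bg_2o"]))

    n_samp = sum((int(round(e.duration / p.dt)) + stride - 1) // stride
                 for e in epochs)
    r_out = np.empty((n_samp, 2, 2, p.n), dtype=np.float32)
    u_out = np.empty_like(r_out) if record_u else None
    times = np.empty(n_samp)

    u = np.zeros((2, 2, p.n))
    isamp = 0
    t0 = 0.0
    w_rc_t = np.ascontiguousarray(kernels.w_rc.T)
    k = kernels
    dtau = p.dt / p.tau
    chunk = 512  # noise drawn in fixed-size blocks (order is deterministic)

    def _advance(u, n_steps, mean_cue, sd_cue, sd_bg, record, t_start):
        nonlocal isamp
        done = 0
        while done < n_steps:
            nsub = min(chunk, n_steps - done)
            drive = np.empty((nsub, 2, 2, p.n))
            for m in range(2):
                xi = rng_cue[m].standard_normal((nsub, p.n))
                cue_part = mean_cue[m] + sd_cue[m] * xi
                for g in range(2):
                    eps = rng_bg[m][g].standard_normal((nsub, p.n))
                    drive[:, m, g] = cue_part + p.i_b + sd_bg * eps
            for i in range(nsub):
                up2 = np.square(np.clip(u, 0.0, None))
                own = up2.sum(axis=-1) * p.grid_weight
                d = own + p.j_int * own[:, ::-1]
                r = up2 / (1.0 + p.omega * d[..., None])
                rec = r @ w_rc_t
                rec[0, 0] += k.w_rp_c[0] @ r[1, 0]
                rec[1, 0] += k.w_rp_c[1] @ r[0, 0]
                rec[0, 1] += k.w_rp_o[0] @ r[1, 1]
                rec[1, 1] += k.w_rp_o[1] @ r[0, 1]
                u = u + dtau * (drive[i] + rec - u)
                j = done + i
                if record and j % stride == 0:
                    if not np.all(np.isfinite(u)):
                        raise SimulationDiverged(
                            "non-finite synaptic input; reduce dt or "
                            "connection strengths")
                    r_out[isamp], _ = divisive_normalize(u, p)
                    if u_out is not None:
                        u_out[isamp] = u
                    times[isamp] = t_start + (j + 1) * p.dt
                    isamp += 1
            done += nsub
        if not np.all(np.isfinite(u)):
            raise SimulationDiverged(
                "non-finite synaptic input; reduce dt or connection strengths")
        return u

    # burn-in under the first epoch's cues, discarded
    if burn_in > 0:
        mean_cue, sd_cue, sd_bg = _epoch_drives(epochs[0].cues, p)
        u = _advance(u, int(round(burn_in / p.dt)), mean_cue, sd_cue, sd_bg,
                     record=False, t_start=-burn_in)
    for e in epochs:
        mean_cue, sd_cue, sd_bg = _epoch_drives(e.cues, p)
        u = _advance(u, int(round(e.duration / p.dt)), mean_cue, sd_cue,
                     sd_bg, record=True, t_start=t0)
        t0 += e.duration
    assert isamp == n_samp, (isamp, n_samp)
    return NetworkTrace(times=times, r=r_out, u=u_out, params=p,
                        epochs=tuple(epochs), stride=stride,
                        seed=p.seed if seed is None else seed)


def estimate_critical_strength(p: NetworkParams, lo: float = 1e-4,
                               hi: float = 0.2, tol: float = 1e-4,
                               warm: float = 20.0, hold: float = 200.0,
                               ) -> float:
    """Empirical critical recurrent strength J_c, by bisection.

    Simulates a single noise-free module (reciprocal coupling off, both
    groups driven by the same cue so the shared inhibition pool is fully
    engaged) with absolute recurrent strength J, removes the drive, and
    asks whether the bump survives ``hold`` time constants.  The smallest
    persistent J, found by bisection to ``tol``, is the critical strength
    against which ``j_rc`` is expressed.
    """

    def persists(j_abs: float) -> bool:
        q = dataclasses.replace(p, j_c=j_abs, j_rc=1.0, j_rp=0.0, fano=0.0,
                                jitter=0.0)
        kernels = build_kernels(q)
        u = np.zeros((2, 2, q.n))
        # probe drive in absolute units (not U0, which depends on j_c)
        profile = 10.0 * np.exp(q.a * (np.cos(q.theta_rad) - 1.0) / 2.0)
        drive = np.empty((2, 2, q.n))
        n_warm = int(round(warm / q.dt))
        n_hold = int(round(hold / q.dt))
        drive[:] = profile + q.i_b
        for _ in range(n_warm):
            u = step(u, kernels, drive, q)
        drive[:] = q.i_b
        for _ in range(n_hold):
            u = step(u, kernels, drive, q)
        modulation = float(u[0, 0].max() - u[0, 0].min())
        return modulation > 1.0

    if persists(lo):
        raise ValueError("lower bracket already persistent; decrease lo")
    if not persists(hi):
        raise ValueError("upper bracket not persistent; increase hi")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if persists(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
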