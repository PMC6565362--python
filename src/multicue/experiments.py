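"""Experiment presets, configuration handling and result bundles.

Each preset reproduces one of the model's standard protocols (Bayesian
sweep curves, tuning curves, optimality sweeps, decision boundary,
single-cue recovery, ROC discrimination) end to end and returns tidy
DataFrames; :func:`run` wraps a preset into an on-disk bundle with the
echoed configuration, a log and a parameter hash so every run can be
reproduced exactly.  :func:`fixture` returns reduced-size seeded configs
for fast tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd
import yaml

from multicue import bayes, decode, neurometrics as nm
from multicue.bayes import CuePair
from multicue.circstats import wrap_deg
from multicue.netsim import CueStimulus, NetworkParams, simulate, u0_scale

__all__ = ["ExperimentConfig", "PRESETS", "make_config", "fixture", "run",
           "load_config", "single_cue_estimates", "combined_estimates",
           "optimality_sweep", "recovery_sweep"]

log = logging.getLogger("multicue")


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass
class ExperimentConfig:
    """A fully resolved experiment: preset, network params, protocol, seed."""

    preset: str
    seed: int = 0
    outdir: Optional[str] = None
    network: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}; "
                              f"choose from {sorted(PRESETS)}")
        try:
            self.params  # validates network overrides
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from e
        spec = PRESETS[self.preset]
        unknown = set(self.protocol) - set(spec.defaults)
        if unknown:
            raise ConfigError(f"unknown protocol keys {sorted(unknown)}; "
                              f"allowed: {sorted(spec.defaults)}")

    @property
    def params(self) -> NetworkParams:
        allowed = {f.name for f in dataclasses.fields(NetworkParams)}
        unknown = set(self.network) - allowed
        if unknown:
            raise ConfigError(f"unknown network keys {sorted(unknown)}")
        return NetworkParams(**{**self.network, "seed": self.seed})

    @property
    def proto(self) -> dict:
        return {**PRESETS[self.preset].defaults, **self.protocol}

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, (tuple, list, np.ndarray)):
                return [plain(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {"preset": self.preset, "seed": self.seed,
                "outdir": self.outdir,
                "network": {k: plain(v) for k, v in self.network.items()},
                "protocol": {k: plain(v) for k, v in self.protocol.items()}}


# --------------------------------------------------------------------------
# shared simulation helpers (used by presets, tests and the acceptance script)

def _decoded(trace, module: int, ntype: str) -> decode.PopulationEstimate:
    z = decode.population_vector(trace.rates(module, ntype),
                                 trace.params.theta_deg)
    return decode.estimate_distribution(z, source=(module, ntype))


def single_cue_estimates(p: NetworkParams, cue: CueStimulus, duration: float,
                         burn_in: float, seed: int) -> dict:
    """Decoded estimates of all four groups under one cue."""
    tr = simulate([cue], p, duration=duration, burn_in=burn_in, seed=seed)
    return {(m, nt): _decoded(tr, m, nt) for m in (1, 2) for nt in "co"}


def combined_estimates(p: NetworkParams, cue1: CueStimulus,
                       cue2: CueStimulus, duration: float, burn_in: float,
                       seed: int) -> dict:
    tr = simulate([cue1, cue2], p, duration=duration, burn_in=burn_in,
                  seed=seed)
    return {(m, nt): _decoded(tr, m, nt) for m in (1, 2) for nt in "co"}


def optimality_condition(p: NetworkParams, x1: float, x2: float,
                         alpha1: float, alpha2: float, duration: float,
                         burn_in: float, seed: int) -> dict:
    """One optimality-test condition: single-cue runs, a combined run,
    decoded module-1 estimates and the vector-algebra predictions."""
    e1 = single_cue_estimates(p, CueStimulus(x1, alpha1, module=1),
                              duration, burn_in, seed)
    e2 = single_cue_estimates(p, CueStimulus(x2, alpha2, module=2),
                              duration, burn_in, seed + 1)
    eb = combined_estimates(p, CueStimulus(x1, alpha1, module=1),
                            CueStimulus(x2, alpha2, module=2),
                            duration, burn_in, seed + 2)
    pred_c = decode.predict_integration(e1[(1, "c")], e2[(1, "c")])
    pred_o = decode.predict_disparity(e1[(1, "o")], e2[(1, "o")])
    pred_o_alt = decode.predict_disparity_from_congruent(e1[(1, "c")],
                                                         e2[(1, "c")])
    return {"obs_c": eb[(1, "c")], "obs_o": eb[(1, "o")], "pred_c": pred_c,
            "pred_o": pred_o, "pred_o_alt": pred_o_alt,
            "single_1": e1, "single_2": e2}


def optimality_sweep(p: NetworkParams, proto: dict, seed: int) -> pd.DataFrame:
    """Sweep cue intensity, disparity and reciprocal strength; tabulate
    decoded combined-cue estimates against the optimality predictions."""
    rows = []
    base = dict(x1=proto["x1"], x2=proto["x2"], alpha1=proto["alpha1"],
                alpha2=proto["alpha2"])
    conditions = [("alpha1", v) for v in proto["alpha_grid"]]
    conditions += [("x2", v) for v in proto["x2_grid"]]
    conditions += [("j_rp", v) for v in proto["jrp_grid"]]
    for i, (name, value) in enumerate(conditions):
        cond = dict(base)
        q = p
        if name == "j_rp":
            q = dataclasses.replace(p, j_rp=value)
        else:
            cond[name] = value
        res = optimality_condition(q, cond["x1"], cond["x2"], cond["alpha1"],
                                   cond["alpha2"], proto["duration"],
                                   proto["burn_in"], seed + 1000 * i)
        for nt, obs, pred in (("c", res["obs_c"], res["pred_c"]),
                              ("o", res["obs_o"], res["pred_o"])):
            rows.append({
                "sweep": name, "value": value, "type": nt,
                "obs_mean": obs.mean, "obs_kappa": obs.kappa,
                "obs_se": obs.mean_se,
                "pred_mean": pred.mean, "pred_kappa": pred.kappa,
                "pred_se": pred.mean_se,
                "mean_err": wrap_deg(obs.mean - pred.mean),
                "kappa_ratio": obs.kappa / pred.kappa,
                "n_samples": obs.n_samples, "seed": seed + 1000 * i,
            })
    return pd.DataFrame(rows)


def recovery_sweep(p: NetworkParams, proto: dict, seed: int) -> pd.DataFrame:
    """Recover the direct-cue estimate from joint congruent/opposite
    activity under combined cues, across random parameter configurations,
    and compare with the direct-cue-only decoded mean."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(proto["n_configs"]):
        alpha1 = rng.uniform(*proto["alpha_range"])
        alpha2 = rng.uniform(*proto["alpha_range"])
        j_rp = rng.uniform(*proto["jrp_range"])
        x1 = rng.uniform(-180.0, 180.0)
        disparity = rng.uniform(-proto["max_disparity"],
                                proto["max_disparity"])
        q = dataclasses.replace(p, j_rp=j_rp)
        run_seed = seed + 1000 * i
        trb = simulate([CueStimulus(x1, alpha1, module=1),
                        CueStimulus(x1 + disparity, alpha2, module=2)],
                       q, duration=proto["duration"],
                       burn_in=proto["burn_in"], seed=run_seed)
        s1 = decode.recover_direct_cue(trb.rates(1, "c"), trb.rates(1, "o"),
                                       q.theta_deg)
        from multicue.circstats import circ_estimate
        recovered = circ_estimate(s1[np.isfinite(s1)])
        tr1 = simulate([CueStimulus(x1, alpha1, module=1)], q,
                       duration=proto["duration"], burn_in=proto["burn_in"],
                       seed=run_seed + 1)
        direct = _decoded(tr1, 1, "c")
        rows.append({"config": i, "alpha1": alpha1, "alpha2": alpha2,
                     "j_rp": j_rp, "x1": x1, "disparity": disparity,
                     "recovered_mean": recovered.mu,
                     "direct_mean": direct.mean, "seed": run_seed})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# preset implementations

def _preset_bayes_curves(p, proto, seed):
    """Integrated/disparity mean and concentration as the probabilistic
    model's parameters vary (reliability, disparity, prior)."""
    x1, x2, kappa = proto["x1"], proto["x2"], proto["kappa"]
    rows = []
    for k in proto["kappa_grid"]:
        c = CuePair(x1, x2, k, k, kappa)
        rows.append(("kappa12", k, c))
    for x in proto["x2_grid"]:
        rows.append(("x2", x, CuePair(x1, x, kappa, kappa, kappa)))
    for ks in proto["kappa_s_grid"]:
        rows.append(("kappa_s", ks, CuePair(x1, x2, kappa, kappa, ks)))
    out = []
    for sweep, value, c in rows:
        integ = bayes.posterior_integrated(c)
        disp = bayes.posterior_disparity(c)
        out.append({"sweep": sweep, "value": value,
                    "int_mean": integ.mu, "int_kappa": integ.kappa,
                    "disp_mean": disp.mu, "disp_kappa": disp.kappa,
                    "loss": bayes.info_loss_fraction(
                        max(c.kappa1, 1e-12), max(c.kappa2, 1e-12),
                        max(c.kappa_s, 1e-12))})
    return {"curves": pd.DataFrame(out)}


def _preset_tuning(p, proto, seed):
    """Tuning curves of example module-1 congruent/opposite neurons under
    the three cueing conditions."""
    probes = np.asarray(proto["probes"], dtype=float)
    idx = int(np.argmin(np.abs(wrap_deg(p.theta_deg - proto["example_pref"]))))
    frames = []
    for cond in ("cue1", "cue2", "both"):
        mean, sd = nm.measure_tuning(
            p, cond, probes, proto["alpha1"], proto["alpha2"],
            duration=proto["duration"], burn_in=proto["burn_in"], seed=seed)
        for nt in "co":
            c = nm.tuning_curve(mean, sd, probes, 1, nt, idx, condition=cond)
            frames.append(pd.DataFrame({
                "condition": cond, "type": nt, "probe": probes,
                "rate": c.mean_rate, "sd": c.sd_rate}))
    return {"tuning_curves": pd.concat(frames, ignore_index=True)}


def _preset_bimodal_tuning(p, proto, seed):
    """Joint tuning over (x1, x2) combinations for the example neurons."""
    grid = np.asarray(proto["grid"], dtype=float)
    idx = int(np.argmin(np.abs(wrap_deg(p.theta_deg - proto["example_pref"]))))
    x1g, x2g = np.meshgrid(grid, grid, indexing="ij")
    mean, sd = nm.measure_tuning(
        p, "both", x1g.ravel(), proto["alpha1"], proto["alpha2"],
        duration=proto["duration"], burn_in=proto["burn_in"], seed=seed,
        probes2=x2g.ravel())
    rows = []
    for k, (x1, x2) in enumerate(zip(x1g.ravel(), x2g.ravel())):
        for g, nt in enumerate("co"):
            rows.append({"x1": x1, "x2": x2, "type": nt,
                         "rate": mean[k, 0, g, idx]})
    return {"bimodal": pd.DataFrame(rows)}


def _preset_intermediate_hist(p, proto, seed):
    """Preferred-direction differences with jittered reciprocal connections."""
    q = dataclasses.replace(p, jitter=proto["jitter"])
    df = nm.pref_diff_histogram(
        q, probes=np.asarray(proto["probes"], dtype=float),
        alpha1=proto["alpha1"], alpha2=proto["alpha2"],
        duration=proto["duration"], burn_in=proto["burn_in"], seed=seed)
    return {"pref_diffs": df}


def _preset_optimality(p, proto, seed):
    return {"optimality": optimality_sweep(p, proto, seed)}


def _preset_decision(p, proto, seed):
    """Congruent/opposite rate-vs-disparity curves and decision boundaries."""
    disparities = np.asarray(proto["disparities"], dtype=float)
    curves = nm.disparity_rate_curves(
        p, disparities, alpha=proto["alpha"], duration=proto["duration"],
        burn_in=proto["burn_in"], seed=seed, statistic=proto["statistic"])
    rc = curves[curves.type == "c"].sort_values("disparity").rate.to_numpy()
    ro = curves[curves.type == "o"].sort_values("disparity").rate.to_numpy()
    d = np.sort(disparities)
    rows = []
    for w in proto["weight_ratios"]:
        rows.append({"w_cong_over_w_oppo": w,
                     "boundary": nm.decision_boundary(d, rc, ro, w_cong=w)})
    return {"rate_curves": curves, "boundaries": pd.DataFrame(rows)}


def _preset_recovery(p, proto, seed):
    df = recovery_sweep(p, proto, seed)
    r2 = decode.recovery_r2(df.recovered_mean.to_numpy(),
                            df.direct_mean.to_numpy())
    return {"recovery": df,
            "recovery_r2": pd.DataFrame([{"r2": r2, "n_configs": len(df)}])}


def _preset_disparity_roc(p, proto, seed):
    """Cue-disparity discrimination: trial rates, neurometric fits and
    thresholds of the example congruent and opposite neuron."""
    disparities = np.asarray(proto["disparities"], dtype=float)
    idx = int(np.argmin(np.abs(wrap_deg(p.theta_deg - proto["example_pref"]))))
    neurons = [(1, "c", idx), (1, "o", idx)]
    table = nm.disparity_trials(
        p, disparities, n_trials=proto["n_trials"], alpha1=proto["alpha1"],
        alpha2=proto["alpha2"], trial_len=proto["trial_len"],
        burn_in=proto["burn_in"], seed=seed, neurons=neurons)
    rows, points = [], []
    for neuron in neurons:
        curve = nm.neurometric_from_trials(table, neuron)
        rows.append({"type": neuron[1], "nidx": neuron[2],
                     "threshold": curve.threshold, "mu": curve.mu,
                     "converged": curve.converged})
        points.append(pd.DataFrame({"type": neuron[1],
                                    "disparity": curve.probes,
                                    "fraction": curve.fractions}))
    return {"trial_rates": table,
            "neurometric_points": pd.concat(points, ignore_index=True),
            "thresholds": pd.DataFrame(rows)}


def _preset_heading_roc(p, proto, seed):
    """Heading discrimination: both cues at the same direction, swept
    around 0; thresholds per cueing condition plus the optimal combined
    prediction."""
    headings = np.asarray(proto["headings"], dtype=float)
    idx = int(np.argmin(np.abs(wrap_deg(p.theta_deg - proto["example_pref"]))))
    neuron = (1, proto["neuron_type"], idx)
    gmap = {"c": 0, "o": 1}
    rows = []
    thresholds = {}
    for ci, cond in enumerate(("cue1", "cue2", "both")):
        by_h = {}
        for i, h in enumerate(headings):
            cues = nm._cues_for(cond, float(h), proto["alpha1"],
                                proto["alpha2"])
            rates = nm.trial_rates(p, cues, n_trials=proto["n_trials"],
                                   trial_len=proto["trial_len"],
                                   burn_in=proto["burn_in"],
                                   seed=seed + 104729 * i + 31 * ci)
            by_h[float(h)] = rates[:, 0, gmap[neuron[1]], idx]
        ref = by_h[0.0]
        fracs = np.array([0.5 if h == 0 else nm.roc_fraction(by_h[h], ref)
                          for h in headings])
        if np.polyfit(headings, fracs, 1)[0] < 0:
            fracs = 1.0 - fracs
        curve = nm.fit_neurometric(headings, fracs)
        thresholds[cond] = curve.threshold
        for h, f in zip(headings, fracs):
            rows.append({"condition": cond, "heading": h, "fraction": f})
    pred = nm.predict_combined_threshold(thresholds["cue1"],
                                         thresholds["cue2"])
    thr = pd.DataFrame([
        {"condition": "cue1", "threshold": thresholds["cue1"]},
        {"condition": "cue2", "threshold": thresholds["cue2"]},
        {"condition": "both", "threshold": thresholds["both"]},
        {"condition": "prediction", "threshold": pred}])
    return {"neurometric_points": pd.DataFrame(rows), "thresholds": thr}


@dataclass(frozen=True)
class _Preset:
    fn: Callable
    defaults: dict
    doc: str


PRESETS: Dict[str, _Preset] = {
    "bayes_curves": _Preset(_preset_bayes_curves, dict(
        x1=0.0, x2=20.0, kappa=50.0,
        kappa_grid=tuple(np.geomspace(1, 200, 25)),
        x2_grid=tuple(np.arange(0.0, 181.0, 7.5)),
        kappa_s_grid=tuple(np.geomspace(1, 200, 25))),
        "Probabilistic-model sweep curves (integration and disparity)."),
    "tuning": _Preset(_preset_tuning, dict(
        probes=tuple(np.arange(-165.0, 181.0, 15.0)), example_pref=-90.0,
        alpha1=0.35, alpha2=0.8, duration=100.0, burn_in=30.0),
        "Unimodal tuning curves of example congruent/opposite neurons."),
    "bimodal_tuning": _Preset(_preset_bimodal_tuning, dict(
        grid=tuple(np.arange(-180.0, 180.0, 30.0)), example_pref=-90.0,
        alpha1=0.87, alpha2=1.5, duration=60.0, burn_in=30.0),
        "Joint (x1, x2) tuning of the example neurons."),
    "intermediate_hist": _Preset(_preset_intermediate_hist, dict(
        probes=tuple(np.arange(-165.0, 181.0, 15.0)), jitter=0.9,
        alpha1=0.35, alpha2=0.35, duration=60.0, burn_in=30.0),
        "Preferred-direction difference histogram with jittered "
        "reciprocal connections."),
    "optimality_sweep": _Preset(_preset_optimality, dict(
        x1=0.0, x2=20.0, alpha1=0.7, alpha2=0.7,
        alpha_grid=(0.4, 0.7, 1.0, 1.3), x2_grid=(40.0, 90.0, 160.0),
        jrp_grid=(0.2, 0.35, 0.5), duration=400.0, burn_in=40.0),
        "Decoded combined-cue estimates vs optimal-integration/segregation "
        "predictions across parameter sweeps."),
    "decision": _Preset(_preset_decision, dict(
        disparities=tuple(np.arange(10.0, 171.0, 10.0)), alpha=0.7,
        duration=100.0, burn_in=30.0, statistic="peak",
        weight_ratios=(0.5, 1.0, 2.0)),
        "Integration-vs-segregation decision boundary from the congruent/"
        "opposite rate crossing."),
    "recovery": _Preset(_preset_recovery, dict(
        n_configs=32, alpha_range=(0.3, 1.5), jrp_range=(0.1, 0.9),
        max_disparity=160.0, duration=100.0, burn_in=30.0),
        "Recover the direct-cue estimate from joint congruent/opposite "
        "activity across random configurations."),
    "disparity_roc": _Preset(_preset_disparity_roc, dict(
        disparities=tuple(np.arange(-32.0, 33.0, 4.0)), example_pref=90.0,
        alpha1=0.25, alpha2=0.8, n_trials=30, trial_len=10.0, burn_in=30.0),
        "Cue-disparity discrimination thresholds (ROC) of example "
        "congruent and opposite neurons."),
    "heading_roc": _Preset(_preset_heading_roc, dict(
        headings=tuple(np.arange(-32.0, 33.0, 8.0)), example_pref=90.0,
        neuron_type="c", alpha1=0.25, alpha2=0.8, n_trials=30,
        trial_len=10.0, burn_in=30.0),
        "Heading discrimination thresholds under three cueing conditions "
        "plus the optimal combined prediction."),
}

_FIXTURE_OVERRIDES = {
    "bayes_curves": dict(protocol=dict(
        kappa_grid=(5.0, 20.0, 50.0), x2_grid=(0.0, 45.0, 90.0, 135.0, 180.0),
        kappa_s_grid=(5.0, 20.0, 50.0))),
    "tuning": dict(network=dict(n=36, dt=0.05), protocol=dict(
        probes=tuple(np.arange(-150.0, 181.0, 30.0)), duration=30.0,
        burn_in=15.0)),
    "bimodal_tuning": dict(network=dict(n=36, dt=0.05), protocol=dict(
        grid=(-120.0, -60.0, 0.0, 60.0, 120.0, 180.0), duration=20.0,
        burn_in=10.0)),
    "intermediate_hist": dict(network=dict(n=36, dt=0.05), protocol=dict(
        probes=tuple(np.arange(-150.0, 181.0, 30.0)), duration=20.0,
        burn_in=10.0)),
    "optimality_sweep": dict(network=dict(n=36, dt=0.05), protocol=dict(
        alpha_grid=(0.7,), x2_grid=(20.0,), jrp_grid=(0.5,), duration=80.0,
        burn_in=20.0)),
    "decision": dict(network=dict(n=36, dt=0.05), protocol=dict(
        disparities=(30.0, 60.0, 90.0, 120.0, 150.0), duration=30.0,
        burn_in=15.0, weight_ratios=(1.0,))),
    "recovery": dict(network=dict(n=36, dt=0.05), protocol=dict(
        n_configs=6, duration=40.0, burn_in=15.0)),
    "disparity_roc": dict(network=dict(n=36, dt=0.05), protocol=dict(
        disparities=tuple(np.arange(-32.0, 33.0, 8.0)), n_trials=12,
        trial_len=5.0, burn_in=15.0)),
    "heading_roc": dict(network=dict(n=36, dt=0.05), protocol=dict(
        headings=(-32.0, -16.0, 0.0, 16.0, 32.0), n_trials=10,
        trial_len=5.0, burn_in=15.0)),
}


def make_config(preset: str, seed: int = 0, outdir: Optional[str] = None,
                network: Optional[dict] = None,
                protocol: Optional[dict] = None) -> ExperimentConfig:
    return ExperimentConfig(preset=preset, seed=seed, outdir=outdir,
                            network=dict(network or {}),
                            protocol=dict(protocol or {}))


def fixture(preset: str, seed: int = 0) -> ExperimentConfig:
    """Reduced-size, seeded config for fast end-to-end tests (~seconds)."""
    ov = _FIXTURE_OVERRIDES.get(preset, {})
    return make_config(preset, seed=seed, network=ov.get("network"),
                       protocol=ov.get("protocol"))


def load_config(path) -> ExperimentConfig:
    """Read a YAML (or JSON — YAML is a superset) config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "preset" not in raw:
        raise ConfigError("config must be a mapping with a 'preset' key")
    allowed = {"preset", "seed", "outdir", "network", "protocol"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}")
    return ExperimentConfig(**raw)


def _param_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(cfg: ExperimentConfig, outdir: Optional[Path] = None) -> dict:
    """Execute a preset; if an output directory is configured, write the
    result bundle (config echo, CSV tables, log, parameter hash).

    Returns the dict of DataFrames either way.  Deterministic given the
    seed: rerunning the same config yields byte-identical tables.
    """
    p = cfg.params
    proto = cfg.proto
    results = PRESETS[cfg.preset].fn(p, proto, cfg.seed)
    target = outdir or cfg.outdir
    if target is not None:
        target = Path(target)
        (target / "results").mkdir(parents=True, exist_ok=True)
        with open(target / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
        lines = [f"preset: {cfg.preset}", f"seed: {cfg.seed}",
                 f"param_hash: {_param_hash(cfg)}",
                 f"j_c: {p.j_c}", f"u0: {u0_scale(p)}"]
        for name, df in results.items():
            path = target / "results" / f"{name}.csv"
            df.to_csv(path, index=False, float_format="%.10g")
            lines.append(f"wrote {path.name}: {len(df)} rows")
        (target / "run.log").write_text("\n".join(lines) + "\n")
    return results
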