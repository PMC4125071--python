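"""Scripted experiment protocols: config handling and figure-style table outputs.

Each experiment reproduces one of the package's standard analyses at full or
reduced scale and writes plain CSV tables plus a JSON manifest (config hash,
seed, package version) into an output directory.  Experiments:

``fig1``  Willshaw information vs potentiated fraction and vs beta.
``fig2``  SP information vs stationary occupancy, g_ratio and q_plus.
``fig3``  MP information vs g_ratio and presentation noise.
``fig4``  SP no-error probability vs age: theory (binomial & Gaussian)
          against simulation.
``fig5``  SP finite-size capacity vs coding level (binomial / Gaussian /
          Gaussian+covariance; fluctuating vs fixed pattern sizes).
``fig6``  error-tolerant capacity vs coding level (simulation).
``fig7``  capacity vs coding level with optimised inhibition.
"""
from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .learning import PlasticityParams
from .simulate import SPStreamConfig, sp_retrieval_curves
from .theory_asymptotic import (
    info_mp,
    info_sp,
    info_willshaw,
    sp_asymptotic_optimum,
)
from .theory_finite import (
    SPFiniteModel,
    capacity_half,
    optimal_inhibition,
    optimize_finite,
    p_noerror_binomial,
    p_noerror_gaussian,
)

__all__ = ["ExperimentConfig", "validate_config", "run_experiment", "EXPERIMENTS"]

_DEFAULTS = dict(
    experiment="fig1",
    model="sp",
    N=10_000,
    scale=1.0,
    n_trials=200,
    seed=0,
    out_dir="results",
    approx="binomial",
    overlap_threshold=0.9,
)


@dataclass
class ExperimentConfig:
    experiment: str
    model: str = "sp"
    N: int = 10_000
    scale: float = 1.0
    n_trials: int = 200
    seed: int = 0
    out_dir: str = "results"
    approx: str = "binomial"
    overlap_threshold: float = 0.9
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.scale <= 1.0:
            raise ValueError(f"scale must be in (0, 1], got {self.scale}")
        if self.N < 100:
            raise ValueError(f"N must be >= 100, got {self.N}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.seed < 0:
            raise ValueError(f"seed must be >= 0, got {self.seed}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path: str | Path) -> ExperimentConfig:
    """Parse and schema-check a YAML experiment config; fill defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    if "experiment" not in raw:
        raise ValueError("config is missing required field 'experiment'")
    known = set(_DEFAULTS) | {"extra"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    merged = {**_DEFAULTS, **raw}
    try:
        return ExperimentConfig(**merged)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid config: {e}") from e


def emit_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


# --------------------------------------------------------------- experiments
def _fig1(cfg, rng):
    g0 = np.linspace(0.02, 0.98, round(97 * cfg.scale) or 10)
    rows = [dict(g0=g, beta=info_willshaw(g0=float(g)).beta,
                 info_bits=info_willshaw(g0=float(g)).info_bits) for g in g0]
    betas = np.geomspace(0.2, 10, round(60 * cfg.scale) or 10)
    rows2 = [dict(beta=float(b), info_bits=info_willshaw(beta=float(b)).info_bits)
             for b in betas]
    return {"fig1a_info_vs_g0.csv": pd.DataFrame(rows),
            "fig1b_info_vs_beta.csv": pd.DataFrame(rows2)}


def _fig2(cfg, rng):
    opt = sp_asymptotic_optimum()
    gs = np.geomspace(0.2, 12, round(50 * cfg.scale) or 8)
    rows = [dict(g_ratio=float(g), g_inf=1 / (1 + g),
                 info_bits=info_sp(g_ratio=float(g)).info_bits) for g in gs]
    qs = np.linspace(0.05, 1.0, round(20 * cfg.scale) or 5)
    rows2 = [dict(q_plus=float(q),
                  info_bits=info_sp(g_ratio=opt.params["g_ratio"], q_plus=float(q)).info_bits)
             for q in qs]
    return {"fig2_info_vs_gratio.csv": pd.DataFrame(rows),
            "fig2_info_vs_qplus.csv": pd.DataFrame(rows2),
            "fig2_optimum.csv": pd.DataFrame([{
                "info_bits": opt.info_bits, **{k: v for k, v in opt.params.items()}}])}


def _fig3(cfg, rng):
    gs = np.geomspace(1e-3, 8, round(40 * cfg.scale) or 8)
    rows = [dict(g_ratio=float(g), info_bits=info_mp(g_ratio=float(g), noise_x=0.0).info_bits)
            for g in gs]
    xs = np.linspace(0.0, 0.9, round(19 * cfg.scale) or 7)
    rows2 = [dict(noise_x=float(x), info_bits=info_mp(g_ratio=1.0, noise_x=float(x)).info_bits)
             for x in xs]
    return {"fig3_info_vs_gratio.csv": pd.DataFrame(rows),
            "fig3_tradeoff_info_vs_noise.csv": pd.DataFrame(rows2)}


def _sp_condition(cfg):
    opt = sp_asymptotic_optimum()
    N = cfg.N
    f = opt.beta * np.log(N) / N
    params = PlasticityParams(q_plus=opt.params["q_plus"], g_ratio=opt.params["g_ratio"])
    return opt, f, params


def _fig4(cfg, rng):
    opt, f, params = _sp_condition(cfg)
    m = SPFiniteModel(N=cfg.N, f=f, theta_scaled=opt.theta, params=params, fixed_size=True)
    K50 = capacity_half(m).capacity_P50
    ages = np.unique(np.round(np.geomspace(max(1, 0.1 * K50), 2.2 * K50,
                                           max(6, round(12 * cfg.scale)))).astype(int))
    sim_cfg = SPStreamConfig(N=cfg.N, f=f, theta_scaled=opt.theta, params=params,
                             fixed_size=True)
    curve = sp_retrieval_curves(sim_cfg, ages, cfg.n_trials, [None], seed=cfg.seed)[0]
    lo, hi = curve.wilson(z=3.0)
    df = pd.DataFrame({
        "age": ages,
        "p_binomial": [p_noerror_binomial(m, int(a)).p_noerror for a in ages],
        "p_gaussian": [p_noerror_gaussian(m, int(a)).p_noerror for a in ages],
        "p_sim": curve.p,
        "ci_lo": lo,
        "ci_hi": hi,
        "n_trials": curve.n_trials,
    })
    return {"fig4_p_noerror_vs_age.csv": df}


def _fig5(cfg, rng):
    n_f = max(4, round(8 * cfg.scale))
    lnN = np.log(cfg.N)
    f_grid = np.geomspace(1.0 * lnN / cfg.N, 6.0 * lnN / cfg.N, n_f)
    opt = optimize_finite(cfg.N, model="sp", f_grid=f_grid, refine=1)
    g, th0 = opt.params["g_ratio"], opt.params["theta_scaled"]
    rows = []
    for fv in f_grid:
        for fixed in (False, True):
            best = 0
            for th in np.linspace(1.05 / (1 + g), (1 + g * 1.0) / (1 + g) * 0.98, 9):
                for approx in ("binomial",):
                    m = SPFiniteModel(N=cfg.N, f=float(fv), theta_scaled=float(th),
                                      params=PlasticityParams(q_plus=1.0, g_ratio=g),
                                      fixed_size=fixed)
                    best = max(best, capacity_half(m).capacity_P50)
            rows.append(dict(f=float(fv), fixed_size=fixed, capacity=best))
    m0 = SPFiniteModel(N=cfg.N, f=opt.params["f"], theta_scaled=th0,
                       params=PlasticityParams(q_plus=1.0, g_ratio=g))
    comp = [dict(approx=a,
                 capacity=capacity_half(
                     SPFiniteModel(N=cfg.N, f=opt.params["f"], theta_scaled=th0,
                                   params=PlasticityParams(q_plus=1.0, g_ratio=g),
                                   approx=a)).capacity_P50)
            for a in ("binomial", "gaussian", "gaussian_cov")]
    return {"fig5_capacity_vs_f.csv": pd.DataFrame(rows),
            "fig5_approximations.csv": pd.DataFrame(comp),
            "fig5_optimum.csv": pd.DataFrame([{**opt.params, "capacity": opt.capacity_P50}])}


def _fig6(cfg, rng):
    opt = optimize_finite(cfg.N, model="sp", refine=1)
    f, th, g = opt.params["f"], opt.params["theta_scaled"], opt.params["g_ratio"]
    params = PlasticityParams(q_plus=1.0, g_ratio=g)
    K50 = opt.capacity_P50
    ages = np.unique(np.round(np.geomspace(0.35 * K50, 2.6 * K50,
                                           max(6, round(12 * cfg.scale)))).astype(int))
    sim_cfg = SPStreamConfig(N=cfg.N, f=f, theta_scaled=th, params=params, fixed_size=False)
    curves = sp_retrieval_curves(
        sim_cfg, ages, cfg.n_trials, [None, cfg.overlap_threshold, 0.8], seed=cfg.seed)
    dfs = {}
    summary = []
    for c in curves:
        dfs[f"fig6_curve_{c.criterion.replace('>=', '_ge_')}.csv"] = pd.DataFrame(
            {"age": c.ages, "p": c.p, "n": c.n_trials})
        summary.append(dict(criterion=c.criterion, capacity=c.capacity_half()))
    dfs["fig6_capacity_summary.csv"] = pd.DataFrame(summary)
    return dfs


def _fig7(cfg, rng):
    opt = optimize_finite(cfg.N, model="sp", refine=1)
    f, g = opt.params["f"], opt.params["g_ratio"]
    params = PlasticityParams(q_plus=1.0, g_ratio=g)
    g_inf, g1 = 1 / (1 + g), (1 + g * 1.0) / (1 + g)
    theta_grid = np.linspace(g_inf * 1.05, g1 * 0.98, 15)
    cap0 = max(capacity_half(SPFiniteModel(N=cfg.N, f=f, theta_scaled=float(t),
                                           params=params)).capacity_P50
               for t in theta_grid)
    I_star, cap_I = optimal_inhibition(cfg.N, f, params)
    cap_fix = max(capacity_half(SPFiniteModel(N=cfg.N, f=f, theta_scaled=float(t),
                                              params=params, fixed_size=True)).capacity_P50
                  for t in theta_grid)
    df = pd.DataFrame([
        dict(scenario="no_inhibition", inhibition_I=0.0, capacity=cap0),
        dict(scenario="optimal_inhibition", inhibition_I=I_star,
             capacity=cap_I.capacity_P50),
        dict(scenario="fixed_size", inhibition_I=0.0, capacity=cap_fix),
    ])
    return {"fig7_inhibition.csv": df}


EXPERIMENTS = {
    "fig1": _fig1, "fig2": _fig2, "fig3": _fig3, "fig4": _fig4,
    "fig5": _fig5, "fig6": _fig6, "fig7": _fig7,
}


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Run one experiment; write CSV tables and a JSON manifest.

    Returns the output directory.  On failure, partially written outputs are
    removed and the exception re-raised.
    """
    if cfg.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {cfg.experiment!r}; choose from {sorted(EXPERIMENTS)}"
        )
    out = Path(cfg.out_dir) / f"{cfg.experiment}_seed{cfg.seed}"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    try:
        tables = EXPERIMENTS[cfg.experiment](cfg, rng)
        for name, df in tables.items():
            df.to_csv(out / name, index=False)
        from . import __version__
        manifest = {
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "tables": sorted(tables),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out
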