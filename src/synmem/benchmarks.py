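"""Headline benchmark protocols built from the library's pieces.

These are the two summary computations quoted throughout the docs:

* the ratio of finite-size to asymptotic SP capacity at realistic network
  sizes (deterministic theory), and
* the capacity gained by accepting error-tolerant fixed points instead of
  exact retrieval, measured by simulation at finite-size-optimised
  parameters.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .learning import PlasticityParams
from .simulate import SPStreamConfig, sp_retrieval_curves
from .theory_asymptotic import sp_asymptotic_optimum
from .theory_finite import SPFiniteModel, capacity_half, optimize_finite

__all__ = ["finite_size_capacity_ratios", "error_tolerance_gain",
           "paired_capacity_crossings"]


def finite_size_capacity_ratios(N_values=(10_000, 20_000, 40_000)) -> dict:
    """Finite-size / asymptotic SP capacity ratio (percent) across sizes.

    Protocol: take the SP parameters that optimise the asymptotic
    information capacity; for each N, evaluate the binomial finite-size
    P(alpha50) capacity at those parameters (fixed pattern size M = f N, the
    regime of the asymptotic theory, whose pattern sizes do not fluctuate)
    and divide by the asymptotic prediction ``alpha (N / ln N)^2``.
    """
    opt = sp_asymptotic_optimum()
    params = PlasticityParams(q_plus=opt.params["q_plus"], g_ratio=opt.params["g_ratio"])
    ratios = {}
    for N in N_values:
        f = opt.beta * np.log(N) / N
        model = SPFiniteModel(N=N, f=f, theta_scaled=opt.theta, params=params,
                              fixed_size=True)
        k50 = capacity_half(model).capacity_P50
        ratios[N] = 100.0 * k50 / opt.pattern_capacity(N)
    ns = list(N_values)
    n_min = min(ns, key=lambda n: ratios[n])
    n_max = max(ns, key=lambda n: ratios[n])
    return {
        "ratios_percent": ratios,
        "min_percent": ratios[n_min],
        "max_percent": ratios[n_max],
        "N_at_min": n_min,
        "N_at_max": n_max,
    }


def paired_capacity_crossings(exact, tolerant) -> tuple[float, float]:
    """Half-crossing ages of two retrieval curves measured on shared trials.

    Fits both curves jointly as logistics in log-age with a common slope and
    separate plateaus/positions, then solves each fitted curve for p = 1/2.
    Because every exact success is also a tolerant success, the two curves
    share most of their sampling noise; the joint shared-slope fit estimates
    the horizontal offset (the capacity ratio) far more stably than two
    independent local interpolations of the 1/2 crossing.
    """
    x = np.log(exact.ages.astype(float))
    n = exact.n_trials.astype(float)

    def curve(p0, x50, s):
        return p0 / (1.0 + np.exp((x - x50) / s))

    def residuals(params):
        p0e, p0t, x50e, dx, s = params
        pe = curve(p0e, x50e, s)
        pt = curve(p0t, x50e + dx, s)
        we = np.sqrt(n / np.maximum(pe * (1 - pe), 0.02))
        wt = np.sqrt(n / np.maximum(pt * (1 - pt), 0.02))
        return np.concatenate([we * (pe - exact.p), wt * (pt - tolerant.p)])

    x0 = [0.9, 0.95, np.median(x), 0.15, 0.35]
    fit = least_squares(residuals, x0,
                        bounds=([0.5, 0.5, x[0] - 2, 0.0, 0.02],
                                [1.0, 1.0, x[-1] + 2, 2.0, 5.0]))
    p0e, p0t, x50e, dx, s = fit.x

    def crossing(p0, x50):
        if p0 <= 0.5:
            return np.nan
        return float(np.exp(x50 + s * np.log(2 * p0 - 1)))

    return crossing(p0e, x50e), crossing(p0t, x50e + dx)


def error_tolerance_gain(
    N: int = 10_000,
    n_trials: int = 300,
    seed: int = 0,
    overlap_threshold: float = 0.9,
    n_ages: int = 16,
    n_streams: int = 16,
) -> dict:
    """Capacity increase from error-tolerant retrieval, by simulation.

    Protocol: optimise (f, theta, g_ratio) for the finite network with the
    binomial calculation (fluctuating pattern sizes), then simulate the SP
    stream at those parameters and estimate the retrieval-vs-age curve under
    two criteria — exact fixed points, and fixed points reached from the
    stored pattern with overlap at least ``overlap_threshold``.  The
    capacity is the age at which each curve crosses 1/2; returns the percent
    increase of the error-tolerant capacity over the exact one.
    """
    res = optimize_finite(N, model="sp")
    f, theta, g = res.params["f"], res.params["theta_scaled"], res.params["g_ratio"]
    params = PlasticityParams(q_plus=res.params["q_plus"], g_ratio=g)
    k50 = max(res.capacity_P50, 1)
    ages = np.unique(np.round(np.geomspace(0.4 * k50, 2.4 * k50, n_ages)).astype(int))
    cfg = SPStreamConfig(N=N, f=f, theta_scaled=theta, params=params, fixed_size=False)
    exact, tolerant = sp_retrieval_curves(
        cfg, ages, n_trials, [None, overlap_threshold], seed=seed,
        n_streams=n_streams,
    )
    cap_exact, cap_tol = paired_capacity_crossings(exact, tolerant)
    increase = 100.0 * (cap_tol - cap_exact) / cap_exact if cap_exact > 0 else np.nan
    return {
        "params": dict(N=N, f=f, theta_scaled=theta, g_ratio=g,
                       overlap_threshold=overlap_threshold, n_trials=n_trials),
        "theory_capacity": res.capacity_P50,
        "capacity_exact": cap_exact,
        "capacity_tolerant": cap_tol,
        "increase_percent": increase,
        "curve_exact": {"ages": exact.ages.tolist(), "p": exact.p.tolist()},
        "curve_tolerant": {"ages": tolerant.ages.tolist(), "p": tolerant.p.tolist()},
    }
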