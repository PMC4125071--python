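"""Large-scale simulation of the SP learning/retrieval protocol.

The estimator follows the protocol used for validating the finite-size
theory: initialise the synaptic matrix at its stationary marginal
(i.i.d. Bernoulli at the stationary potentiated fraction — the marginal
distribution is then exactly stationary under the learning rule), stream
random patterns through the stochastic update, and at checkpoints test
whether patterns stored a given number of steps ago are still retrievable.
Testing a pattern of age K therefore always rests on a fully simulated
storage event plus K-1 subsequent presentations.

States are sparse (fN active neurons out of N), so all hot paths work with
index sets: a presentation touches only the active columns of J, and a
field evaluation gathers those columns.  This keeps a network of 10^4
neurons and a stream of 10^5 presentations within minutes on one core.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import spawn
from .dynamics import (
    RetrievalConfig,
    local_fields,
    retrieve,
    wilson_interval,
)
from .learning import PlasticityParams, present_pattern, sp_occupancy, stationary_init

__all__ = [
    "SPStreamConfig",
    "RetrievalCurve",
    "sp_retrieval_curves",
    "sp_retrieval_curve",
    "estimate_retrieval_probability",
]


@dataclass(frozen=True)
class SPStreamConfig:
    """One SP simulation condition.

    ``theta_scaled`` sets the raw activation threshold ``theta f N``;
    ``fixed_size`` streams patterns with exactly ``round(f N)`` selective
    neurons instead of Bernoulli(f) selectivity.
    """

    N: int
    f: float
    theta_scaled: float
    params: PlasticityParams
    fixed_size: bool = True
    inhibition_I: float = 0.0
    max_iters: int = 100


@dataclass
class RetrievalCurve:
    """Estimated retrieval probability per age with Wilson intervals."""

    ages: np.ndarray
    n_success: np.ndarray
    n_trials: np.ndarray
    criterion: str  # "exact" or "overlap>=x"

    @property
    def p(self) -> np.ndarray:
        return self.n_success / self.n_trials

    def wilson(self, z: float = 1.96) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = zip(*(wilson_interval(int(k), int(n), z)
                       for k, n in zip(self.n_success, self.n_trials)))
        return np.array(lo), np.array(hi)

    def capacity_half(self) -> float:
        """Age at which the estimated probability crosses 1/2 (linear
        interpolation between the bracketing ages; 0 if always below)."""
        p = self.p
        above = np.flatnonzero(p >= 0.5)
        if above.size == 0:
            return 0.0
        i = above[-1]
        if i == len(p) - 1:
            return float(self.ages[-1])
        a0, a1 = self.ages[i], self.ages[i + 1]
        p0, p1 = p[i], p[i + 1]
        if p1 >= 0.5 or p0 == p1:
            return float(a1)
        return float(a0 + (p0 - 0.5) / (p0 - p1) * (a1 - a0))


def _draw_pattern(rng, N, f, fixed_size, m_fixed):
    if fixed_size:
        return rng.choice(N, size=m_fixed, replace=False)
    # geometric gap sampling of a Bernoulli(f) index set
    size = int(N * f + 6 * np.sqrt(N * f) + 16)
    pos = np.cumsum(rng.geometric(f, size=size)) - 1
    while pos.size and pos[-1] < N - 1:
        pos = np.concatenate([pos, pos[-1] + np.cumsum(rng.geometric(f, size=size))])
    return pos[pos < N]


def _run_stream(
    cfg: SPStreamConfig,
    ages: np.ndarray,
    n_checkpoints: int,
    spacing: int,
    rng: np.random.Generator,
    criteria: list,
    counters: list,
    burn_in: int = 0,
) -> None:
    """One independent realisation: stream patterns, test at checkpoints.

    ``criteria`` is a list of ``None`` (exact one-step fixed point) or float
    overlap thresholds; every criterion is evaluated on the same stream.
    ``burn_in`` untracked presentations precede the tracked window, letting
    the matrix build up the stationary within-row correlations on top of the
    stationary marginal it is initialised at.
    """
    N, f = cfg.N, cfg.f
    q_plus, q_minus, _ = cfg.params.resolve(f)
    m_fixed = round(f * N)
    occ = sp_occupancy(1, cfg.params, f, N=cfg.N, fixed_size=cfg.fixed_size)
    J = stationary_init(N, occ.g_inf, rng)
    for _ in range(burn_in):
        present_pattern(J, _draw_pattern(rng, N, f, cfg.fixed_size, m_fixed),
                        q_plus, q_minus, rng)
    max_age = int(ages.max())
    history: list = []
    first_test = max_age
    total_steps = first_test + (n_checkpoints - 1) * spacing + 1
    ret_cfg = RetrievalConfig(
        theta_scaled=cfg.theta_scaled, f=f, inhibition_I=cfg.inhibition_I,
        max_iters=cfg.max_iters, mode="iterate_to_fixed_point",
    )
    thr = cfg.theta_scaled * f * N
    checkpoints = {first_test + i * spacing for i in range(n_checkpoints)}
    need_iteration = any(c is not None for c in criteria)
    for t in range(total_steps):
        act = _draw_pattern(rng, N, f, cfg.fixed_size, m_fixed)
        present_pattern(J, act, q_plus, q_minus, rng)
        history.append(act)
        if t - max_age - 1 >= 0:
            history[t - max_age - 1] = None
        if t not in checkpoints:
            continue
        for ia, age in enumerate(ages):
            act_k = history[t - (int(age) - 1)]
            state = np.zeros(N, dtype=np.uint8)
            state[act_k] = 1
            h = local_fields(J, state, cfg.inhibition_I)
            new_active = h > thr
            exact_ok = bool(new_active[act_k].all() and new_active.sum() == act_k.size)
            res = None
            for ic, crit in enumerate(criteria):
                if crit is None:
                    ok = exact_ok
                elif exact_ok:
                    ok = True  # an exact fixed point trivially passes any overlap
                else:
                    if res is None:
                        res = retrieve(J, state, state, ret_cfg)
                    ok = bool(res.converged and res.overlap_m >= crit)
                counters[ic][ia][0] += ok
                counters[ic][ia][1] += 1


def _run_matched_stream(
    cfg: SPStreamConfig,
    ages: np.ndarray,
    rng: np.random.Generator,
    criteria: list,
    counters: list,
) -> None:
    """One matched-history trial: store a tracked pattern on a fresh
    stationary-marginal matrix, then stream further patterns, testing the
    tracked pattern each time it reaches one of the requested ages.

    This realises exactly the ensemble the finite-size theory computes (a
    pattern of age K has precisely a storage event plus K-1 subsequent
    presentations on top of the stationary marginal), without the slow
    build-up of within-row synaptic correlations that a long stationary
    stream accumulates.
    """
    N, f = cfg.N, cfg.f
    q_plus, q_minus, _ = cfg.params.resolve(f)
    m_fixed = round(f * N)
    occ = sp_occupancy(1, cfg.params, f, N=cfg.N, fixed_size=cfg.fixed_size)
    J = stationary_init(N, occ.g_inf, rng)
    ret_cfg = RetrievalConfig(
        theta_scaled=cfg.theta_scaled, f=f, inhibition_I=cfg.inhibition_I,
        max_iters=cfg.max_iters, mode="iterate_to_fixed_point",
    )
    thr = cfg.theta_scaled * f * N
    tracked = _draw_pattern(rng, N, f, cfg.fixed_size, m_fixed)
    present_pattern(J, tracked, q_plus, q_minus, rng)
    age_now = 1
    state = np.zeros(N, dtype=np.uint8)
    state[tracked] = 1
    max_age = int(ages.max())
    age_set = {int(a): ia for ia, a in enumerate(ages)}
    while age_now <= max_age:
        if age_now in age_set:
            ia = age_set[age_now]
            h = local_fields(J, state, cfg.inhibition_I)
            new_active = h > thr
            exact_ok = bool(new_active[tracked].all() and new_active.sum() == tracked.size)
            res = None
            for ic, crit in enumerate(criteria):
                if crit is None:
                    ok = exact_ok
                elif exact_ok:
                    ok = True
                else:
                    if res is None:
                        res = retrieve(J, state, state, ret_cfg)
                    ok = bool(res.converged and res.overlap_m >= crit)
                counters[ic][ia][0] += ok
                counters[ic][ia][1] += 1
        act = _draw_pattern(rng, N, f, cfg.fixed_size, m_fixed)
        present_pattern(J, act, q_plus, q_minus, rng)
        age_now += 1


def sp_retrieval_curves(
    cfg: SPStreamConfig,
    ages,
    n_trials: int,
    criteria: list,
    seed=None,
    n_streams: int = 8,
    checkpoint_spacing: int | None = None,
    matched_history: bool = False,
    burn_in: int = 0,
) -> list[RetrievalCurve]:
    """Estimate P(retrieval) versus pattern age under several criteria at once.

    ``n_trials`` tests per age (and criterion) are split over ``n_streams``
    independent network realisations — fresh stationary matrix and fresh
    stream each — with checkpoints spaced along every stream so consecutive
    tests share little synaptic history.  Criteria: ``None`` counts exact
    one-step fixed points; a float counts trials whose retrieval dynamics,
    started at the stored pattern, converge to a fixed point with at least
    that overlap.

    With ``matched_history=True`` each trial is an independent
    matched-history stream (one tracked pattern per fresh matrix, tested at
    every requested age) — the exact ensemble of the finite-size theory.
    """
    ages = np.asarray(sorted(int(a) for a in np.atleast_1d(ages)))
    if ages.min() < 1:
        raise ValueError("ages must be >= 1")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    counters = [[[0, 0] for _ in ages] for _ in criteria]
    if matched_history:
        for trial_rng in spawn(seed, n_trials):
            _run_matched_stream(cfg, ages, trial_rng, criteria, counters)
    else:
        n_streams = min(n_streams, n_trials)
        per_stream = -(-n_trials // n_streams)  # ceil
        spacing = checkpoint_spacing or max(1, int(ages.max() // 20))
        for stream_rng in spawn(seed, n_streams):
            _run_stream(cfg, ages, per_stream, spacing, stream_rng, criteria,
                        counters, burn_in=burn_in)
    out = []
    for ic, crit in enumerate(criteria):
        out.append(RetrievalCurve(
            ages=ages,
            n_success=np.array([c[0] for c in counters[ic]]),
            n_trials=np.array([c[1] for c in counters[ic]]),
            criterion="exact" if crit is None else f"overlap>={crit}",
        ))
    return out


def sp_retrieval_curve(
    cfg: SPStreamConfig,
    ages,
    n_trials: int,
    seed=None,
    overlap_threshold: float | None = None,
    n_streams: int = 8,
    matched_history: bool = False,
) -> RetrievalCurve:
    """Single-criterion convenience wrapper around :func:`sp_retrieval_curves`."""
    return sp_retrieval_curves(
        cfg, ages, n_trials, [overlap_threshold], seed=seed, n_streams=n_streams,
        matched_history=matched_history,
    )[0]


def estimate_retrieval_probability(
    cfg: SPStreamConfig,
    age: int,
    n_trials: int,
    overlap_threshold: float | None = None,
    seed=None,
    z: float = 1.96,
) -> dict:
    """Retrieval probability of a pattern of the given age, with a Wilson CI."""
    if n_trials <= 0:
        raise ValueError("n_trials must be >= 1")
    curve = sp_retrieval_curve(cfg, [age], n_trials, seed=seed,
                               overlap_threshold=overlap_threshold)
    k, n = int(curve.n_success[0]), int(curve.n_trials[0])
    lo, hi = wilson_interval(k, n, z)
    return {"estimate": k / n, "n_success": k, "n_trials": n,
            "ci_low": lo, "ci_high": hi, "criterion": curve.criterion}
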