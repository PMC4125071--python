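"""Large-N storage capacity: rate functions, saturation, information per synapse.

In the sparse-coding limit (``f = beta ln N / N``) a tested pattern with
occupancies ``(g_plus, g_minus)`` is an exact fixed point with probability
approaching one iff the fields of its ~``fN`` selective neurons stay above
the scaled threshold ``theta`` while the fields of the ~``N`` non-selective
neurons stay below.  The fields are binomial sums, so the wrong-side
probabilities decay with the binomial large-deviation rate function

    Phi(x; g) = x ln(x/g) + (1-x) ln((1-x)/(1-g)),

giving the two capacity conditions (for a load of ``P = alpha (N/ln N)^2``
patterns, which stores ``i = alpha beta / ln 2`` bits per synapse):

    selective side:      Phi(theta; g_plus)  > 0        (theta < g_plus),
    non-selective side:  beta Phi(theta; g_minus) > 1.

Maximal information saturates both: ``theta -> g_plus`` and
``beta = 1 / Phi(g_plus; g_minus)``.  Model-specific links between the load
and the occupancies then yield closed information formulas for the
Willshaw, SP and MP scenarios, optimised here over their parameters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .learning import PlasticityParams, mp_occupancy

__all__ = [
    "LN2",
    "rate_function",
    "gaussian_rate_function",
    "AsymptoticConditions",
    "AsymptoticCapacity",
    "capacity_exponents",
    "x_max",
    "saturate",
    "info_willshaw",
    "info_sp",
    "info_mp",
    "sp_asymptotic_optimum",
    "sp_load_boundary",
    "optimize_asymptotic",
]

LN2 = float(np.log(2.0))


def rate_function(x, mean_g):
    """Binomial large-deviation rate function Phi(x; g).

    Equals the Kullback-Leibler divergence between Bernoulli(x) and
    Bernoulli(g): nonnegative, convex in x, zero only at x = g, and
    ``-(1/n) ln P[Bin(n, g) >= x n] -> Phi(x; g)`` for x > g (similarly for
    the lower tail).  ``x`` may take the boundary value 1 (then
    ``Phi = -ln g``); ``mean_g`` must be strictly inside (0, 1).
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(mean_g, dtype=float)
    if np.any((g <= 0) | (g >= 1)):
        raise ValueError("mean_g must be in (0, 1)")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must be in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(x > 0, x * (np.log(x) - np.log(g)), 0.0)
        t2 = np.where(x < 1, (1 - x) * (np.log1p(-x) - np.log1p(-g)), 0.0)
    out = t1 + t2
    return float(out) if out.ndim == 0 else out


def gaussian_rate_function(x, mean_g):
    """Quadratic rate function of the Gaussian field approximation."""
    x = np.asarray(x, dtype=float)
    g = np.asarray(mean_g, dtype=float)
    out = (x - g) ** 2 / (2 * g * (1 - g))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AsymptoticConditions:
    """Capacity exponents and the threshold window they define.

    ``E_plus = beta Phi(theta; g_plus)`` and
    ``E_minus = beta Phi(theta; g_minus) - 1`` must both be positive for
    retrieval with probability -> 1; ``x_max`` is the lower edge of the
    admissible threshold window, ``beta Phi(x_max; g_minus) = 1`` with
    ``x_max > g_minus``.
    """

    E_plus: float
    E_minus: float
    x_max: float | None
    theta: float
    beta: float
    alpha: float | None = None


def x_max(beta: float, g_minus: float) -> float:
    """Solve ``beta Phi(x; g_minus) = 1`` on (g_minus, 1).

    Returns the threshold value above which the non-selective side is safe;
    raises if even ``x = 1`` cannot satisfy the condition.
    """
    target = 1.0 / beta
    top = rate_function(1.0, g_minus)  # = -ln g_minus
    if top < target:
        raise ValueError(
            f"beta={beta} cannot satisfy the non-selective condition at g_minus={g_minus}"
        )
    fn = lambda x: rate_function(x, g_minus) - target
    lo = g_minus * (1 + 1e-12) + 1e-300
    return float(optimize.brentq(fn, lo, 1.0, xtol=1e-12))


def capacity_exponents(
    theta: float,
    beta: float,
    g_plus: float,
    g_minus: float,
    alpha: float | None = None,
) -> AsymptoticConditions:
    """Exponents of the two error probabilities at scaled threshold theta.

    Requires ``g_minus < theta <= g_plus`` (both mean fields on the correct
    side of the threshold); otherwise the margins are unsatisfiable and a
    ``ValueError`` is raised.
    """
    if not g_minus < theta <= g_plus:
        raise ValueError(
            f"threshold {theta} outside (g_minus, g_plus] = ({g_minus}, {g_plus}]: "
            "mean fields on the wrong side"
        )
    E_plus = beta * rate_function(theta, g_plus) if g_plus < 1 else (
        beta * rate_function(theta, 1 - 1e-15)
    )
    E_minus = beta * rate_function(theta, g_minus) - 1.0
    try:
        xm = x_max(beta, g_minus)
    except ValueError:
        xm = None
    return AsymptoticConditions(
        E_plus=float(E_plus), E_minus=float(E_minus), x_max=xm,
        theta=theta, beta=beta, alpha=alpha,
    )


def saturate(g_plus: float, g_minus: float) -> tuple[float, float]:
    """Saturating (theta_opt, beta_opt) for given occupancies.

    Information is maximal when both conditions hold with equality:
    ``theta_opt = g_plus`` and ``beta_opt = 1 / Phi(g_plus; g_minus)``.
    """
    if not 0.0 <= g_minus < g_plus <= 1.0:
        raise ValueError(f"need 0 <= g_minus < g_plus <= 1, got ({g_minus}, {g_plus})")
    if g_minus <= 0.0:
        raise ValueError("g_minus must be > 0")
    theta_opt = g_plus
    beta_opt = 1.0 / rate_function(g_plus, g_minus)
    return float(theta_opt), float(beta_opt)


@dataclass
class AsymptoticCapacity:
    """Large-N capacity summary: ``P = alpha (N / ln N)^2`` patterns and
    ``info_bits = alpha beta / ln 2`` bits per synapse."""

    model: str
    info_bits: float
    alpha: float
    beta: float
    theta: float
    g_plus: float
    g_minus: float
    params: dict = field(default_factory=dict)

    def pattern_capacity(self, N: int) -> float:
        """Asymptotic number of storable patterns at network size N."""
        return self.alpha * (N / np.log(N)) ** 2


# --------------------------------------------------------------------- Willshaw
def info_willshaw(beta: float | None = None, g0: float | None = None) -> AsymptoticCapacity:
    """Willshaw information per synapse at a given potentiated fraction or beta.

    Saturating the two conditions with ``g_plus = 1`` gives

        i = ln(1 - g0) ln(g0) / ln 2   bits/synapse,

    where ``g0`` is the potentiated fraction; equivalently ``g0 = e^(-1/beta)``
    so ``i = -ln(1 - e^(-1/beta)) / (beta ln 2)``.  The optimum i = ln 2 is
    reached at g0 = 1/2 (beta = 1/ln 2); i vanishes in both the g0 -> 0 and
    g0 -> 1 limits.
    """
    if (beta is None) == (g0 is None):
        raise ValueError("give exactly one of beta or g0")
    if beta is not None:
        if beta <= 0:
            raise ValueError("beta must be > 0")
        g0 = float(np.exp(-1.0 / beta))
    else:
        if not 0.0 < g0 < 1.0:
            raise ValueError("g0 must be in (0, 1)")
        beta = 1.0 / rate_function(1.0, g0)  # = -1/ln(g0)
    alpha = -np.log1p(-g0) / beta**2  # from g0 = 1 - exp(-alpha beta^2)
    info = np.log1p(-g0) * np.log(g0) / LN2
    return AsymptoticCapacity(
        model="willshaw", info_bits=float(info), alpha=float(alpha), beta=float(beta),
        theta=1.0, g_plus=1.0, g_minus=float(g0), params={"g0": float(g0)},
    )


# --------------------------------------------------------------------- SP
def _sp_info_of(w: float, g_ratio: float, q_plus: float) -> tuple[float, dict]:
    """Information at scaled age w = K f^2 q_plus (1 + g) for the SP model."""
    if w <= 0 or g_ratio <= 0 or not 0 < q_plus <= 1:
        return 0.0, {}
    g_inf = 1.0 / (1.0 + g_ratio)
    g_plus = g_inf * (1.0 + g_ratio * q_plus * np.exp(-w))
    if g_plus >= 1.0 or g_plus <= g_inf:
        return 0.0, {}
    phi = rate_function(g_plus, g_inf)
    beta = 1.0 / phi
    alpha = w / (beta**2 * q_plus * (1.0 + g_ratio))
    info = alpha * beta / LN2
    return info, {
        "beta": beta, "theta": g_plus, "alpha": alpha,
        "g_plus": g_plus, "g_minus": g_inf, "w": w,
    }


def info_sp(
    params: PlasticityParams | None = None,
    g_ratio: float | None = None,
    q_plus: float = 1.0,
    w: float | None = None,
) -> AsymptoticCapacity:
    """SP information per synapse, maximised over the load (oldest age).

    The oldest stored pattern has scaled age ``w = K f^2 q_plus (1+g)``
    (= ``alpha beta^2 q_plus (1+g)``); its selective-pair occupancy is
    ``g_plus = g_inf (1 + g q_plus e^-w)`` with ``g_inf = 1/(1+g)``.
    Saturating the threshold and coding level at that age gives

        i(w) = w Phi(g_plus(w); g_inf) / (q_plus (1+g) ln 2),

    maximised over w here (or evaluated at a supplied ``w``).
    """
    if params is not None:
        g_ratio = params.g_ratio
        q_plus = params.q_plus
    if g_ratio is None:
        raise ValueError("g_ratio needed (directly or via params)")
    if w is None:
        res = optimize.minimize_scalar(
            lambda lw: -_sp_info_of(np.exp(lw), g_ratio, q_plus)[0],
            bounds=(np.log(1e-3), np.log(20.0)), method="bounded",
            options={"xatol": 1e-12},
        )
        w = float(np.exp(res.x))
    info, aux = _sp_info_of(w, g_ratio, q_plus)
    if not aux:
        return AsymptoticCapacity(
            model="sp", info_bits=0.0, alpha=0.0, beta=np.nan, theta=np.nan,
            g_plus=np.nan, g_minus=np.nan, params={"g_ratio": g_ratio, "q_plus": q_plus, "w": w},
        )
    return AsymptoticCapacity(
        model="sp", info_bits=info, alpha=aux["alpha"], beta=aux["beta"],
        theta=aux["theta"], g_plus=aux["g_plus"], g_minus=aux["g_minus"],
        params={"g_ratio": g_ratio, "q_plus": q_plus, "w": w},
    )


def sp_load_boundary(
    theta: float, beta: float, g_ratio: float, q_plus: float = 1.0
) -> float:
    """Asymptotic SP load boundary alpha_max at fixed (theta, beta, g, q_plus).

    The oldest retrievable pattern is the one whose selective occupancy has
    decayed down to the threshold, ``g_plus(w) = theta`` with
    ``w = alpha beta^2 q_plus (1+g)``; solving gives

        alpha_max = -ln((theta/g_inf - 1)/(g q_plus)) / (beta^2 q_plus (1+g)).

    Loads strictly below (above) this boundary are retrieved with
    probability -> 1 (0) in the large-N limit provided the non-selective
    condition ``beta Phi(theta; g_inf) > 1`` also holds strictly.
    """
    g_inf = 1.0 / (1.0 + g_ratio)
    if not g_inf < theta < g_inf * (1 + g_ratio * q_plus):
        raise ValueError("theta outside (g_inf, g_plus(age 1)): no finite load boundary")
    w_b = -np.log((theta / g_inf - 1.0) / (g_ratio * q_plus))
    return float(w_b / (beta**2 * q_plus * (1.0 + g_ratio)))


_SP_OPT_CACHE: dict = {}


def sp_asymptotic_optimum() -> AsymptoticCapacity:
    """Globally optimal SP capacity over (g_ratio, q_plus, load).

    A coarse log grid over (w, g_ratio, q_plus) followed by Nelder-Mead
    refinement; q_plus = 1 is optimal (stochastic potentiation only lowers
    the imprint of the tracked pattern).  Deterministic.
    """
    if "opt" in _SP_OPT_CACHE:
        return _SP_OPT_CACHE["opt"]
    best = (-1.0, None)
    for q_plus in (0.25, 0.5, 0.75, 1.0):
        for g in np.geomspace(0.2, 8.0, 25):
            for w in np.geomspace(0.05, 3.0, 25):
                v, _ = _sp_info_of(w, g, q_plus)
                if v > best[0]:
                    best = (v, (w, g, q_plus))
    w0, g0, qp0 = best[1]
    res = optimize.minimize(
        lambda p: -_sp_info_of(np.exp(p[0]), np.exp(p[1]), min(1.0, np.exp(p[2])))[0],
        [np.log(w0), np.log(g0), np.log(qp0)],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
    )
    w, g, qp = np.exp(res.x[0]), np.exp(res.x[1]), min(1.0, np.exp(res.x[2]))
    out = info_sp(g_ratio=float(g), q_plus=float(qp), w=float(w))
    _SP_OPT_CACHE["opt"] = out
    return out


# --------------------------------------------------------------------- MP
def _mp_info_of(omega: float, g_ratio: float, noise_x: float) -> tuple[float, dict]:
    if omega <= 0:
        return 0.0, {}
    occ = mp_occupancy(
        PlasticityParams(q_plus=1.0, g_ratio=g_ratio, noise_x=noise_x), omega=omega
    )
    g_plus, g_minus = occ.g_plus, occ.g_minus
    if g_plus <= g_minus or g_minus <= 0.0 or g_minus >= 1.0:
        return 0.0, {}
    phi = rate_function(min(g_plus, 1.0), g_minus)
    if phi <= 0:
        return 0.0, {}
    beta = 1.0 / phi
    alpha = omega / beta**2
    info = alpha * beta / LN2  # = omega * phi / ln 2
    return info, {"beta": beta, "theta": g_plus, "alpha": alpha,
                  "g_plus": g_plus, "g_minus": g_minus, "omega": omega}


def info_mp(
    params: PlasticityParams | None = None,
    g_ratio: float | None = None,
    noise_x: float | None = None,
    omega: float | None = None,
) -> AsymptoticCapacity:
    """MP information per synapse, maximised over the load omega = P f^2.

    ``i(omega) = omega Phi(g_plus(omega); g_minus(omega)) / ln 2`` with the
    slow-learning occupancies of :func:`synmem.learning.mp_occupancy`.  At
    ``g_ratio -> 0`` and ``noise_x = 0`` this reduces exactly to the
    Willshaw expression; information decreases with the presentation noise
    (capacity/generalisation trade-off) and never exceeds the Willshaw
    optimum.
    """
    if params is not None:
        g_ratio = params.g_ratio
        noise_x = params.noise_x
    if g_ratio is None or noise_x is None:
        raise ValueError("g_ratio and noise_x needed (directly or via params)")
    if omega is None:
        res = optimize.minimize_scalar(
            lambda lo: -_mp_info_of(np.exp(lo), g_ratio, noise_x)[0],
            bounds=(np.log(1e-3), np.log(30.0)), method="bounded",
            options={"xatol": 1e-12},
        )
        omega = float(np.exp(res.x))
    info, aux = _mp_info_of(omega, g_ratio, noise_x)
    if not aux:
        return AsymptoticCapacity(
            model="mp", info_bits=0.0, alpha=0.0, beta=np.nan, theta=np.nan,
            g_plus=np.nan, g_minus=np.nan,
            params={"g_ratio": g_ratio, "noise_x": noise_x, "omega": omega},
        )
    return AsymptoticCapacity(
        model="mp", info_bits=info, alpha=aux["alpha"], beta=aux["beta"],
        theta=aux["theta"], g_plus=aux["g_plus"], g_minus=aux["g_minus"],
        params={"g_ratio": g_ratio, "noise_x": noise_x, "omega": omega},
    )


# --------------------------------------------------------------------- optimiser
def optimize_asymptotic(model: str, **fixed) -> AsymptoticCapacity:
    """Optimal information per synapse of a model over its free parameters.

    ``model`` is one of ``willshaw`` (free: beta), ``sp`` (free: g_ratio,
    q_plus, load; any can be fixed by keyword) or ``mp`` (free: g_ratio and
    load at fixed ``noise_x``, default 0).  Grid scan plus deterministic
    local refinement.
    """
    if model == "willshaw":
        res = optimize.minimize_scalar(
            lambda lg: -info_willshaw(g0=1 / (1 + np.exp(-lg))).info_bits,
            bounds=(-8, 8), method="bounded", options={"xatol": 1e-12},
        )
        return info_willshaw(g0=1 / (1 + np.exp(-res.x)))
    if model == "sp":
        if not fixed:
            return sp_asymptotic_optimum()
        g_ratio = fixed.get("g_ratio")
        q_plus = fixed.get("q_plus", 1.0)
        if g_ratio is not None:
            return info_sp(g_ratio=g_ratio, q_plus=q_plus, w=fixed.get("w"))
        best = None
        for g in np.geomspace(0.05, 20.0, 200):
            cand = info_sp(g_ratio=float(g), q_plus=q_plus)
            if best is None or cand.info_bits > best.info_bits:
                best = cand
        return best
    if model == "mp":
        noise_x = fixed.get("noise_x", 0.0)
        g_ratio = fixed.get("g_ratio")
        if g_ratio is not None:
            return info_mp(g_ratio=g_ratio, noise_x=noise_x, omega=fixed.get("omega"))
        # free g_ratio: the optimum sits at the lower boundary of the scan range
        best = None
        for g in np.geomspace(1e-4, 10.0, 120):
            cand = info_mp(g_ratio=float(g), noise_x=noise_x)
            if best is None or cand.info_bits > best.info_bits:
                best = cand
        return best
    raise ValueError(f"unknown model {model!r}")
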