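"""Finite-N retrieval probability and capacity, with binomial and Gaussian fields.

For a network of N neurons storing patterns at coding level f, a tested
pattern with M selective neurons is an exact fixed point of one synchronous
update iff every selective field (a Binomial(M-1, g_plus) sum) exceeds the
raw threshold and every non-selective field (Binomial(M, g_minus)) does not.
Neglecting correlations between neurons,

    P_noerror(M) = (1 - p_sel_wrong)^M * (1 - p_ns_wrong)^(N-M),

computed here with exact log-domain binomial tails (the asymptotic
geometric-series expansion of those tails is also provided, since it is what
the leading-order capacity formula is built from).  The probability is
averaged over the binomial distribution of M when pattern sizes fluctuate,
and the finite-size capacity is defined as the largest age (or pattern
count) at which the averaged probability still reaches 1/2.

A Gaussian approximation of the field distributions (optionally corrected
with the exact within-row synaptic covariance of the SP rule) is included
for comparison: in the sparse regime it overestimates retrieval because the
capacity probes the far tail of the field distribution, which a Gaussian
underestimates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats as sps
from scipy.special import betainc, log_ndtr

from .learning import (
    OccupancyStats,
    PlasticityParams,
    mp_occupancy,
    sp_occupancy,
    willshaw_occupancy,
)
from .theory_asymptotic import rate_function

__all__ = [
    "FiniteFieldModel",
    "SPFiniteModel",
    "WillshawFiniteModel",
    "MPFiniteModel",
    "PNoErrorResult",
    "FiniteCapacityResult",
    "binomial_tail_expansion",
    "p_noerror_given_M",
    "p_noerror_binomial",
    "p_noerror_gaussian",
    "average_over_pattern_size",
    "capacity_half",
    "leading_order_capacity",
    "sp_capacity_continuous",
    "sp_log_p_noerror_continuous",
    "optimize_finite",
    "optimal_inhibition",
    "sp_row_covariance",
]


# ------------------------------------------------------------------ containers
@dataclass(frozen=True)
class FiniteFieldModel:
    """Field statistics of one tested pattern in a finite network."""

    N: int
    f: float
    g_plus: float
    g_minus: float
    theta_scaled: float
    M: int | None = None          # None: average over Binomial(N, f)
    approx: str = "binomial"      # binomial | gaussian | gaussian_cov
    inhibition_I: float = 0.0
    cov_plus: float = 0.0
    cov_minus: float = 0.0

    @property
    def thr_raw(self) -> float:
        return self.theta_scaled * self.f * self.N


@dataclass
class PNoErrorResult:
    """No-error probability and its single-neuron ingredients."""

    p_noerror: float
    log_p_noerror: float
    p_wrong_selective: float
    p_wrong_nonselective: float
    approx: str
    M: int | None = None
    mu_plus: float | None = None
    mu_minus: float | None = None
    sigma_plus: float | None = None
    sigma_minus: float | None = None
    correction_terms: dict = field(default_factory=dict)


@dataclass
class FiniteCapacityResult:
    """P(alpha50) capacity: largest age/pattern count with P_noerror >= 1/2."""

    capacity_P50: int
    N: int
    model: str
    approx: str
    params: dict = field(default_factory=dict)
    inhibition_I: float = 0.0
    p_at_capacity: float | None = None


# ------------------------------------------------------------------ tails
def _exact_tails(M_sel: int, M_ns: int, g_plus: float, g_minus: float, T: float):
    """Log of the two wrong-side probabilities from exact binomial tails.

    Selective wrong: field <= T, field ~ Bin(M_sel, g_plus).
    Non-selective wrong: field > T, field ~ Bin(M_ns, g_minus).
    ``T`` is the integer part of the raw threshold (fields are integers and
    ties go silent, so "above threshold" means ``field >= floor(T) + 1``).
    """
    Tf = np.floor(T)
    log_sel_wrong = sps.binom.logcdf(Tf, M_sel, g_plus) if g_plus < 1.0 else (
        0.0 if M_sel <= Tf else -np.inf
    )
    log_ns_wrong = sps.binom.logsf(Tf, M_ns, g_minus) if g_minus > 0.0 else -np.inf
    return log_sel_wrong, log_ns_wrong


def binomial_tail_expansion(n: int, g: float, x: float, lower: bool) -> dict:
    """Stirling/geometric-series approximation of a binomial tail.

    Approximates ``P[Bin(n, g) >= x n]`` (or ``<=`` when ``lower``) by the
    dominant term of the sum times the geometric correction:

        P ~ exp(-n Phi(x; g)) / (sqrt(2 pi n x (1-x)) (1 - r)),

    with ``r = g(1-x)/(x(1-g))`` for the upper tail (reciprocal for the
    lower).  Returns the log-probability, the pieces, and a validity flag
    (the expansion needs the tail to be on the far side of the mean and the
    geometric ratio bounded away from 1).
    """
    if not (0.0 < x < 1.0 and 0.0 < g < 1.0):
        return {"valid": False, "log_p": np.nan}
    r = g * (1 - x) / (x * (1 - g))
    if lower:
        r = 1.0 / r
    valid = (x > g) if not lower else (x < g)
    valid = valid and r < 0.95
    phi = rate_function(x, g)
    log_p = -n * phi - 0.5 * np.log(2 * np.pi * n * x * (1 - x)) - np.log1p(-r) if valid else np.nan
    return {
        "valid": bool(valid),
        "log_p": log_p,
        "rate": phi,
        "geometric_ratio": r,
        "prefactor_log": -0.5 * np.log(2 * np.pi * n * x * (1 - x)) if valid else np.nan,
    }


def p_noerror_given_M(model: FiniteFieldModel, M: int) -> PNoErrorResult:
    """No-error probability for a tested pattern with exactly M selective neurons."""
    N = model.N
    if not 1 <= M <= N:
        raise ValueError(f"M must be in [1, N], got {M}")
    T_eff = model.thr_raw + model.inhibition_I * M
    if model.approx == "binomial":
        l_sel, l_ns = _exact_tails(M - 1, M, model.g_plus, model.g_minus, T_eff)
        p_sel = float(np.exp(l_sel))
        p_ns = float(np.exp(l_ns))
        extras = {}
        mu_p = mu_m = s_p = s_m = None
    elif model.approx in ("gaussian", "gaussian_cov"):
        mu_p = (M - 1) * model.g_plus
        mu_m = M * model.g_minus
        var_p = (M - 1) * model.g_plus * (1 - model.g_plus)
        var_m = M * model.g_minus * (1 - model.g_minus)
        if model.approx == "gaussian_cov":
            var_p += (M - 1) * (M - 2) * model.cov_plus
            var_m += M * (M - 1) * model.cov_minus
        if var_p < 0 or var_m < 0:
            raise ValueError("covariance correction produced a negative variance")
        s_p, s_m = np.sqrt(var_p), np.sqrt(var_m)
        # fields are integers and ties go silent, so the Gaussian cut sits at
        # the half-integer between the last silent and first active count
        T_c = np.floor(T_eff) + 0.5
        l_sel = log_ndtr((T_c - mu_p) / s_p) if s_p > 0 else (0.0 if mu_p <= T_eff else -np.inf)
        l_ns = log_ndtr(-(T_c - mu_m) / s_m) if s_m > 0 else (0.0 if mu_m > T_eff else -np.inf)
        p_sel = float(np.exp(l_sel))
        p_ns = float(np.exp(l_ns))
        extras = {"cov_plus": model.cov_plus, "cov_minus": model.cov_minus} \
            if model.approx == "gaussian_cov" else {}
    else:
        raise ValueError(f"unknown approximation {model.approx!r}")
    with np.errstate(divide="ignore"):
        log_p = M * np.log1p(-min(p_sel, 1.0)) + (N - M) * np.log1p(-min(p_ns, 1.0))
    return PNoErrorResult(
        p_noerror=float(np.exp(log_p)),
        log_p_noerror=float(log_p),
        p_wrong_selective=p_sel,
        p_wrong_nonselective=p_ns,
        approx=model.approx,
        M=M,
        mu_plus=mu_p,
        mu_minus=mu_m,
        sigma_plus=None if s_p is None else float(s_p),
        sigma_minus=None if s_m is None else float(s_m),
        correction_terms=extras,
    )


def average_over_pattern_size(
    p_fn,
    N: int,
    f: float,
    window_sd: float = 6.0,
    gaussian_surrogate: bool = False,
) -> float:
    """Average a per-size probability over the distribution of pattern sizes.

    The number of selective neurons M is Binomial(N, f); the average is the
    exact binomial-weighted sum over M within ``window_sd`` standard
    deviations of the mean (renormalised; the window widens automatically if
    it traps less than 1 - 1e-10 of the mass).  With ``gaussian_surrogate``
    the binomial weights are replaced by a discretised normal density — the
    variant used in the original large-N derivation — for comparison.
    """
    mean = N * f
    sd = np.sqrt(N * f * (1 - f))
    while True:
        lo = max(1, int(np.floor(mean - window_sd * sd)))
        hi = min(N, int(np.ceil(mean + window_sd * sd)))
        Ms = np.arange(lo, hi + 1)
        if gaussian_surrogate:
            w = np.exp(-((Ms - mean) ** 2) / (2 * sd * sd))
        else:
            w = sps.binom.pmf(Ms, N, f)
        mass = sps.binom.cdf(hi, N, f) - sps.binom.cdf(lo - 1, N, f)
        if gaussian_surrogate or mass >= 1 - 1e-10 or (lo == 1 and hi == N):
            break
        window_sd *= 1.5
    w = w / w.sum()
    vals = np.array([p_fn(int(M)) for M in Ms])
    return float(w @ vals)


# ------------------------------------------------------------------ model families
@dataclass(frozen=True)
class SPFiniteModel:
    """SP network at finite N: occupancies as a function of pattern age."""

    N: int
    f: float
    theta_scaled: float
    params: PlasticityParams
    fixed_size: bool = False
    inhibition_I: float = 0.0
    approx: str = "binomial"

    @property
    def M_mean(self) -> float:
        return self.f * self.N

    def occupancy(self, age_K: int) -> OccupancyStats:
        return sp_occupancy(age_K, self.params, self.f, N=self.N, fixed_size=self.fixed_size)

    def field_model(self, age_K: int) -> FiniteFieldModel:
        occ = self.occupancy(age_K)
        cov_p = cov_m = 0.0
        if self.approx == "gaussian_cov":
            cov_p, cov_m = sp_row_covariance(age_K, self.params, self.f, self.N, self.fixed_size)
        return FiniteFieldModel(
            N=self.N, f=self.f, g_plus=occ.g_plus, g_minus=occ.g_minus,
            theta_scaled=self.theta_scaled,
            M=round(self.M_mean) if self.fixed_size else None,
            approx=self.approx, inhibition_I=self.inhibition_I,
            cov_plus=cov_p, cov_minus=cov_m,
        )


@dataclass(frozen=True)
class WillshawFiniteModel:
    """Willshaw network at finite N: occupancies as a function of pattern count."""

    N: int
    f: float
    theta_scaled: float
    fixed_size: bool = False
    inhibition_I: float = 0.0
    approx: str = "binomial"

    @property
    def M_mean(self) -> float:
        return self.f * self.N

    def field_model(self, P: int) -> FiniteFieldModel:
        occ = willshaw_occupancy(self.f, P)
        return FiniteFieldModel(
            N=self.N, f=self.f, g_plus=occ.g_plus, g_minus=occ.g_minus,
            theta_scaled=self.theta_scaled,
            M=round(self.M_mean) if self.fixed_size else None,
            approx=self.approx, inhibition_I=self.inhibition_I,
        )


@dataclass(frozen=True)
class MPFiniteModel:
    """MP network at finite N: occupancies as a function of prototype count."""

    N: int
    f: float
    theta_scaled: float
    params: PlasticityParams
    fixed_size: bool = False
    inhibition_I: float = 0.0
    approx: str = "binomial"

    @property
    def M_mean(self) -> float:
        return self.f * self.N

    def field_model(self, P: int) -> FiniteFieldModel:
        occ = mp_occupancy(self.params, f=self.f, n_prototypes=P)
        return FiniteFieldModel(
            N=self.N, f=self.f, g_plus=occ.g_plus, g_minus=occ.g_minus,
            theta_scaled=self.theta_scaled,
            M=round(self.M_mean) if self.fixed_size else None,
            approx=self.approx, inhibition_I=self.inhibition_I,
        )


def _p_noerror_M_array(fm: FiniteFieldModel, Ms: np.ndarray) -> np.ndarray:
    """Vectorised no-error probability over an array of pattern sizes."""
    Ms = np.asarray(Ms, dtype=np.int64)
    N = fm.N
    T_eff = fm.thr_raw + fm.inhibition_I * Ms
    if fm.approx == "binomial":
        Tf = np.floor(T_eff)
        with np.errstate(divide="ignore"):
            l_sel = (sps.binom.logcdf(Tf, Ms - 1, fm.g_plus) if fm.g_plus < 1.0
                     else np.where(Ms - 1 <= Tf, 0.0, -np.inf))
            l_ns = (sps.binom.logsf(Tf, Ms, fm.g_minus) if fm.g_minus > 0.0
                    else np.full(Ms.shape, -np.inf))
    else:
        T_c = np.floor(T_eff) + 0.5
        mu_p = (Ms - 1) * fm.g_plus
        mu_m = Ms * fm.g_minus
        var_p = (Ms - 1) * fm.g_plus * (1 - fm.g_plus)
        var_m = Ms * fm.g_minus * (1 - fm.g_minus)
        if fm.approx == "gaussian_cov":
            var_p = var_p + (Ms - 1) * (Ms - 2) * fm.cov_plus
            var_m = var_m + Ms * (Ms - 1) * fm.cov_minus
        if np.any(var_p < 0) or np.any(var_m < 0):
            raise ValueError("covariance correction produced a negative variance")
        s_p = np.sqrt(np.maximum(var_p, 1e-300))
        s_m = np.sqrt(np.maximum(var_m, 1e-300))
        l_sel = log_ndtr((T_c - mu_p) / s_p)
        l_ns = log_ndtr(-(T_c - mu_m) / s_m)
    p_sel = np.minimum(np.exp(l_sel), 1.0)
    p_ns = np.minimum(np.exp(l_ns), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = Ms * np.log1p(-p_sel) + (N - Ms) * np.log1p(-p_ns)
    log_p = np.where((p_sel >= 1.0) | (p_ns >= 1.0), -np.inf, log_p)
    return np.exp(log_p)


def _p_noerror_at(field_model: FiniteFieldModel) -> float:
    if field_model.M is not None:
        return float(_p_noerror_M_array(field_model, np.array([field_model.M]))[0])
    N, f = field_model.N, field_model.f
    mean = N * f
    sd = np.sqrt(N * f * (1 - f))
    lo = max(1, int(np.floor(mean - 6 * sd)))
    hi = min(N, int(np.ceil(mean + 6 * sd)))
    Ms = np.arange(lo, hi + 1)
    w = sps.binom.pmf(Ms, N, f)
    w = w / w.sum()
    return float(w @ _p_noerror_M_array(field_model, Ms))


def p_noerror_binomial(model, load: int) -> PNoErrorResult:
    """Averaged no-error probability under the binomial field approximation.

    ``model`` is one of the finite model families; ``load`` is the pattern
    age (SP) or pattern count (Willshaw/MP).  Tails are exact log-domain
    binomial sums; the asymptotic expansion of those tails lives in
    :func:`binomial_tail_expansion` and the leading-order capacity formula.
    """
    fm = replace(model.field_model(load), approx="binomial")
    p = _p_noerror_at(fm)
    rep = p_noerror_given_M(fm, fm.M if fm.M is not None else max(1, round(fm.N * fm.f)))
    rep.p_noerror = p
    rep.log_p_noerror = float(np.log(p)) if p > 0 else -np.inf
    rep.M = fm.M
    return rep


def p_noerror_gaussian(model, load: int, with_covariance: bool = False) -> PNoErrorResult:
    """Averaged no-error probability under the Gaussian field approximation."""
    if with_covariance:
        if not isinstance(model, SPFiniteModel):
            raise NotImplementedError("covariance-corrected variances are available for the SP model")
        # rebuild so the field model carries the stationary row covariance
        fm = replace(model, approx="gaussian_cov").field_model(load)
    else:
        fm = replace(model.field_model(load), approx="gaussian")
    p = _p_noerror_at(fm)
    rep = p_noerror_given_M(fm, fm.M if fm.M is not None else max(1, round(fm.N * fm.f)))
    rep.p_noerror = p
    rep.log_p_noerror = float(np.log(p)) if p > 0 else -np.inf
    rep.M = fm.M
    return rep


# ------------------------------------------------------------------ covariance
def sp_row_covariance(
    age_K: int,
    params: PlasticityParams,
    f: float,
    N: int | None = None,
    fixed_size: bool = False,
) -> tuple[float, float]:
    """Covariance between two synapses sharing their postsynaptic neuron (SP).

    Synapses J_ij and J_ik (j, k selective in the tested pattern) are driven
    by the shared activity history of neuron i: conditional on that history
    they are independent with identical conditional potentiation probability
    m(history), so ``Cov(J_ij, J_ik) = Var(m)``.  The first two moments of m
    follow closed linear recursions over presentations (the update map is
    affine in m), which are summed in closed form here.  Returns
    ``(cov_plus, cov_minus)`` for selective resp. non-selective postsynaptic
    neurons, at pattern age K.

    These within-row correlations are what the Gaussian-with-covariance
    approximation adds; they grow with f and explain the capacity drop at
    large coding levels.
    """
    q_plus, q_minus, _ = params.resolve(f)
    if fixed_size:
        if N is None:
            raise ValueError("fixed_size covariance needs N")
        M = round(f * N)
        p_post = M / N
        pre_given_post = (M - 1) / (N - 1)
        pre_given_nopost = M / (N - 1)
    else:
        p_post = f
        pre_given_post = pre_given_nopost = f
    a = pre_given_post * q_plus        # active post: m -> m(1-a) + a
    d = pre_given_nopost * q_minus     # silent post: m -> m(1-d)
    p = p_post
    lam = 1 - p * a - (1 - p) * d
    if p * a + (1 - p) * d == 0:
        return 0.0, 0.0
    g_inf = p * a / (p * a + (1 - p) * d)
    A = p * (1 - a) ** 2 + (1 - p) * (1 - d) ** 2
    B = 2 * p * a * (1 - a)
    C = p * a * a
    S_star = (B * g_inf + C) / (1 - A)

    def moments_after(E0: float, S0: float, t: int) -> tuple[float, float]:
        E_t = g_inf + (E0 - g_inf) * lam**t
        geo = (1 - A**t) / (1 - A)
        if abs(A - lam) > 1e-14:
            mix = (A**t - lam**t) / (A - lam)
        else:
            mix = t * A ** (t - 1)
        S_t = A**t * S0 + (B * g_inf + C) * geo + B * (E0 - g_inf) * mix
        return E_t, S_t

    t = age_K - 1
    # selective post: storage step applies a sure-pre potentiation opportunity
    E0 = g_inf * (1 - q_plus) + q_plus
    S0 = (1 - q_plus) ** 2 * S_star + 2 * q_plus * (1 - q_plus) * g_inf + q_plus**2
    E_p, S_p = moments_after(E0, S0, t)
    cov_plus = S_p - E_p**2
    # non-selective post: storage step applies a sure-pre depression opportunity
    E0 = g_inf * (1 - q_minus)
    S0 = (1 - q_minus) ** 2 * S_star
    E_m, S_m = moments_after(E0, S0, t)
    cov_minus = S_m - E_m**2
    return float(cov_plus), float(cov_minus)


# ------------------------------------------------------------------ capacity
def capacity_half(model, p_target: float = 0.5, load_max: int = 2**40) -> FiniteCapacityResult:
    """Largest load with averaged no-error probability still >= ``p_target``.

    Integer bisection bracketed by exponential doubling; a load of 0 means
    even the freshest pattern fails the criterion.  Ties at exactly
    ``p_target`` resolve to the larger load.
    """
    def p(load: int) -> float:
        return _p_noerror_at(model.field_model(load))

    if p(1) < p_target:
        return FiniteCapacityResult(
            capacity_P50=0, N=model.N, model=type(model).__name__,
            approx=model.approx, inhibition_I=model.inhibition_I,
            p_at_capacity=p(1),
        )
    lo, hi = 1, 2
    while p(hi) >= p_target:
        lo, hi = hi, hi * 2
        if hi > load_max:
            raise RuntimeError("capacity exceeds load_max; probability never crosses the target")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if p(mid) >= p_target:
            lo = mid
        else:
            hi = mid
    return FiniteCapacityResult(
        capacity_P50=lo, N=model.N, model=type(model).__name__,
        approx=model.approx, inhibition_I=model.inhibition_I,
        p_at_capacity=p(lo),
        params={"theta_scaled": model.theta_scaled, "f": model.f,
                "fixed_size": model.fixed_size},
    )


def _binom_cdf_continuous(t: float, n: float, g: float) -> float:
    """``P[Bin(n, g) <= t]`` continued to real t (and n) via the regularised
    incomplete beta function; matches the integer cdf at integer t."""
    if t < 0:
        return 0.0
    if t >= n:
        return 1.0
    return float(betainc(n - t, t + 1.0, 1.0 - g))


def log_p_noerror_continuous(
    N: float,
    beta: float,
    theta_scaled: float,
    g_plus: float,
    g_minus: float,
) -> float:
    """Log no-error probability with M and the threshold treated as continuous.

    Identical to the fixed-size binomial calculation except that the number
    of selective neurons ``M = beta ln N`` and the threshold ``theta M`` are
    continuous (binomial tails continued via the incomplete beta function).
    This removes integer-rounding jitter — M grows only logarithmically with
    N, so ``round``/``floor`` effects never die out at any realistic size —
    and is the evaluation used for asymptotic-regime checks (convergence of
    the leading-order capacity formula, the step-function limit of the
    retrieval probability).
    """
    lnN = np.log(N)
    Mc = beta * lnN
    thr = theta_scaled * Mc
    p_sel = _binom_cdf_continuous(thr, Mc - 1, g_plus) if g_plus < 1.0 else 0.0
    p_ns = 1.0 - _binom_cdf_continuous(thr, Mc, g_minus) if g_minus > 0.0 else 0.0
    if p_sel >= 1.0 or p_ns >= 1.0:
        return -np.inf
    return float(Mc * np.log1p(-p_sel) + (N - Mc) * np.log1p(-p_ns))


def sp_log_p_noerror_continuous(
    N: float,
    beta: float,
    theta_scaled: float,
    g_ratio: float,
    K: float,
    q_plus: float = 1.0,
) -> float:
    """Continuous-evaluation log no-error probability for an SP pattern of age K."""
    lnN = np.log(N)
    f = beta * lnN / N
    g_inf = 1.0 / (1.0 + g_ratio)
    q_minus = g_ratio * q_plus * f / (1 - f)
    lam = 1 - f * f * q_plus - f * (1 - f) * q_minus
    g_plus = g_inf + (1 - g_inf) * q_plus * lam ** (K - 1)
    return log_p_noerror_continuous(N, beta, theta_scaled, g_plus, g_inf)


def willshaw_log_p_noerror_continuous(
    N: float,
    beta: float,
    theta_scaled: float,
    P: float,
) -> float:
    """Continuous-evaluation log no-error probability for Willshaw at load P.

    The load acts through the background occupancy
    ``g_minus = 1 - (1 - f^2)^P``; selective pairs are potentiated with
    certainty.
    """
    lnN = np.log(N)
    f = beta * lnN / N
    g_minus = float(-np.expm1(P * np.log1p(-f * f)))
    return log_p_noerror_continuous(N, beta, theta_scaled, 1.0, g_minus)


def sp_capacity_continuous(
    N: float,
    beta: float,
    theta_scaled: float,
    g_ratio: float,
    q_plus: float = 1.0,
    p_target: float = 0.5,
) -> float:
    """SP capacity (1/2 crossing) from the continuous binomial calculation."""
    def log_p(K: float) -> float:
        return sp_log_p_noerror_continuous(N, beta, theta_scaled, g_ratio, K, q_plus)
    if log_p(1.0) < np.log(p_target):
        return 0.0
    return float(optimize.brentq(lambda K: log_p(K) - np.log(p_target), 1.0, 1e18, xtol=1e-6))


def leading_order_capacity(
    N: float,
    beta: float,
    theta_scaled: float,
    g_ratio: float,
    q_plus: float = 1.0,
    p_target: float = 0.5,
) -> dict:
    """Leading-finite-size-correction formula for the SP pattern capacity.

    Derivation (fixed-size patterns, threshold high enough that
    non-selective errors are negligible): approximating the selective-side
    binomial tail by its dominant term times the Stirling prefactor and the
    geometric-series factor, the 1/2 crossing satisfies

        M Phi(theta; theta + Delta) = L0 - ln(1 - r(Delta)),
        L0 = (1/2) ln(M / (2 pi theta(1-theta))) - ln ln 2,
        r  = theta (1 - theta - Delta) / ((1 - theta)(theta + Delta)),

    with M = beta ln N; the margin Delta is obtained by root finding (its
    quadratic-expansion form is ``sqrt(2 theta(1-theta) L0 / M)``).
    Inverting the age dependence g_plus(K) = g_inf (1 + g q_plus e^{-(K-1)/tau})
    then gives

        P(N) = (N/ln N)^2 [ A1 - (A2/(theta - g_inf)) sqrt(L0/M) + ... ],

        A1 = ln(g_inf g q_plus / (theta - g_inf)) / (beta^2 q_plus (1+g)),
        A2 = sqrt(2 theta (1-theta)) / (beta^2 q_plus (1+g)).

    The dominant term scales as (N/ln N)^2: ``scaled_capacity -> A1`` as N
    grows.  Returns the capacity estimate together with A1 and A2; raises if
    the parameters are outside the derivation's regime (``g_inf < theta``
    and margin below the age-1 occupancy).
    """
    lnN = np.log(N)
    M = beta * lnN
    f = beta * lnN / N
    g_inf = 1.0 / (1.0 + g_ratio)
    theta = theta_scaled
    if not g_inf < theta < 1.0:
        raise ValueError("theta must lie in (g_inf, 1) for the leading-order formula")
    L0 = 0.5 * np.log(M / (2 * np.pi * theta * (1 - theta))) - np.log(-np.log(p_target))
    if L0 <= 0:
        raise ValueError("network too small for the asymptotic expansion (L0 <= 0)")
    g1 = g_inf * (1 + g_ratio * q_plus)  # age-1 occupancy
    d_quad = np.sqrt(2 * theta * (1 - theta) * L0 / M)

    def condition(d: float) -> float:
        gp = theta + d
        r = theta * (1 - gp) / ((1 - theta) * gp)
        return M * rate_function(theta, gp) - (L0 - np.log1p(-r))

    d_hi = g1 - theta - 1e-12
    if d_hi <= 0 or condition(d_hi) < 0:
        raise ValueError("threshold margin exceeds the age-1 occupancy: no patterns storable")
    delta = float(optimize.brentq(condition, 1e-12, d_hi, xtol=1e-14))
    tau = 1.0 / (f * f * q_plus * (1 + g_ratio))
    K = 1.0 + tau * np.log(g_inf * g_ratio * q_plus / (theta + delta - g_inf))
    denom = beta**2 * q_plus * (1 + g_ratio)
    A1 = np.log(g_inf * g_ratio * q_plus / (theta - g_inf)) / denom
    A2 = np.sqrt(2 * theta * (1 - theta)) / denom
    return {
        "capacity": float(K),
        "A1": float(A1),
        "A2": float(A2),
        "margin_delta": float(delta),
        "margin_delta_quadratic": float(d_quad),
        "scaled_capacity": float(K / (N / lnN) ** 2),
    }


# ------------------------------------------------------------------ optimisation
def _best_theta(make_model, theta_grid) -> tuple[float, FiniteCapacityResult]:
    best = None
    for th in theta_grid:
        cap = capacity_half(make_model(float(th)))
        if best is None or cap.capacity_P50 > best[1].capacity_P50:
            best = (float(th), cap)
    return best


def optimize_finite(
    N: int,
    model: str = "sp",
    approx: str = "binomial",
    fixed_size: bool = False,
    inhibition_I: float = 0.0,
    q_plus: float = 1.0,
    g_grid=None,
    f_grid=None,
    n_theta: int = 13,
    refine: int = 2,
) -> FiniteCapacityResult:
    """Grid search over (f, theta, g_ratio) maximising the P50 capacity.

    Coarse logarithmic grids followed by local grid refinement around the
    incumbent; deterministic given the grid specification.  Returns the best
    capacity with its optimising parameters recorded in ``params``.
    """
    if N < 100:
        raise ValueError("finite-size optimisation needs N >= 100")
    if model != "sp":
        raise NotImplementedError("parameter optimisation is implemented for the SP model")
    lnN = np.log(N)
    if f_grid is None:
        f_grid = np.geomspace(1.0 * lnN / N, 6.0 * lnN / N, 8)
    if g_grid is None:
        g_grid = np.geomspace(0.8, 6.0, 6)
    best = None  # (capacity, f, theta, g, result)

    def theta_grid_for(g, lo_frac=1.05, hi_frac=0.98, n=n_theta):
        g_inf = 1.0 / (1.0 + g)
        g1 = g_inf * (1 + g * q_plus)
        return np.linspace(g_inf * lo_frac + 1e-6, g1 * hi_frac, n)

    def evaluate(fv, th, g):
        params = PlasticityParams(q_plus=q_plus, g_ratio=float(g))
        m = SPFiniteModel(
            N=N, f=float(fv), theta_scaled=float(th), params=params,
            fixed_size=fixed_size, inhibition_I=inhibition_I, approx=approx,
        )
        return capacity_half(m)

    for g in g_grid:
        for fv in f_grid:
            for th in theta_grid_for(g):
                cap = evaluate(fv, th, g)
                if best is None or cap.capacity_P50 > best[0]:
                    best = (cap.capacity_P50, float(fv), float(th), float(g), cap)
    for _ in range(refine):
        c0, f0, th0, g0, _ = best
        for g in np.geomspace(g0 / 1.5, g0 * 1.5, 5):
            for fv in np.geomspace(f0 / 1.4, min(f0 * 1.4, 0.5), 5):
                for th in np.linspace(th0 * 0.92, th0 * 1.08, 7):
                    g_inf = 1.0 / (1.0 + g)
                    if not g_inf < th < g_inf * (1 + g * q_plus):
                        continue
                    cap = evaluate(fv, th, g)
                    if cap.capacity_P50 > best[0]:
                        best = (cap.capacity_P50, float(fv), float(th), float(g), cap)
    c, fv, th, g, cap = best
    cap.params.update({"f": fv, "theta_scaled": th, "g_ratio": g, "q_plus": q_plus,
                       "fixed_size": fixed_size})
    return cap


def optimal_inhibition(
    N: int,
    f: float,
    params: PlasticityParams,
    theta_grid=None,
    n_inhibition: int = 11,
    approx: str = "binomial",
) -> tuple[float, FiniteCapacityResult]:
    """Inhibition strength maximising the P50 capacity at fluctuating sizes.

    The fields with inhibition are ``h_i - I * n_active``: choosing I between
    the stationary and the tested-pattern occupancies cancels most of the
    field variance caused by pattern-size fluctuations.  Scans a documented
    grid of I in [0, g_plus(1)] (with the threshold re-optimised for every
    I, since inhibition shifts the operating point) and returns the best.
    """
    q_plus, q_minus, g_ratio = params.resolve(f)
    g_inf = 1.0 / (1.0 + g_ratio)
    g1 = g_inf * (1 + g_ratio * q_plus)
    I_grid = np.concatenate([[0.0], np.linspace(0.5 * g_inf, g1, n_inhibition - 1)])
    best = None
    for I in I_grid:
        def make(th, I=I):
            return SPFiniteModel(
                N=N, f=f, theta_scaled=th, params=params,
                fixed_size=False, inhibition_I=float(I), approx=approx,
            )
        # with inhibition the raw threshold compensates the -I*M shift:
        # scan scaled thresholds around (margin + I) * roughly 1
        grid = theta_grid
        if grid is None:
            lo = max(1e-3, g_inf * 1.05 - I)
            hi = g1 * 0.98 - I
            if hi <= lo:
                hi = lo + 0.2
            grid = np.linspace(lo, hi, 13)
            grid = grid[grid > 0]
        th, cap = _best_theta(make, grid)
        if best is None or cap.capacity_P50 > best[1].capacity_P50:
            best = (float(I), cap)
    return best
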