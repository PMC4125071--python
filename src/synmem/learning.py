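"""Binary synaptic matrices under Willshaw, single- and multiple-presentation learning.

Three learning scenarios build an N x N binary connectivity matrix J from
sparse binary patterns:

* **Willshaw**: J_ij = 1 iff some presented pattern had neurons i and j
  co-active.  Potentiation only; deterministic.
* **SP (single presentation)**: patterns arrive once each, in a stream.  At
  each presentation plasticity is presynaptically gated: a synapse whose
  presynaptic neuron is active is potentiated with probability ``q_plus``
  when the postsynaptic neuron is also active, and depressed with
  probability ``q_minus`` when it is not.  Synapses with silent presynaptic
  neurons are untouched.  This makes the network a palimpsest: old memories
  fade as new ones are written.
* **MP (multiple presentations)**: noisy instances of a fixed set of
  prototypes are presented over and over in random order; in the
  slow-learning regime (small transition probabilities) the synaptic
  occupancies converge to stationary values that depend on the
  depression-potentiation ratio and the presentation noise.

The per-synapse statistics (probability of being potentiated, for pairs
selective / non-selective in a tested pattern) are exposed as
``OccupancyStats`` and feed the capacity theory modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from ._rng import as_generator
from .patterns import PatternSet, noisy_instance

__all__ = [
    "PlasticityParams",
    "SynapticMatrix",
    "OccupancyStats",
    "learn_willshaw",
    "willshaw_occupancy",
    "present_pattern",
    "learn_sp",
    "sp_occupancy",
    "learn_mp",
    "mp_occupancy",
    "mp_occupancy_finite",
]


# --------------------------------------------------------------------------- params
@dataclass(frozen=True)
class PlasticityParams:
    """Stochastic plasticity parameters.

    ``q_plus`` (``q_minus``) is the probability that an eligible synapse is
    potentiated (depressed) at one pattern presentation.  The
    depression-potentiation ratio ``g_ratio`` is the ratio between the
    expected number of depressing and potentiating events per presentation,

        g_ratio = q_minus (1 - f) / (q_plus f),

    so specifying any two of (q_minus, g_ratio, f) fixes the third.  If both
    ``q_minus`` and ``g_ratio`` are supplied they must be consistent with the
    coding level; inconsistency raises instead of silently renormalising.
    """

    q_plus: float
    q_minus: float | None = None
    g_ratio: float | None = None
    noise_x: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.q_plus <= 1.0:
            raise ValueError(f"q_plus must be in [0, 1], got {self.q_plus}")
        if self.q_minus is not None and not 0.0 <= self.q_minus <= 1.0:
            raise ValueError(f"q_minus must be in [0, 1], got {self.q_minus}")
        if self.g_ratio is not None and self.g_ratio < 0:
            raise ValueError(f"g_ratio must be >= 0, got {self.g_ratio}")
        if not 0.0 <= self.noise_x <= 1.0:
            raise ValueError(f"noise_x must be in [0, 1], got {self.noise_x}")
        if self.q_minus is None and self.g_ratio is None:
            raise ValueError("one of q_minus or g_ratio must be given")

    def resolve(self, f: float) -> tuple[float, float, float]:
        """Return consistent ``(q_plus, q_minus, g_ratio)`` at coding level f."""
        if self.q_minus is not None and self.g_ratio is not None:
            implied = self.q_minus * (1 - f) / (self.q_plus * f) if self.q_plus > 0 else np.inf
            if not np.isclose(implied, self.g_ratio, rtol=1e-8, atol=1e-12):
                raise ValueError(
                    f"q_minus={self.q_minus} implies g_ratio={implied:.6g} at f={f}, "
                    f"inconsistent with supplied g_ratio={self.g_ratio}"
                )
            return self.q_plus, self.q_minus, self.g_ratio
        if self.q_minus is not None:
            g = self.q_minus * (1 - f) / (self.q_plus * f) if self.q_plus > 0 else np.inf
            return self.q_plus, self.q_minus, g
        q_minus = self.g_ratio * self.q_plus * f / (1 - f)
        if q_minus > 1:
            raise ValueError(
                f"g_ratio={self.g_ratio} at f={f} requires q_minus={q_minus:.3g} > 1"
            )
        return self.q_plus, q_minus, self.g_ratio


@dataclass(frozen=True)
class OccupancyStats:
    """Potentiation probabilities of synapse classes for a tested pattern.

    ``g_plus``: probability that a synapse between two neurons selective in
    the tested pattern is potentiated; ``g_minus``: the same for synapses
    whose presynaptic neuron is selective but postsynaptic is not (the pairs
    that feed non-selective neurons during retrieval); ``g_inf``: stationary
    potentiated fraction of the whole matrix.
    """

    g_inf: float
    g_plus: float
    g_minus: float
    age_K: int | None = None
    tau_eff: float | None = None


# --------------------------------------------------------------------------- matrix
@dataclass
class SynapticMatrix:
    """Binary connectivity with learning-rule provenance.  Diagonal is 0."""

    J: np.ndarray
    rule: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.J = np.ascontiguousarray(self.J, dtype=np.uint8)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError("J must be square")
        np.fill_diagonal(self.J, 0)

    @property
    def N(self) -> int:
        return self.J.shape[0]

    @property
    def potentiated_fraction(self) -> float:
        n = self.N
        return float(self.J.sum() / (n * (n - 1)))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        packed = np.packbits(self.J, axis=1, bitorder="little")
        path.with_suffix(".bin").write_bytes(packed.tobytes())
        meta = {"N": self.N, "rule": self.rule, "provenance": self.provenance}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SynapticMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        n = meta["N"]
        n_bytes = (n + 7) // 8
        raw = np.frombuffer(path.with_suffix(".bin").read_bytes(), dtype=np.uint8)
        J = np.unpackbits(raw.reshape(n, n_bytes), axis=1, bitorder="little")[:, :n]
        return cls(J=J, rule=meta["rule"], provenance=meta["provenance"])


# --------------------------------------------------------------------------- Willshaw
def learn_willshaw(patterns: PatternSet) -> SynapticMatrix:
    """Willshaw rule: potentiate every synapse co-activated by some pattern."""
    N = patterns.N
    J = np.zeros((N, N), dtype=np.uint8)
    for mu in range(patterns.P):
        sel = patterns.selective_indices(mu)
        J[np.ix_(sel, sel)] = 1
    np.fill_diagonal(J, 0)
    return SynapticMatrix(J=J, rule="willshaw", provenance={"P": patterns.P, "f": patterns.f})


def willshaw_occupancy(f: float, P: int) -> OccupancyStats:
    """Analytic Willshaw occupancies after storing P patterns at coding level f.

    A synapse between two neurons selective in the tested pattern is
    potentiated with certainty; any other synapse is potentiated iff at least
    one of the remaining patterns co-activated its two neurons:
    ``g_minus = 1 - (1 - f^2)^P``.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"coding level f must be in (0, 1), got {f}")
    if P < 0:
        raise ValueError(f"P must be >= 0, got {P}")
    g0 = -np.expm1(P * np.log1p(-f * f))
    return OccupancyStats(g_inf=float(g0), g_plus=1.0, g_minus=float(g0))


# --------------------------------------------------------------------------- SP
def _bernoulli_positions(rng: np.random.Generator, n_cells: int, q: float) -> np.ndarray:
    """Indices of an i.i.d. Bernoulli(q) mask over ``n_cells`` cells.

    Uses geometric gap sampling: exact and O(#hits) instead of O(n_cells).
    """
    if q <= 0.0 or n_cells == 0:
        return np.empty(0, dtype=np.int64)
    if q >= 1.0:
        return np.arange(n_cells, dtype=np.int64)
    mean = n_cells * q
    size = int(mean + 6.0 * np.sqrt(mean) + 16)
    gaps = rng.geometric(q, size=size)
    pos = np.cumsum(gaps) - 1
    while pos[-1] < n_cells - 1:  # rare: extend until past the end
        extra = rng.geometric(q, size=size)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
    return pos[pos < n_cells]


def present_pattern(
    J: np.ndarray,
    active: np.ndarray,
    q_plus: float,
    q_minus: float,
    rng: np.random.Generator,
) -> None:
    """Apply one presynaptically gated stochastic update of J in place.

    ``active`` are the indices of neurons active in the presented pattern.
    Synapses (post i, pre j) with j active are eligible: potentiated to 1
    with probability ``q_plus`` if i is active, depressed to 0 with
    probability ``q_minus`` if i is silent.  The diagonal is never touched.
    """
    act = np.asarray(active)
    m = act.size
    if m == 0:
        return
    N = J.shape[0]
    # potentiation on the active x active block
    if q_plus >= 1.0:
        J[np.ix_(act, act)] = 1
    elif q_plus > 0.0:
        mask = rng.random((m, m)) < q_plus
        J[np.ix_(act, act)] |= mask
    J[act, act] = 0  # keep diagonal silent
    # depression: post anywhere, pre active; cells with active post are the
    # potentiation class and are filtered out after exact Bernoulli sampling
    pos = _bernoulli_positions(rng, N * m, q_minus)
    if pos.size:
        rows = pos // m
        cols = act[pos % m]
        is_active = np.zeros(N, dtype=bool)
        is_active[act] = True
        keep = ~is_active[rows]
        J[rows[keep], cols[keep]] = 0


def stationary_init(N: int, g_inf: float, rng: np.random.Generator) -> np.ndarray:
    """J drawn i.i.d. Bernoulli(g_inf), diagonal zero (stationary marginals)."""
    J = (rng.random((N, N)) < g_inf).astype(np.uint8)
    np.fill_diagonal(J, 0)
    return J


def learn_sp(
    pattern_stream: PatternSet,
    params: PlasticityParams,
    seed=None,
    init: str | np.ndarray = "stationary",
) -> SynapticMatrix:
    """Present a stream of patterns once each through the stochastic SP rule.

    ``init`` is ``"stationary"`` (i.i.d. Bernoulli at the stationary
    potentiated fraction — the regime the capacity theory describes),
    ``"zero"``, or an explicit matrix.
    """
    N = pattern_stream.N
    q_plus, q_minus, g_ratio = params.resolve(pattern_stream.f)
    rng = as_generator(seed)
    if isinstance(init, np.ndarray):
        J = np.array(init, dtype=np.uint8, copy=True)
    elif init == "zero":
        J = np.zeros((N, N), dtype=np.uint8)
    elif init == "stationary":
        g_inf = sp_occupancy(1, params, pattern_stream.f).g_inf
        J = stationary_init(N, g_inf, rng)
    else:
        raise ValueError(f"unknown init {init!r}")
    for mu in range(pattern_stream.P):
        present_pattern(J, pattern_stream.selective_indices(mu), q_plus, q_minus, rng)
    return SynapticMatrix(
        J=J,
        rule="sp",
        provenance={
            "q_plus": q_plus,
            "q_minus": q_minus,
            "g_ratio": g_ratio,
            "n_presented": pattern_stream.P,
            "f": pattern_stream.f,
        },
    )


def sp_pair_probs(f: float, N: int | None = None, fixed_size: bool = False) -> tuple[float, float]:
    """Per-presentation probabilities that a synapse's (pre, post) pair is
    (active, active) resp. (active, silent) in a random pattern.

    For Bernoulli patterns these are ``f^2`` and ``f(1-f)``; for fixed-size
    patterns (exactly M = f N selective neurons) the exact hypergeometric
    pair probabilities are used.
    """
    if fixed_size:
        if N is None:
            raise ValueError("fixed_size pair probabilities need N")
        M = round(f * N)
        p_both = M * (M - 1) / (N * (N - 1))
        p_pre_only = M * (N - M) / (N * (N - 1))
        return p_both, p_pre_only
    return f * f, f * (1 - f)


def sp_occupancy(
    age_K: int,
    params: PlasticityParams,
    f: float,
    N: int | None = None,
    fixed_size: bool = False,
) -> OccupancyStats:
    """Occupancies for a pattern of age K under the SP rule.

    Each synapse is a two-state Markov chain with per-presentation
    potentiation rate ``a = P(pair co-active) q_plus`` and depression rate
    ``b = P(pre active, post silent) q_minus``; hence

        g_inf     = a / (a + b),
        g_plus(K) = g_inf + (1 - g_inf) q_plus lambda^(K-1),
        lambda    = 1 - a - b,

    i.e. the imprint left at storage decays geometrically with an effective
    time constant ``tau_eff = -1/ln(lambda)`` (= ``1/(f^2 q_plus (1+g))`` in
    the sparse limit).  ``g_minus`` carries the (tiny) depression imprint the
    tested pattern leaves on pre-selective/post-silent pairs,
    ``g_inf (1 - q_minus lambda^(K-1))``; in the sparse limit it equals
    ``g_inf``.
    """
    if age_K < 1:
        raise ValueError(f"pattern age must be >= 1, got {age_K}")
    q_plus, q_minus, g_ratio = params.resolve(f)
    a_p, a_d = sp_pair_probs(f, N, fixed_size)
    a = a_p * q_plus
    b = a_d * q_minus
    if a + b == 0:
        raise ValueError("no plasticity: q_plus and q_minus both zero at this coding level")
    g_inf = a / (a + b)
    lam = 1.0 - a - b
    decay = lam ** (age_K - 1)
    g_plus = g_inf + (1 - g_inf) * q_plus * decay
    g_minus = g_inf * (1 - q_minus * decay)
    tau_eff = -1.0 / np.log(lam) if lam < 1.0 else np.inf
    return OccupancyStats(
        g_inf=float(g_inf),
        g_plus=float(g_plus),
        g_minus=float(g_minus),
        age_K=age_K,
        tau_eff=float(tau_eff),
    )


# --------------------------------------------------------------------------- MP
def learn_mp(
    prototypes: PatternSet,
    params: PlasticityParams,
    n_presentations: int,
    seed=None,
    init: str | np.ndarray = "zero",
) -> SynapticMatrix:
    """Present noisy prototype instances repeatedly through the SP update rule.

    At each step a prototype is chosen uniformly at random, corrupted at
    mixing level ``params.noise_x``, and presented.  With ``noise_x = 0``,
    ``g_ratio -> 0`` and ``q_plus = 1`` from an all-zero matrix this
    reproduces the Willshaw rule exactly.
    """
    if n_presentations < 0:
        raise ValueError(f"n_presentations must be >= 0, got {n_presentations}")
    N = prototypes.N
    q_plus, q_minus, g_ratio = params.resolve(prototypes.f)
    rng = as_generator(seed)
    if isinstance(init, np.ndarray):
        J = np.array(init, dtype=np.uint8, copy=True)
    elif init == "zero":
        J = np.zeros((N, N), dtype=np.uint8)
    elif init == "stationary":
        g0 = mp_occupancy(params, f=prototypes.f, n_prototypes=prototypes.P).g_minus
        J = stationary_init(N, g0, rng)
    else:
        raise ValueError(f"unknown init {init!r}")
    for _ in range(n_presentations):
        mu = int(rng.integers(prototypes.P))
        shown = noisy_instance(prototypes.patterns[mu], params.noise_x, prototypes.f, rng)
        present_pattern(J, np.flatnonzero(shown), q_plus, q_minus, rng)
    return SynapticMatrix(
        J=J,
        rule="mp",
        provenance={
            "q_plus": q_plus,
            "q_minus": q_minus,
            "g_ratio": g_ratio,
            "noise_x": params.noise_x,
            "n_presented": n_presentations,
            "P": prototypes.P,
            "f": prototypes.f,
        },
    )


def _mp_rho(k: np.ndarray, omega: float, g_ratio: float, noise_x: float) -> np.ndarray:
    """Stationary potentiation probability of a synapse whose neurons are
    co-selective in ``k`` prototypes, in the sparse slow-learning limit."""
    x = noise_x
    num = k * (1 - x) ** 2 / omega + x * (2 - x)
    den = num + g_ratio
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return rho


def mp_occupancy(
    params: PlasticityParams,
    f: float | None = None,
    n_prototypes: int | None = None,
    omega: float | None = None,
) -> OccupancyStats:
    """Slow-learning stationary occupancies for the MP scenario (sparse limit).

    The load enters through ``omega = P f^2`` (= ``alpha beta^2``), the mean
    number of prototypes co-selecting a given synapse.  Conditional on a
    synapse's two neurons being co-selective in ``k`` prototypes, its
    stationary potentiation probability balances the potentiation rate
    (presentations of those k prototypes, plus noise-driven co-activations)
    against the depression rate:

        rho(k) = (k(1-x)^2/omega + x(2-x)) / (k(1-x)^2/omega + x(2-x) + g).

    ``g_minus`` averages rho(k) over k ~ Poisson(omega); ``g_plus`` over
    k + 1 (the tested prototype co-selects the pair by construction).  At
    x = 1, g_plus = g_minus; at x = 0 with g -> 0 the Willshaw occupancies
    (g_plus = 1, g_minus = 1 - e^-omega) are recovered exactly.
    """
    if omega is None:
        if f is None or n_prototypes is None:
            raise ValueError("give omega, or both f and n_prototypes")
        omega = n_prototypes * f * f
    if omega <= 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    _, _, g_ratio = (params.q_plus, params.q_minus, params.g_ratio) if params.g_ratio is not None \
        else params.resolve(f if f is not None else 0.5)
    if g_ratio is None:
        raise ValueError("MP occupancy needs g_ratio (or q_minus with f)")
    x = params.noise_x
    kmax = int(omega + 12 * np.sqrt(omega) + 30)
    k = np.arange(kmax + 1)
    pk = sps.poisson.pmf(k, omega)
    pk = pk / pk.sum()
    g_minus = float(pk @ _mp_rho(k, omega, g_ratio, x))
    g_plus = float(pk @ _mp_rho(k + 1, omega, g_ratio, x))
    return OccupancyStats(g_inf=g_minus, g_plus=g_plus, g_minus=g_minus)


def mp_occupancy_finite(params: PlasticityParams, f: float, P: int) -> OccupancyStats:
    """Exact finite-(P, f) slow-learning occupancies, by enumeration.

    Exact counterpart of :func:`mp_occupancy` used for validation: enumerates
    the joint distribution of how many prototypes co-select the pair (k),
    select only the postsynaptic (l_i) or only the presynaptic (l_j) neuron,
    and balances the exact per-presentation potentiation/depression rates.
    """
    q_plus, q_minus, g_ratio = params.resolve(f)
    x = params.noise_x
    A = 1 - x + x * f  # P(neuron shown active | selective in shown prototype)
    B = x * f          # P(neuron shown active | not selective)

    def axis(nb: int, p: float) -> np.ndarray:
        # the multinomial counts concentrate around nb*p; a 10-sd window
        # (always including 0) carries all but ~1e-20 of the mass
        hi = min(nb, int(nb * p + 10 * np.sqrt(max(nb * p * (1 - p), 1.0)) + 5))
        return np.arange(hi + 1)

    def class_average(extra_both: int, extra_lj: int) -> float:
        # background counts over the P-1 prototypes other than the tested one;
        # the tested prototype contributes `extra_*` to the pair's class totals
        nb = P - 1
        k, li, lj = np.meshgrid(
            axis(nb, f * f), axis(nb, f * (1 - f)), axis(nb, f * (1 - f)),
            indexing="ij",
        )
        valid = k + li + lj <= nb
        rest = np.where(valid, nb - k - li - lj, 0)
        p2, p1 = f * f, f * (1 - f)
        p0 = (1 - f) ** 2
        with np.errstate(divide="ignore"):
            logw = (
                gammaln(nb + 1)
                - gammaln(k + 1) - gammaln(li + 1) - gammaln(lj + 1) - gammaln(rest + 1)
                + k * np.log(p2)
                + (li + lj) * np.log(p1)
                + rest * np.log(p0)
            )
        w = np.where(valid, np.exp(logw), 0.0)
        kk = k + extra_both
        ljt = lj + extra_lj
        none = P - kk - li - ljt
        r_pot = q_plus * (kk * A * A + (li + ljt) * A * B + none * B * B) / P
        r_dep = q_minus * (
            kk * A * (1 - A) + ljt * A * (1 - B) + li * B * (1 - A) + none * B * (1 - B)
        ) / P
        den = r_pot + r_dep
        rho = np.where(den > 0, r_pot / np.where(den > 0, den, 1.0), 0.0)
        return float((w * rho).sum() / w.sum())

    g_minus = class_average(0, 1)  # pre selective in tested pattern, post not
    g_plus = class_average(1, 0)   # both selective
    return OccupancyStats(g_inf=g_minus, g_plus=g_plus, g_minus=g_minus)
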