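"""Threshold retrieval dynamics: fields, synchronous updates, fixed points, overlaps.

A network state is a binary vector s.  Neuron i receives the integer field

    h_i = sum_j J_ij s_j  -  I * sum_j s_j,

where the second term is an optional instantaneous linear inhibitory
feedback proportional to the number of currently active neurons.  The
synchronous update activates neuron i iff ``h_i > theta_scaled * f * N``
(strict inequality; a neuron exactly at threshold goes silent).  The scaled
threshold ``theta_scaled`` is a constant of order one: fields of selective
neurons are sums of ~fN terms, so the raw threshold scales with fN.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = [
    "RetrievalConfig",
    "RetrievalResult",
    "raw_threshold",
    "local_fields",
    "synchronous_update",
    "is_exact_fixed_point",
    "overlap",
    "retrieve",
    "wilson_interval",
]


@dataclass(frozen=True)
class RetrievalConfig:
    """Parameters of the retrieval test.

    ``theta_scaled``: dimensionless activation threshold (raw threshold is
    ``theta_scaled * f * N``).  ``inhibition_I``: uniform inhibition strength
    (0 disables it).  ``mode`` selects a one-step stability check or full
    iteration to a fixed point.
    """

    theta_scaled: float
    f: float
    inhibition_I: float = 0.0
    max_iters: int = 100
    mode: str = "iterate_to_fixed_point"

    def __post_init__(self):
        if self.theta_scaled <= 0:
            raise ValueError("theta_scaled must be > 0")
        if not 0.0 < self.f < 1.0:
            raise ValueError("f must be in (0, 1)")
        if self.inhibition_I < 0:
            raise ValueError("inhibition_I must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.mode not in ("single_step_check", "iterate_to_fixed_point"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RetrievalResult:
    final_state: np.ndarray
    overlap_m: float
    exact: bool
    converged: bool
    n_iters: int


def raw_threshold(theta_scaled: float, f: float, N: int) -> float:
    """Raw field threshold corresponding to a scaled threshold."""
    return theta_scaled * f * N


def local_fields(J: np.ndarray, state: np.ndarray, inhibition_I: float = 0.0) -> np.ndarray:
    """Fields h_i = sum_j J_ij s_j - I * (number of active neurons).

    The diagonal of J is identically zero, so no self-term contributes.
    Computed by gathering the columns of the active neurons, which is fast
    for the sparse states used throughout.
    """
    s = np.asarray(state)
    if s.shape[0] != J.shape[1]:
        raise ValueError(f"state length {s.shape[0]} != N = {J.shape[1]}")
    active = np.flatnonzero(s)
    if active.size == 0:
        return np.zeros(J.shape[0], dtype=float)
    h = J[:, active].sum(axis=1).astype(float)
    if inhibition_I > 0.0:
        h -= inhibition_I * active.size
    return h


def synchronous_update(J: np.ndarray, state: np.ndarray, config: RetrievalConfig) -> np.ndarray:
    """One parallel threshold update of every neuron (ties go silent)."""
    thr = raw_threshold(config.theta_scaled, config.f, J.shape[0])
    h = local_fields(J, state, config.inhibition_I)
    return (h > thr).astype(np.uint8)


def is_exact_fixed_point(J: np.ndarray, pattern: np.ndarray, config: RetrievalConfig) -> bool:
    """True iff one synchronous update maps ``pattern`` to itself."""
    new = synchronous_update(J, pattern, config)
    return bool(np.array_equal(new, np.asarray(pattern, dtype=np.uint8)))


def overlap(state: np.ndarray, pattern: np.ndarray, f: float | None = None) -> float:
    """Normalised overlap m between a state and a tested pattern.

    With M selective neurons in the pattern and coding level f,

        m = (1 / (M (1 - f))) * sum_i (eta_i - f) s_i,

    which is 1 when the state equals the pattern, 0 for the all-silent
    state, and penalises spurious active neurons outside the pattern.  If
    ``f`` is not given, the pattern's own activity fraction M/N is used.
    """
    eta = np.asarray(pattern, dtype=float)
    s = np.asarray(state, dtype=float)
    M = eta.sum()
    if M == 0:
        raise ValueError("tested pattern has no selective neurons")
    if f is None:
        f = M / eta.size
    return float(((eta - f) @ s) / (M * (1.0 - f)))


def retrieve(
    J: np.ndarray,
    init: np.ndarray,
    tested_pattern: np.ndarray,
    config: RetrievalConfig,
) -> RetrievalResult:
    """Iterate synchronous updates from ``init`` until a fixed point.

    Stops at a fixed point, at a period-2 cycle (``converged=False``), or at
    ``max_iters``.  The overlap of the final state with ``tested_pattern``
    is reported; ``exact`` flags final state == tested pattern.
    """
    tested = np.asarray(tested_pattern, dtype=np.uint8)
    prev = np.asarray(init, dtype=np.uint8)
    prev2 = None
    converged = False
    n_iters = 0
    for n_iters in range(1, config.max_iters + 1):
        cur = synchronous_update(J, prev, config)
        if np.array_equal(cur, prev):
            converged = True
            break
        if prev2 is not None and np.array_equal(cur, prev2):
            break  # period-2 cycle
        prev2, prev = prev, cur
    final = cur
    return RetrievalResult(
        final_state=final,
        overlap_m=overlap(final, tested, config.f),
        exact=bool(np.array_equal(final, tested)),
        converged=converged,
        n_iters=n_iters,
    )


def wilson_interval(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)
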