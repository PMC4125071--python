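"""Random sparse memory patterns and their noisy presentations.

Stored memories are binary activity patterns over ``N`` neurons.  Each neuron
is selective for a given memory with probability ``f`` (the coding level);
alternatively every pattern can be constrained to exactly ``M_fixed``
selective neurons.  In the sparse-coding regime studied throughout the
package the coding level scales as ``f = beta * ln(N) / N`` with ``beta`` of
order one, so ``beta`` is the natural dimensionless knob.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rng import as_generator

__all__ = [
    "PatternSet",
    "NoisySpec",
    "coding_from_beta",
    "beta_from_coding",
    "generate_prototypes",
    "noisy_instance",
]


def coding_from_beta(N: int, beta: float) -> float:
    """Coding level ``f = beta * ln(N) / N``.

    Raises ``ValueError`` if the result falls outside the open interval (0, 1).
    """
    if N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    f = beta * np.log(N) / N
    if not 0.0 < f < 1.0:
        raise ValueError(f"beta={beta} gives coding level f={f}, outside (0, 1)")
    return float(f)


def beta_from_coding(N: int, f: float) -> float:
    """Inverse of :func:`coding_from_beta`."""
    if not 0.0 < f < 1.0:
        raise ValueError(f"coding level f must be in (0, 1), got {f}")
    return float(f * N / np.log(N))


@dataclass(frozen=True)
class NoisySpec:
    """How a stored prototype is corrupted before being presented.

    ``noise_x`` is a mixing level in [0, 1]: each neuron independently keeps
    its prototype state with probability ``1 - x`` and is redrawn as a fresh
    Bernoulli(f) variable with probability ``x``.  At ``x = 0`` the
    presentation is the prototype itself; at ``x = 1`` it is statistically a
    fresh random pattern, uncorrelated with the prototype.
    """

    noise_x: float
    prototype_index: int = 0

    def __post_init__(self):
        if not 0.0 <= self.noise_x <= 1.0:
            raise ValueError(f"noise_x must be in [0, 1], got {self.noise_x}")


@dataclass
class PatternSet:
    """A set of ``P`` binary memory patterns over ``N`` neurons.

    Attributes
    ----------
    patterns : (P, N) uint8 array with entries 0/1.
    f : nominal coding level.
    beta : scaled coding parameter ``f N / ln N``.
    fixed_size : if True, every pattern has exactly ``m_fixed`` selective
        neurons; otherwise selectivity is i.i.d. Bernoulli(f).
    """

    patterns: np.ndarray
    f: float
    fixed_size: bool = False
    m_fixed: int | None = None
    seed: int | None = None
    beta: float = field(init=False)

    def __post_init__(self):
        self.patterns = np.ascontiguousarray(self.patterns, dtype=np.uint8)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be a (P, N) matrix")
        if not np.isin(self.patterns, (0, 1)).all():
            raise ValueError("pattern entries must be 0 or 1")
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"coding level f must be in (0, 1), got {self.f}")
        if self.fixed_size:
            if self.m_fixed is None:
                raise ValueError("fixed_size requires m_fixed")
            if (self.row_sums != self.m_fixed).any():
                raise ValueError("fixed_size set but row sums differ from m_fixed")
        self.beta = beta_from_coding(self.N, self.f)

    @property
    def N(self) -> int:
        return self.patterns.shape[1]

    @property
    def P(self) -> int:
        return self.patterns.shape[0]

    @property
    def row_sums(self) -> np.ndarray:
        """Number of selective neurons per pattern (M per pattern)."""
        return self.patterns.sum(axis=1)

    # alias used in a few call sites for readability
    selective_counts = row_sums

    def selective_indices(self, mu: int) -> np.ndarray:
        return np.flatnonzero(self.patterns[mu])

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """Write bit-packed patterns plus a JSON metadata sidecar.

        ``path`` is the stem; ``<path>.bin`` holds row-major bit-packed
        patterns (little-endian, rows padded to whole bytes) and
        ``<path>.json`` the metadata needed to reconstruct them.
        """
        path = Path(path)
        packed = np.packbits(self.patterns, axis=1, bitorder="little")
        path.with_suffix(".bin").write_bytes(packed.tobytes())
        meta = {
            "N": self.N,
            "P": self.P,
            "f": self.f,
            "beta": self.beta,
            "fixed_size": self.fixed_size,
            "m_fixed": self.m_fixed,
            "seed": self.seed,
            "created_by": "synmem.patterns.PatternSet",
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PatternSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        n_bytes = (meta["N"] + 7) // 8
        raw = np.frombuffer(path.with_suffix(".bin").read_bytes(), dtype=np.uint8)
        packed = raw.reshape(meta["P"], n_bytes)
        patterns = np.unpackbits(packed, axis=1, bitorder="little")[:, : meta["N"]]
        return cls(
            patterns=patterns,
            f=meta["f"],
            fixed_size=meta["fixed_size"],
            m_fixed=meta["m_fixed"],
            seed=meta["seed"],
        )


def _resolve_coding(N: int, f=None, beta=None, m_fixed=None) -> tuple[float, bool, int | None]:
    given = [v is not None for v in (f, beta, m_fixed)]
    if sum(given) != 1:
        raise ValueError("exactly one of f, beta, m_fixed must be given")
    if beta is not None:
        return coding_from_beta(N, beta), False, None
    if m_fixed is not None:
        if not 0 < m_fixed <= N:
            raise ValueError(f"m_fixed must be in [1, N], got {m_fixed}")
        fval = m_fixed / N
        if not 0.0 < fval < 1.0:
            raise ValueError(f"m_fixed={m_fixed} gives degenerate coding level {fval}")
        return fval, True, int(m_fixed)
    if not 0.0 < f < 1.0:
        raise ValueError(f"coding level f must be in (0, 1), got {f}")
    return float(f), False, None


def generate_prototypes(
    N: int,
    P: int,
    *,
    f: float | None = None,
    beta: float | None = None,
    m_fixed: int | None = None,
    seed=None,
) -> PatternSet:
    """Draw ``P`` random memory prototypes over ``N`` neurons.

    Exactly one coding specification must be given: the coding level ``f``,
    the scaled parameter ``beta`` (then ``f = beta ln N / N``), or ``m_fixed``
    (every pattern gets a uniformly drawn set of exactly ``m_fixed`` selective
    neurons).  Reproducible given ``seed``.
    """
    if N <= 0 or P < 0:
        raise ValueError(f"need N > 0 and P >= 0, got N={N}, P={P}")
    fval, fixed, m = _resolve_coding(N, f=f, beta=beta, m_fixed=m_fixed)
    rng = as_generator(seed)
    if fixed:
        patterns = np.zeros((P, N), dtype=np.uint8)
        for mu in range(P):
            patterns[mu, rng.choice(N, size=m, replace=False)] = 1
    else:
        patterns = (rng.random((P, N)) < fval).astype(np.uint8)
    return PatternSet(
        patterns=patterns,
        f=fval,
        fixed_size=fixed,
        m_fixed=m,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def noisy_instance(prototype: np.ndarray, spec: NoisySpec | float, f: float, seed=None) -> np.ndarray:
    """A corrupted presentation of ``prototype`` at mixing level ``x``.

    Each neuron keeps its prototype state with probability ``1 - x`` and is
    resampled as Bernoulli(f) with probability ``x``, independently.  Hence
    ``P(s_i = 1 | proto_i = 1) = 1 - x + x f`` and
    ``P(s_i = 1 | proto_i = 0) = x f``: the presentation is the prototype
    verbatim at ``x = 0`` and an independent random pattern at ``x = 1``.
    """
    x = spec.noise_x if isinstance(spec, NoisySpec) else float(spec)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"noise_x must be in [0, 1], got {x}")
    proto = np.asarray(prototype, dtype=np.uint8)
    if x == 0.0:
        return proto.copy()
    rng = as_generator(seed)
    resample = rng.random(proto.shape) < x
    fresh = (rng.random(proto.shape) < f).astype(np.uint8)
    return np.where(resample, fresh, proto).astype(np.uint8)
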