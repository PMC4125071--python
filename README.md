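# synmem — memory capacity of networks with stochastic binary synapses

`synmem` is a Python library for the storage capacity of fully connected
recurrent networks of `N` binary neurons whose synapses are binary (0/1)
and learn stochastically.  It is aimed at computational neuroscientists
studying attractor memory: it answers how many sparse activity patterns
such a network can hold as fixed points of its threshold dynamics, and how
many bits per synapse that represents, for three learning scenarios —

* **Willshaw**: potentiation-only, patterns written once and forever;
* **SP** (single presentation): one-shot stochastic potentiation/depression,
  giving a palimpsest that learns continuously while old memories fade;
* **MP** (multiple presentations): noisy versions of prototypes shown
  repeatedly in the slow-learning regime, trading capacity for
  generalisation.

## The theory in brief

Patterns have coding level `f = beta ln N / N` (sparse limit).  A stored
pattern is retrieved if it is a fixed point of the synchronous dynamics
`s_i <- H(sum_j J_ij s_j - theta f N)`.  The fields of the pattern's ~`fN`
selective neurons and of the ~`N` background neurons are binomial sums with
means set by the synaptic occupancies `g+` (selective pairs) and `g-`
(background), so the probability a neuron ends on the wrong side of the
threshold decays with the binomial rate function

    Phi(x; g) = x ln(x/g) + (1-x) ln((1-x)/(1-g)).

With a load of `P = alpha (N/ln N)^2` patterns the network stores
`i = alpha beta / ln 2` bits per synapse, and retrievability requires
`Phi(theta; g+) > 0` and `beta Phi(theta; g-) > 1`.  Saturating both and
optimising over parameters yields `i = ln 2` bits/synapse for Willshaw (at
half the synapses potentiated), `i ~ 0.083` for the SP palimpsest, and the
full capacity/generalisation trade-off for MP.  The package also implements
the finite-`N` calculation (exact binomial tails, pattern-size averaging,
Gaussian and covariance-corrected Gaussian approximations, uniform
inhibition) which shows that realistic network sizes reach only a fraction
of the asymptotic capacity, and a large-scale simulator that verifies it.

## Worked example

```python
import numpy as np
from synmem import (PlasticityParams, SPFiniteModel, capacity_half,
                    optimize_asymptotic, sp_asymptotic_optimum)

# asymptotic optima
print(optimize_asymptotic("willshaw").info_bits)   # 0.6931471805599454
opt = sp_asymptotic_optimum()
print(opt.info_bits, opt.params["g_ratio"])        # 0.08271187067763329 2.456224268687527

# finite-size capacity at the same SP parameters, N = 10^4
N = 10_000
f = opt.beta * np.log(N) / N
model = SPFiniteModel(N=N, f=f, theta_scaled=opt.theta,
                      params=PlasticityParams(q_plus=1.0,
                                              g_ratio=opt.params["g_ratio"]),
                      fixed_size=True)
print(capacity_half(model).capacity_P50)           # 9073
print(opt.pattern_capacity(N))                     # 26879.662...
```

The Willshaw network stores ln 2 ≈ 0.693 bits per synapse; one-shot
learning costs a factor ~8.4 (0.0827 bits/synapse); and at `N = 10^4` the
finite network holds 9073 patterns — only ~34% of the 26880 predicted by
the large-`N` formula, because the finite-size corrections shrink only like
`sqrt(ln M / M)` with `M = f N` a few tens of neurons.

The `examples/` directory contains one short script per capability
(asymptotic curves, palimpsest trade-off, MP generalisation, finite-size
effects, simulated retrieval, inhibition).  A thin CLI exposes the same
machinery: `capacity theory --model sp`, `capacity simulate --n 2000`,
`capacity figure --id fig4 --scale 0.5 --seed 1 --out results`, and
`capacity run config.yaml`.

## Layout

| module | contents |
|---|---|
| `synmem.patterns` | sparse pattern generation, noisy presentations, bit-packed I/O |
| `synmem.learning` | Willshaw/SP/MP rules and occupancy statistics |
| `synmem.dynamics` | fields, synchronous updates, fixed points, overlap |
| `synmem.theory_asymptotic` | rate functions, saturation, information optima |
| `synmem.theory_finite` | finite-N retrieval probability, capacity, inhibition |
| `synmem.simulate` | large-N stream simulator and retrieval curves |
| `synmem.experiments` / `synmem.cli` | scripted protocols, YAML configs, CLI |

`docs/methods.md` documents the model, every formula implemented, numerical
conventions, and known limitations.
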