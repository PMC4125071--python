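"""Finite-size effects: real networks reach a fraction of the asymptotic capacity.

Evaluates the binomial finite-size retrieval calculation for the SP model
at the asymptotically optimal parameters and compares the resulting P50
capacity with the large-N prediction alpha (N/ln N)^2.
"""
import numpy as np

from synmem import PlasticityParams, SPFiniteModel, capacity_half, sp_asymptotic_optimum

opt = sp_asymptotic_optimum()
params = PlasticityParams(q_plus=opt.params["q_plus"], g_ratio=opt.params["g_ratio"])
print("      N    finite P50    asymptotic    ratio")
for N in (10_000, 20_000, 40_000):
    f = opt.beta * np.log(N) / N
    model = SPFiniteModel(N=N, f=f, theta_scaled=opt.theta, params=params,
                          fixed_size=True)
    k50 = capacity_half(model).capacity_P50
    pinf = opt.pattern_capacity(N)
    print(f"  {N:6d}   {k50:9d}   {pinf:11.0f}   {100 * k50 / pinf:5.1f}%")
# Finite-size corrections scale as sqrt(ln M / M) with M = f N only a few
# tens of neurons, so even networks of 4*10^4 neurons store just ~a third
# of the asymptotic capacity.
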