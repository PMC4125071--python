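"""Simulated retrieval vs theory for a 2000-neuron SP network.

Streams patterns through the stochastic learning rule and measures the
probability that a pattern of a given age is still an exact fixed point,
comparing with the binomial finite-size calculation.  Runs in ~20 s.
"""
import numpy as np

from synmem import PlasticityParams, SPFiniteModel, capacity_half, p_noerror_binomial
from synmem.simulate import SPStreamConfig, sp_retrieval_curve
from synmem.theory_asymptotic import sp_asymptotic_optimum

N = 2000
opt = sp_asymptotic_optimum()
f = opt.beta * np.log(N) / N
params = PlasticityParams(q_plus=opt.params["q_plus"], g_ratio=opt.params["g_ratio"])
model = SPFiniteModel(N=N, f=f, theta_scaled=opt.theta, params=params, fixed_size=True)
K50 = capacity_half(model).capacity_P50
ages = np.unique(np.round(np.geomspace(0.2 * K50, 2 * K50, 8)).astype(int))

cfg = SPStreamConfig(N=N, f=f, theta_scaled=opt.theta, params=params, fixed_size=True)
curve = sp_retrieval_curve(cfg, ages, 150, seed=0, matched_history=True)

print(f"theory capacity P50 = {K50} patterns (N={N}, M={round(f*N)})")
print("  age    P_theory   P_sim")
for a, p_sim in zip(curve.ages, curve.p):
    p_th = p_noerror_binomial(model, int(a)).p_noerror
    print(f"  {a:5d}   {p_th:6.3f}    {p_sim:6.3f}")
print(f"simulated capacity (1/2 crossing): ~{curve.capacity_half():.0f} patterns")
# Recent patterns are retrieved reliably; memories fade with age and the
# 1/2-crossing age defines the palimpsest capacity.
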