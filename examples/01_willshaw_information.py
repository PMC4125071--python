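"""Asymptotic information capacity of the Willshaw network.

Builds the information-per-synapse curve as a function of the potentiated
fraction of the synaptic matrix and locates its optimum.
"""
import numpy as np

from synmem import info_willshaw, optimize_asymptotic

g0 = np.linspace(0.05, 0.95, 19)
print("potentiated fraction g0   info (bits/synapse)")
for g in g0:
    print(f"  {g:4.2f}                    {info_willshaw(g0=float(g)).info_bits:.4f}")

opt = optimize_asymptotic("willshaw")
print(f"\noptimum: {opt.info_bits:.4f} bits/synapse at g0 = {opt.params['g0']:.3f} "
      f"(beta = {opt.beta:.3f})")
print("ln 2    :", np.log(2))
# The optimum ln 2 ~ 0.693 bits/synapse occurs when half the synapses are
# potentiated; capacity vanishes for nearly empty or nearly full matrices.
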