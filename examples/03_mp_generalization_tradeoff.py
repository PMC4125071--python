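"""Multiple presentations of noisy prototypes: capacity vs generalisation.

When presentations are noisy versions of prototypes, synaptic depression is
what lets the network average out the noise (generalise) — but depression
also erases old memories, so capacity falls as the noise level rises.
"""
from synmem import info_mp
from synmem.theory_asymptotic import LN2

print("noise x   optimal info at g=1 (bits/synapse)")
for x in (0.0, 0.1, 0.2, 0.4, 0.6, 0.8):
    print(f"  {x:3.1f}        {info_mp(g_ratio=1.0, noise_x=x).info_bits:.4f}")

print(f"\nno-depression, noiseless limit: "
      f"{info_mp(g_ratio=0.0, noise_x=0.0).info_bits:.4f} bits/synapse "
      f"(= Willshaw ln 2 = {LN2:.4f})")
# At g -> 0 and x = 0 the rule stops depressing and becomes the Willshaw
# network; any generalisation ability (g > 0 handling x > 0) costs capacity.
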