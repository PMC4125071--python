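"""One-shot (single-presentation) learning: the palimpsest trade-off.

Stochastic potentiation/depression lets the network learn continuously, at
the price of roughly an order of magnitude of information capacity relative
to the potentiation-only Willshaw rule.
"""
import numpy as np

from synmem import info_sp, sp_asymptotic_optimum
from synmem.theory_asymptotic import LN2

print("depression/potentiation ratio g   optimal info (bits/synapse)")
for g in (0.5, 1.0, 2.0, 2.46, 3.0, 5.0):
    print(f"  {g:4.2f}                            {info_sp(g_ratio=g).info_bits:.4f}")

opt = sp_asymptotic_optimum()
print(f"\nglobal SP optimum: {opt.info_bits:.4f} bits/synapse at "
      f"g = {opt.params['g_ratio']:.3f}, q+ = {opt.params['q_plus']:.2f}")
print(f"Willshaw optimum : {LN2:.4f} bits/synapse "
      f"(ratio {LN2 / opt.info_bits:.1f}x)")
# The curve is single-peaked and broad: a biologically plausible range of
# depression/potentiation balance performs close to the optimum.
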