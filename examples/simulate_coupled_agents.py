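"""Simulate a coupled binary dyad and check the driver's calibration.

A confederate agent C emits an event (1) at base rate 0.25 and drives a
participant agent S, whose event probability jumps to 0.33 whenever C
emitted on the previous step.  The expected event rate of C follows from
its two-state Markov chain.
"""

import numpy as np

import crossrec as cr

params = cr.SimParams(p_c=0.25, p_s=0.05, p_cc=0.05, p_ss=0.05, p_sc=0.33,
                      steps=1000, seed=42)
c, s = cr.simulate_coupled_binary(params)

print(f"confederate event rate : {c.values.mean():.3f}")
print(f"expected (stationary)  : {cr.stationary_rate(params.p_c, params.p_cc):.3f}")
print(f"participant event rate : {s.values.mean():.3f}")
print(f"participant base rate  : {params.p_s:.3f}")

# The participant's rate sits well above its 0.05 base rate because the
# confederate's events recruit extra events through the 0.33 coupling.
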