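"""Locate the leader-follower lag of a simulated dyad, two ways.

Cross-correlation measures lagged co-variation; the diagonal-wise
recurrence profile measures lagged co-visitation of the event state.
Both peak at lag -1 for these agents: negative lag means series 1 (the
confederate) leads, by one step, exactly as built into the simulation.
"""

import numpy as np

import crossrec as cr

HIGH = dict(p_c=0.25, p_s=0.05, p_cc=0.05, p_ss=0.05, p_sc=0.33, steps=1000)

xcorr, drp = [], []
for seed in range(20):
    c, s = cr.simulate_coupled_binary(cr.SimParams(seed=seed, **HIGH))
    xcorr.append(cr.cross_correlation_profile(c, s, W=5).r)
    drp.append(cr.diagonal_recurrence_profile(c, s, W=5, exclude_nonevent=0).rr)

lags = np.arange(-5, 6)
mean_xcorr = np.nanmean(xcorr, axis=0)
mean_drp = np.mean(drp, axis=0)

print("lag   mean r   mean RR%")
for lag, r, rr in zip(lags, mean_xcorr, mean_drp):
    print(f"{lag:+3d}   {r:+.3f}   {rr:6.2f}")
print(f"\ncross-correlation peak at lag {lags[np.argmax(mean_xcorr)]:+d}"
      f" (r = {mean_xcorr.max():.3f})")
print(f"recurrence-profile peak at lag {lags[np.argmax(mean_drp)]:+d}"
      f" (RR = {mean_drp.max():.2f}%)")

# Joint non-events (both agents silent) are excluded from the recurrence
# counts, so the profile reflects co-visitation of the *event* state only.
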