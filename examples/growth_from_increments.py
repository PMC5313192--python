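"""Fit the growth-increment model to the packaged recapture table.

Loads the synthetic 118-recapture stand-in, fits two nested model
variants (measurement error only; plus growth variability), compares
them by likelihood-ratio gain and AIC, and converts the winner to
conventional VBGF parameters.
"""

import reefshark as rs

ds = rs.synthetic_s1_table()
print("records:", len(ds), rs.summarize_times(ds))

m1 = rs.fit(ds, free=("g_alpha", "g_beta", "s"), seed=0)
m2 = rs.fit(ds, free=("g_alpha", "g_beta", "nu", "s"), seed=0)
sel = rs.compare_models([m1, m2])
gain = sel["lrt_pairs"][0]["loglik_gain"]
best = [m1, m2][sel["best_index"]]

print(f"\nlog-likelihood gain from freeing growth variability: {gain:.1f} "
      "(threshold 1.92 for one extra parameter)")
print(best.summary())
print("\nThe fitted g100/g130 are mean annual growth (cm/yr) at 100 and "
      "130 cm; L_inf and k are the equivalent conventional VBGF parameters.")

diag = rs.residual_diagnostics(best)
print(f"rank corr of |residual| vs predicted growth: "
      f"{diag['rho_absresid_predicted']:+.2f} (positive = growth variability "
      "scales with expected growth, as the model assumes)")
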