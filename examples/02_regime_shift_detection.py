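"""Detect a mean shift in an annual series with the sequential t-test (STARS).

Simulates 30 years of an index that steps up by four standard deviations at
year 16, runs the STARS scan (cut-off length 10, significance 0.05) and
prints the confirmed shift with its Regime Shift Index.
"""

from floodshift import StarsParams, gen_annual_series, stars

series, truth = gen_annual_series("step_mean", {"a": 0.0, "c": 4.0},
                                  n=30, noise_sd=1.0, seed=1, tau=16)
result = stars(series, StarsParams(significance=0.05, cutoff=10,
                                   prewhiten=False))

print(f"series of {len(series)} years, true shift at year {truth['tau']}")
print(f"critical difference (diff) = {result.diff:.3f}")
print(f"window variance sigma_l^2  = {result.sigma_l2:.3f}")
for lab in result.shifts:
    print(f"confirmed shift at year {lab}: RSI = {result.rsi[lab]:.3f}")
print(f"regime means: {[round(m, 2) for m in result.regime_means]}")
print(
    "\nA point deviating from the running regime mean by more than diff is a"
    "\ncandidate; the RSI cumulates its normalized exceedance over the next"
    "\nwindow and a positive total confirms the new regime."
)
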