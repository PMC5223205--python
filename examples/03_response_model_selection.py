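"""Characterize a regime shift by AICc selection among seven response shapes.

Simulates an abrupt step in an annual index, fixes the change point at the
known shift year (in the pipeline STARS supplies it) and ranks the seven
candidate response functions — null, linear, step-mean, the three segmented
shapes and the sigmoid — by small-sample-corrected AIC.
"""

import warnings

from floodshift import gen_annual_series, select_best

warnings.simplefilter("ignore")

series, _ = gen_annual_series("step_mean", {"a": 0.0, "c": -3.5},
                              n=30, noise_sd=1.0, seed=3, tau=16)
comparison = select_best(series, tau=16.0)

print(f"{'family':14s} {'k':>2s} {'AICc':>8s} {'dAICc':>7s}")
base = comparison.fits[0].aicc
for f in comparison.fits:
    print(f"{f.family:14s} {f.k:2d} {f.aicc:8.2f} {f.aicc - base:7.2f}")
print(f"\nselected: {comparison.best_family} "
      f"(error structure: {comparison.error_structure})")
print(f"estimates: {({k: round(v, 2) for k, v in comparison.best.params.items()})}")
print(
    "\nLower AICc is better; models within 2 units are equivalently supported"
    "\nand the most parsimonious of them is selected.  The fitted step size c"
    "\nestimates the simulated -3.5 drop at the change point."
)
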