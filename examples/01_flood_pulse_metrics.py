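"""Segment a daily stage record into flood-pulse cycles and compute metrics.

Builds a 15-year synthetic hydrograph for a Negro-River-like gauge (annual
pulse between ~17 m dry-season minima and ~28 m flood peaks, with a regime
change in year 8 that raises amplitude and lowers the minima), segments it at
upward crossings of the 20 m threshold and prints the seven per-cycle
hydrological metrics.
"""

import warnings

from floodshift import HydroScenario, gen_hydrograph, segment_cycles
from floodshift.hydrology import metrics_table

warnings.simplefilter("ignore")

stage, truth = gen_hydrograph(HydroScenario(seed=1))
cycles = segment_cycles(stage)
metrics = metrics_table(cycles)

print(f"{len(stage)} daily stage records -> {len(cycles)} complete cycles\n")
print(metrics.round(2).to_string())
print(
    "\nEach row is one flood-pulse cycle (upward 20 m crossing to the next):"
    "\namplitude/min/max describe the pulse in metres; the day counts split"
    "\nthe cycle into dry (<20 m), rising, flood (>26 m) and receding phases."
    f"\nThe generator's regime change (year {truth['change_calendar_year']})"
    " shows up as higher amplitude and longer dry seasons afterwards."
)
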