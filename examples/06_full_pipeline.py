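"""End to end: are hydrology and assemblage shifts the same event?

Simulates 25 years of river stage with a regime change (bigger floods, drier
dry seasons from year 12) and a fish community whose functional groups step
up or down at the same cycle, runs the whole pipeline — metrics, ordinations,
STARS, response-function selection — and prints the driver report comparing
the hydrological and biological response types.
"""

import warnings

from floodshift import RunConfig, gen_community, gen_hydrograph, run_pipeline, segment_cycles
from floodshift.synth import end_to_end_scenarios

warnings.simplefilter("ignore")

hydro_scen, comm_scen = end_to_end_scenarios(seed=4)
stage, _ = gen_hydrograph(hydro_scen)
config = RunConfig(stars_window=7, prewhiten=False)
cycles = [c for c in segment_cycles(stage, config) if c.usable]
catch, effort, labels, _ = gen_community(comm_scen, cycles)

result = run_pipeline(stage, catch, effort, labels, config=config)

h = result.hydrology
print(f"hydrology PC1: shift(s) {h.shifts.shifts}, "
      f"best model {h.models.best_family}")
for name, analysis in result.assemblage.items():
    report = result.driver_reports[name]
    print(f"{name:14s}: shift(s) {analysis.shifts.shifts}, "
          f"best model {analysis.models.best_family} -> {report.driver}")
print(
    "\nA structure is labelled 'extrinsic' when its best-fit response family"
    "\nmatches the hydrological one and the STARS shifts coincide within one"
    "\ncycle — the signature of a flood-pulse-driven assemblage shift."
)
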