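"""From catch records to assemblage structure: CPUE, diversity, ordination.

Simulates a 196-species survey over 14 flood-pulse cycles (97 common species
in five life-history groups whose abundances change at a mid-series regime
shift), standardizes catches to CPUE, filters common species, and summarizes
the assemblage by diversity indices, taxonomic ordination (Bray-Curtis PCoA)
and the before/after repeated-measures ANOVA on functional-group CPUE.
"""

import warnings

from floodshift import (
    CommunityScenario, HydroScenario, cpue, diversity, filter_common,
    gen_community, gen_hydrograph, rm_anova, segment_cycles,
    taxonomic_structure,
)
from floodshift.assemblage import aggregate_groups

warnings.simplefilter("ignore")

stage, _ = gen_hydrograph(HydroScenario(seed=11))
cycles = [c for c in segment_cycles(stage) if c.usable]
catch, effort, labels, truth = gen_community(CommunityScenario(seed=12), cycles)

matrix = cpue(catch, effort, cycles)
common = filter_common(matrix, threshold=0.01)
print(f"CPUE matrix: {matrix.shape[0]} cycles x {matrix.shape[1]} species; "
      f"{common.shape[1]} common (> 0.01 ind/m^2)")

div = diversity(common)
print("\nper-cycle diversity (first/last 3 cycles):")
print(div.iloc[[0, 1, 2, -3, -2, -1]].round(3).to_string())

ordn = taxonomic_structure(common)
pc1 = ordn.scores.iloc[:, 0]
print(f"\ntaxonomic PCoA axis 1 ({ordn.proportion_explained[0]:.0%} of "
      f"variation):")
print(pc1.round(3).to_string())

split_year = int(truth["tau_cycle_id"].split("-")[0])
grouped = aggregate_groups(common, labels, "life_history")
res = rm_anova(grouped, split=split_year)
inter = res.interaction
print(f"\nRM-ANOVA period x life-history interaction: "
      f"F({inter['df1']:.0f},{inter['df2']:.0f}) = {inter['F']:.2f}, "
      f"p = {inter['p']:.4f}")
print(
    "\nThe ordination axis separates pre- and post-shift cycles, and the"
    "\ninteraction tests whether functional groups changed unequally between"
    "\nthe two periods."
)
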