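# Methods

This note records the models implemented in `floodshift`, their assumptions,
the parameters that matter, and the design decisions taken where the
methodology left genuine freedom.  Nothing here reports an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Flood-pulse segmentation and metrics

A flood-pulse **cycle** runs from one upward crossing of the low threshold
(default 20 m) to the next, so each cycle contains exactly one dry season —
the dry days preceding a crossing belong to the ending cycle.  Season labels
partition every day: `dry` strictly below the low threshold, `flood`
strictly above the high threshold (default 26 m), and the closed band in
between split by direction of stage change (`rising` ascending, `receding`
descending).  The thresholds are properties of the gauge (they delimit the
seasons of the Manaus stage record) and are configurable.

Decisions the definitions do not force:

- **Direction of a day** is the sign of `level_t − level_{t−1}`; flat days
  inherit the previous day's direction and the first day borrows the next
  step's sign.  This leaves no unlabeled day.
- **Crossing hysteresis.** An upward crossing re-arms only after the stage
  drops below `low − 0.25 m`.  Day-to-day gauge noise near the threshold
  would otherwise split one pulse into spurious micro-cycles; 0.25 m is
  several standard deviations of daily gauge noise and far smaller than any
  real seasonal excursion, so clean records are unaffected.
- **Gaps** are recorded, never interpolated.  A cycle missing more than 5 %
  of its days (configurable) is flagged unusable and carries missing metric
  values.

The seven per-cycle metrics — amplitude, minimum, maximum, and the four
season day-counts — are z-scored across cycles (sample sd) before
ordination.  A zero-variance metric is left at zero with a warning.

## Ordination

PCA is the standard SVD construction; eigenvalues are score variances
(n − 1 denominator) and each axis' sign is fixed so its largest-magnitude
loading is positive, making runs reproducible across platforms.  PCoA is
classical scaling: double-centre −D²/2, eigendecompose, coordinates are
eigenvectors scaled by the square root of positive eigenvalues.  Negative
eigenvalues (possible under Bray–Curtis) are reported as a magnitude share
but not corrected — results using only the leading axes are unaffected by
small negative tails.  Axis retention uses the broken-stick rule with the
largest-drop scree elbow as a fallback when the broken stick retains
nothing; when the two disagree the broken stick wins.

Composition enters ordination through the square-root transform (taxonomic,
before Bray–Curtis) or the Hellinger transform (functional groups, before
PCA): the Hellinger rows are square roots of relative abundances, so each
nonzero row has unit sum of squares and Euclidean geometry becomes
appropriate for compositional data.

## Assemblage summaries

- **CPUE**: summed counts per cycle divided by summed gillnet area,
  individuals/m².  Catches dated outside every cycle are excluded (logged).
- **Common-species filter**: a species is common when its *maximum* CPUE
  over cycles exceeds the threshold (default 0.01 ind/m²).  The maximum is
  used because a species abundant in even one cycle carries compositional
  signal; the aggregation rule is configurable at the call site by
  pre-transforming the matrix.
- **Diversity**: richness, Shannon H (natural log) and Pielou evenness
  J = H / ln S (missing when S = 1).
- **Life-history strategies**: a PCA of the five traits (log maximum and
  maturation length, log fecundity, oocyte diameter, parental-care score,
  all z-scored) yields the fecundity/parental-care continuum on axis 1 and
  body size on the next informative axis.  Suggested labels split
  equilibrium (care side) from periodic (fecundity side), with an
  intermediate band of half-width 0.5 axis-1 standard deviations, and large
  from small at the axis score a species of the configured cut length
  (default 200 mm) would attain.  These labels are a convenience; an expert
  label file always takes precedence, because the original groupings were
  partly expert judgement.
- **Trophic levels** from volumetric diet proportions: level 1 when
  plant + detritus + algae ≥ 0.6, level 2 when invertebrate + plankton
  ≥ 0.6, level 3 when fish ≥ 0.6, otherwise omnivory (1.5).  The 0.6
  dominance cut-off is configurable; the categories themselves are fixed.
- **RM-ANOVA**: cycles are subjects measured repeatedly across functional
  groups; period (before/after a split year) is the between-subject factor.
  Sums of squares follow the standard mixed two-factor decomposition
  (period tested against cycles-within-period; group and period × group
  against the group × cycle-within-period error), cross-checked against an
  independent mixed-ANOVA implementation in the test suite.  Per-group
  before/after contrasts are Welch t-tests.  Degrees of freedom follow this
  explicit design.

## STARS

The sequential t-test scan is implemented as a single forward pass:

- σ_l² is the average sample variance over *all* consecutive l-point
  windows of the (possibly prewhitened) series, estimated once — the common
  convention; per-regime re-estimation is not used.
- `diff = t_crit(2l−2, p) · sqrt(2σ_l²/l)`, two-sided.
- Regime means always use the most recent `min(l, regime length)` points.
- A candidate is confirmed only if its RSI stays positive through a **full**
  window of l points.  When the series ends inside the window the candidate
  is reported separately as *tentative*: its evidence rests on fewer than l
  points, and treating such candidates as confirmed would raise the
  white-noise false-alarm rate from under 1 % to over 30 % at n = 30,
  l = 10, p = 0.01 — the operating characteristics that motivate the method
  would be lost.
- No retroactive adjustment of shift timing; no outlier downweighting (the
  RSI rejection rule is the only robustness mechanism); no variance- or
  correlation-shift variants.
- Missing years are simply absent points; a confirmation window that spans
  a labelled gap flags the shift.

Prewhitening estimates α by OLS of the centred series on its lag
(clamped to ±0.99) and filters `x'_t = x_t − α x_{t−1}`, the first value
scaled by (1 − α) so constants map to constants.  Note the OLS estimate is
inflated by large mean shifts (a 4-sd step drives α̂ toward 0.85, and the
filter then ruins the step itself), so prewhitening is a switch, on by
default for observational series but off in the synthetic operating-
characteristic experiments, which probe the sequential t-test itself.

## Response-function selection

All seven families are fitted with the change point τ fixed in advance
(STARS supplies it; `free_tau` profiles τ over interior years for
sensitivity checks).  Segmented families allow a discontinuity at τ —
independent parameters per segment; continuity is not imposed.  Families
linear in their parameters are solved per-segment in closed form; the
sigmoid by bounded multi-start least squares (five deterministic starts
with centres spread over the series; slope bounded below at 0.1 yr so it
cannot collapse onto the step).

Error structures: iid; AR(1) correlation φ^|i−j| (φ profiled on a grid and
polished, the GLS solve using the Prais–Winsten whitening transform, whose
quadratic form and determinant are exact for AR(1)); and AR(1) with one
variance per side of τ.  The likelihood is the Gaussian ML value with the
overall variance profiled out; `k` counts every estimated quantity — mean
parameters, each variance, and φ — uniformly across families, so AICc
comparisons are coherent; fixed τ is not counted.

**Selection rule.**  Models are ranked by AICc; among models within 2 AICc
units of the minimum the one with fewest parameters is selected.  A
difference below 2 is the conventional "equivalent support" band, and
without the rule a nested family with one superfluous parameter overtakes
the true simpler family whenever a χ²₁ fluctuation exceeds the penalty gap
— roughly a 10 % accident rate per competitor at n ≈ 30.  Setting
`parsimony_delta = 0` restores raw minimum-AICc selection.  After the first
pass the best model's residuals are checked for lag-1 autocorrelation
(|r₁| > 1.96/√n); if flagged, every family is refitted with AR(1) errors
and the ranking redone — the two-pass procedure.

Exact fits (zero residual sum of squares) are handled by flooring the
profiled variance at a relative 1e−12, so noise-free benchmark series rank
by parameter count as intended.

## Missing-value sweep and driver inference

The sweep inserts every value from the observed minimum to maximum
(inclusive; the final step truncated to end exactly at the maximum) at the
single missing cycle, reruns the full selection, and reports per-family
winning proportions; AICc ties within 1e−9 are counted fractionally so
proportions always sum to 1.

A biological series' shift is labelled **extrinsic** when its best-fit
family equals the hydrological series' best-fit family and some pair of
STARS shift years coincides within a tolerance of one cycle (consecutive
cycle labels describe the same event); otherwise the label is the combined
"internal or unmeasured driver" — the dichotomy cannot separate those two.
The pipeline fixes each series' own first confirmed shift as its τ;
`consensus_tau=True` instead fixes the most frequent first-shift year
across all scanned series in every regression.

## Synthetic data

The generators define the study conditions for every statistical check.

- **Hydrograph**: per year, a dry-season trough (1 January) rising through
  a cosine half-wave to a mid-year flood peak and back to the next trough.
  Defaults: troughs 17 m, peaks 28 m, 15 years; inter-annual jitter of
  peaks (sd 0.3 m) and troughs (sd 0.2 m); daily gauge noise sd 0.05 m.  A
  regime change raises amplitude (+2 m) and lowers the dry-season minima
  (−1 m); the minimum change applies from the year *after* the amplitude
  change because a cycle pairs the peak of year c with the dry season of
  year c + 1 — this makes the cycle indexed by the change year the first
  fully post-change cycle rather than a transitional mixture.  Generation
  fails loudly if any year's pulse misses a season threshold.
- **Community**: 97 common species in the five life-history groups
  (ES 12, EL 3, IS 18, PL 29, PS 35) plus 99 rare species far below the
  CPUE filter; per-group multiplicative response functions from the
  seven-family catalogue; lognormal year effects shared within groups
  (sd 0.25, optional AR(1)) plus independent species-level residuals
  (sd 0.15); counts Poisson(CPUE × effort) at the cycle midpoint, so CPUE
  estimation inverts generation exactly.  Trait and diet tables are drawn
  from strategy archetypes (≈ 4:1 between:within cluster separation on log
  traits) and trophic-level base diets.
- **Benchmarks** frozen in `synth.RECOVERY_BENCHMARK` (per-family signals
  of ~4 noise sd at n = 30 — the sigmoid with a sharp 0.5-yr transition,
  where the step is its natural near-equivalent) and
  `synth.end_to_end_scenarios` (a 25-year record, change at cycle 12, with
  all-step community responses: ES/EL −60 %, IS −50 %, PL −30 %, PS +60 %).
  The 25-year length gives the biological STARS scan (p = 0.01, l = 7) a
  complete confirmation window on both sides of the change, which a
  15-year record does not.

What the generators deliberately do not emulate: within-cycle seasonal
catch dynamics (each cycle's catch sits at its midpoint date), species-level
responses diverging from their group, gear selectivity, observation gaps,
and any real species' parameter values.  Passing tests therefore demonstrate
that the *algorithms* recover known regime structure under realistic noise
— not that any particular field system behaves this way.

## Known limitations

- The OLS AR(1) estimate used for prewhitening is biased upward by large
  mean shifts; subsample estimators would mitigate this but are not part of
  the implemented procedure.
- Exact-family agreement between two independently selected best models is
  a strict concordance criterion: even with the parsimony band, chance
  promotion of a nested neighbour (e.g. stable–linear over step-mean) on
  one side occurs in roughly 5–10 % of series at two dozen cycles, so joint
  agreement saturates near 80 % even when both series shifted identically.
  The driver report exposes family and timing components separately so
  users can see which one failed.
- PCoA applies no correction for negative eigenvalues; with strongly
  non-Euclidean dissimilarities the reported proportions understate the
  leading axes' share.
- The RM-ANOVA assumes compound symmetry (no sphericity correction is
  applied) and the repeated dimension is the functional-group profile per
  cycle; designs with other repeated structures need external tools.
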