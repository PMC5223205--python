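# floodshift

Detection and characterization of simultaneous regime shifts in river
hydrology and fish assemblage structure, for floodplain systems organised by
an annual flood pulse.

Long-term monitoring of tropical floodplain lakes produces two parallel time
series: a daily river-stage record and a standardized fish survey (catch per
unit effort, CPUE).  `floodshift` implements the complete analytical chain
needed to ask whether an abrupt change in the fish assemblage is the same
event as an abrupt change in the flood pulse:

1. **Flood-pulse hydrology** — segment the daily stage record into annual
   cycles at upward crossings of a low-water threshold (20 m by default) and
   compute seven metrics per cycle: pulse amplitude, annual minimum and
   maximum stage, and day counts of the dry (< 20 m), rising, flood (> 26 m)
   and receding seasons.
2. **Ordination** — standardized PCA of the cycle × metric table;
   square-root transform → Bray–Curtis dissimilarity → principal coordinates
   (PCoA) for taxonomic composition; Hellinger transform → centred PCA for
   functional-group composition; broken-stick and scree criteria for axis
   retention.
3. **Regime-shift detection (STARS)** — the sequential t-test scan.  With
   cut-off length *l* and significance *p*, the critical difference is

   ```
   diff = t_crit(2l − 2, p) · sqrt(2 σ_l² / l)
   ```

   with σ_l² the average variance of all *l*-point windows.  A point
   deviating from the running regime mean by more than `diff` is a candidate
   shift; the Regime Shift Index `RSI = Σ (x_j − (mean ± diff)) / (l σ_l)`
   cumulated over the following window confirms (stays positive) or rejects
   (turns negative) the candidate.  Series with red noise are prewhitened by
   the OLS AR(1) filter `x'_t = x_t − α̂ x_{t−1}` first.
4. **Response-function models** — with the change point τ fixed from STARS,
   seven candidate shapes are fitted by (generalized) nonlinear least
   squares — null, linear, step-mean, segmented linear–linear,
   linear–stable, stable–linear, and sigmoid — under iid, AR(1), or
   AR(1)-plus-per-regime-variance Gaussian errors, and ranked by
   `AICc = −2 logL + 2k + 2k(k+1)/(n−k−1)`.  If the best model's residuals
   are lag-1 autocorrelated, all families are refitted with AR(1) errors.
5. **Missing-value sweep** — a single unobserved cycle is swept over a value
   grid from the observed minimum to maximum; the proportion of grid values
   at which each family wins measures the robustness of the selected model.
6. **Driver inference** — a biological shift whose best-fit family matches
   the hydrological one, with STARS moments coinciding within one cycle, is
   labelled extrinsically (hydrologically) driven; otherwise it is
   attributed to internal or unmeasured drivers.

A synthetic-data module generates daily hydrographs and species × cycle
communities with known regime structure (and machine-readable truth
records), so the whole pipeline is testable without any field data.

## Worked example

```bash
python examples/02_regime_shift_detection.py
```

```
series of 30 years, true shift at year 16
critical difference (diff) = 1.380
window variance sigma_l^2  = 2.157
confirmed shift at year 16: RSI = 1.667
regime means: [0.03, 3.73]
```

A 4-standard-deviation step at year 16 is confirmed exactly at year 16: the
new regime's first point exceeds the old regime mean by more than the
critical difference 1.38, and the positive RSI (1.67) means every point of
the following decade supported the new mean (≈ 3.7 vs ≈ 0.0).

The other scripts in `examples/` walk through each capability the same way:
flood-pulse metrics (`01`), model selection (`03`, which prints the AICc
table and selects `step_mean` with a fitted step of −2.95 for a simulated
−3.5 drop), CPUE/diversity/ordination/RM-ANOVA (`04`), the missing-value
sweep (`05`, step-mean wins 100 % of the grid), and the full
hydrology-vs-assemblage driver report (`06`).

A thin command-line interface chains the same stages on CSV files:

```bash
floodshift simulate --seed 11 --out-dir fixtures
floodshift hydro-features --stage fixtures/stage.csv --out-dir results
floodshift compare-drivers --stage fixtures/stage.csv \
    --catch fixtures/catch.csv --effort fixtures/effort.csv --out-dir results
```

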