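"""Fish assemblage structure: CPUE, diversity, ordination and group analyses.

Catch records are standardized to catch per unit effort (CPUE, individuals
per m^2 of gillnet) per flood-pulse cycle, filtered to common species, and
summarized three ways: taxonomic structure (square root -> Bray-Curtis ->
PCoA of cycles), functional structure (group-aggregated CPUE -> Hellinger ->
centred PCA) and simple diversity indices per cycle.  Species are placed into
five life-history strategies (equilibrium/periodic/intermediate crossed with
a size split) from a trait PCA and into four trophic levels from volumetric
diet proportions.  A repeated-measures ANOVA contrasts group CPUE before and
after a chosen split year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hydrology import FloodPulseCycle
from .multivariate import (
    OrdinationResult, bray_curtis, hellinger_transform, pca, pcoa,
    sqrt_transform,
)

__all__ = [
    "cpue",
    "filter_common",
    "diversity",
    "anomaly",
    "taxonomic_structure",
    "functional_structure",
    "life_history_pca",
    "assign_trophic",
    "rm_anova",
    "RmAnovaResult",
]


def cpue(catch: pd.DataFrame, effort: pd.DataFrame,
         cycles: list[FloodPulseCycle]) -> pd.DataFrame:
    """Cycle x species CPUE matrix (total counts / total effort, per m^2).

    Catch dates falling outside every cycle are excluded (their total count
    is reported in a warning); a cycle without positive effort is an error.
    """
    if (effort["effort_m2"] <= 0).any():
        raise ValueError("every cycle must have positive effort")
    date_to_cycle = {}
    for c in cycles:
        start, end = c.start_date, c.end_date
        date_to_cycle[c.cycle_id] = (start, end)

    assigned = pd.Series(pd.NA, index=catch.index, dtype="object")
    for cid, (start, end) in date_to_cycle.items():
        mask = (catch["date"] >= start) & (catch["date"] <= end)
        assigned[mask] = cid
    outside = assigned.isna()
    if outside.any():
        lost = int(catch.loc[outside, "count"].sum())
        warnings.warn(f"excluded {lost} individuals caught outside all cycles",
                      stacklevel=2)
    kept = catch[~outside].copy()
    kept["cycle_id"] = assigned[~outside]

    counts = kept.pivot_table(index="cycle_id", columns="species_id",
                              values="count", aggfunc="sum", fill_value=0.0)
    cycle_ids = [c.cycle_id for c in cycles]
    counts = counts.reindex(index=cycle_ids, fill_value=0.0)
    missing_effort = [cid for cid in cycle_ids if cid not in effort.index]
    if missing_effort:
        raise ValueError(f"cycles without effort records: {missing_effort}")
    return counts.div(effort.loc[cycle_ids, "effort_m2"], axis=0)


def filter_common(cpue_matrix: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Keep species whose maximum CPUE over cycles exceeds ``threshold``."""
    keep = cpue_matrix.max(axis=0) > threshold
    if not keep.any():
        raise ValueError(f"no species exceeds the CPUE threshold {threshold}")
    return cpue_matrix.loc[:, keep]


def diversity(cpue_matrix: pd.DataFrame) -> pd.DataFrame:
    """Richness S, Shannon H (natural log) and Pielou evenness J per cycle.

    J = H / ln(S) is undefined for a single-species cycle and reported as
    missing there.  An all-zero cycle is an error.
    """
    rows = []
    for cid, row in cpue_matrix.iterrows():
        x = row.to_numpy(dtype=float)
        if (x < 0).any():
            raise ValueError("CPUE must be non-negative")
        total = x.sum()
        if total == 0:
            raise ValueError(f"cycle {cid} has no catch at all")
        p = x[x > 0] / total
        s = int(len(p))
        h = float(-(p * np.log(p)).sum())
        j = h / np.log(s) if s > 1 else np.nan
        rows.append({"cycle_id": cid, "richness": s, "shannon": h, "evenness": j})
    return pd.DataFrame(rows).set_index("cycle_id")


def anomaly(series: pd.Series, baseline: list) -> pd.Series:
    """Relative-abundance anomaly: value minus the mean over baseline cycles."""
    if len(baseline) == 0:
        raise ValueError("baseline set must be non-empty")
    missing = [b for b in baseline if b not in series.index]
    if missing:
        raise ValueError(f"baseline cycles absent from series: {missing}")
    return series - series.loc[list(baseline)].mean()


def taxonomic_structure(common_cpue: pd.DataFrame) -> OrdinationResult:
    """Ordinate cycles by composition: sqrt CPUE -> Bray-Curtis -> PCoA."""
    return pcoa(bray_curtis(sqrt_transform(common_cpue)))


def aggregate_groups(cpue_matrix: pd.DataFrame, labels: pd.DataFrame,
                     scheme: str) -> pd.DataFrame:
    """Sum CPUE over species within each functional group (cycle x group)."""
    if scheme not in ("life_history", "trophic_level"):
        raise ValueError("scheme must be 'life_history' or 'trophic_level'")
    unlabeled = [s for s in cpue_matrix.columns if s not in labels.index]
    if unlabeled:
        raise ValueError(f"species lacking a {scheme} label: {unlabeled}")
    groups = labels.loc[cpue_matrix.columns, scheme]
    return cpue_matrix.T.groupby(groups).sum().T


def functional_structure(cpue_matrix: pd.DataFrame, labels: pd.DataFrame,
                         scheme: str) -> OrdinationResult:
    """Ordinate cycles by functional composition: group sums -> Hellinger ->
    centred (unscaled) PCA."""
    grouped = aggregate_groups(cpue_matrix, labels, scheme)
    return pca(hellinger_transform(grouped), center=True, scale=False)


# ---------------------------------------------------------------------------
# life-history strategies


_LOG_TRAITS = ("max_sl_mm", "maturation_sl_mm", "fecundity")


def life_history_pca(traits: pd.DataFrame, sl_cut_mm: float = 200.0,
                     intermediate_band: float = 0.5
                     ) -> tuple[OrdinationResult, pd.Series]:
    """Ordinate species along the life-history continuum and suggest strategies.

    Size and fecundity traits are log-transformed, all five traits z-scored,
    and a PCA extracts (i) the fecundity/parental-care gradient separating
    periodic from equilibrium strategists and (ii) the body-size gradient.
    Suggested labels: species within ``intermediate_band`` axis-1 standard
    deviations of the origin are intermediate (IS); otherwise the
    parental-care side of axis 1 is equilibrium (E) and the fecundity side
    periodic (P); large vs small is decided on the size axis against the
    score a species of standard length ``sl_cut_mm`` would attain.  The
    suggestions are a convenience — expert label files take precedence in the
    pipeline.
    """
    if (traits[list(_LOG_TRAITS)] <= 0).any().any():
        raise ValueError("size and fecundity traits must be positive for log transform")
    X = traits.copy().astype(float)
    for c in _LOG_TRAITS:
        X[c] = np.log(X[c])
    # oocyte diameter spans < 1 order of magnitude; kept on natural scale
    mean, sd = X.mean(), X.std(ddof=1)
    sd = sd.replace(0.0, 1.0)
    Z = (X - mean) / sd
    ord_res = pca(Z, center=True, scale=False)
    scores = ord_res.scores
    loadings = ord_res.loadings

    # orient axis 1 so that positive = periodic (high fecundity, low care)
    axis1 = scores["PC1"].copy()
    sign1 = np.sign(loadings.loc["fecundity", "PC1"]
                    - loadings.loc["parental_care_score", "PC1"])
    axis1 *= sign1 if sign1 != 0 else 1.0

    # size axis: among the informative components (>5% variance, excluding
    # the reproductive axis 1) the one loading heaviest on maximum length —
    # axis 2 in any data resembling the strategy continuum
    informative = [c for c, p in zip(scores.columns,
                                     ord_res.proportion_explained)
                   if p > 0.05 and c != "PC1"]
    if not informative:
        informative = ["PC2"]
    size_axis = loadings.loc["max_sl_mm", informative].abs().idxmax()
    z_cut = (np.log(sl_cut_mm) - mean["max_sl_mm"]) / sd["max_sl_mm"]
    cut_score = z_cut * loadings.loc["max_sl_mm", size_axis]
    orient = np.sign(loadings.loc["max_sl_mm", size_axis]) or 1.0
    large = (scores[size_axis] - cut_score) * orient > 0

    band = intermediate_band * axis1.std(ddof=1)
    labels = []
    for sp in scores.index:
        if abs(axis1[sp]) <= band:
            labels.append("IS")  # intermediate strategists are small-bodied
        elif axis1[sp] > 0:
            labels.append("PL" if large[sp] else "PS")
        else:
            labels.append("EL" if large[sp] else "ES")
    return ord_res, pd.Series(labels, index=scores.index, name="life_history")


_PLANT = ["detritus", "algae", "plant"]
_ANIMAL_INVERT = ["invertebrate", "plankton"]


def assign_trophic(diet: pd.DataFrame, dominance: float = 0.6) -> pd.Series:
    """Assign each species one of four trophic levels from diet proportions.

    Level 1 = herbivores/detritivores (plant+detritus+algae share >= 0.6),
    2 = invertivores/planktivores, 3 = piscivores; a mixed plant-and-animal
    diet without a dominant category is omnivory, level 1.5.
    """
    sums = diet.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("empty diet rows")
    p = diet.div(sums, axis=0)
    plant = p[_PLANT].sum(axis=1)
    invert = p[_ANIMAL_INVERT].sum(axis=1)
    fish = p["fish"]
    out = pd.Series(1.5, index=diet.index, name="trophic_level")
    out[plant >= dominance] = 1.0
    out[invert >= dominance] = 2.0
    out[fish >= dominance] = 3.0
    return out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass
class RmAnovaResult:
    """Mixed repeated-measures ANOVA table plus per-group contrasts."""

    table: pd.DataFrame      # effects: period, group, period x group
    contrasts: pd.DataFrame  # per-group before/after Welch t-tests

    @property
    def interaction(self) -> pd.Series:
        return self.table.loc["period_x_group"]


def rm_anova(group_cpue: pd.DataFrame, split: float) -> RmAnovaResult:
    """Before/after x functional-group repeated-measures ANOVA.

    Cycles are the subjects: every cycle measures all groups (the repeated,
    within-subject factor) and belongs to one period (before/after ``split``
    by start year, the between-subject factor).  Sums of squares follow the
    standard mixed two-factor decomposition: the period effect is tested
    against cycles-within-period, the group and interaction effects against
    the group x cycle-within-period error.  Per-group before/after contrasts
    are Welch two-sample t-tests.
    """
    years = np.array([float(str(c).split("-")[0].split("–")[0])
                      for c in group_cpue.index])
    period = np.where(years < split, "before", "after")
    n_before = int((period == "before").sum())
    n_after = int((period == "after").sum())
    if n_before < 2 or n_after < 2:
        raise ValueError("each period needs at least 2 cycles")

    Y = group_cpue.to_numpy(dtype=float)
    n_s, b = Y.shape                      # subjects (cycles) x groups
    grand = Y.mean()
    subj_means = Y.mean(axis=1)           # per cycle
    group_means = Y.mean(axis=0)          # per group
    period_codes = (period == "after").astype(int)
    a = 2
    n_per = np.array([n_before, n_after], dtype=float)

    period_mean = np.array([subj_means[period_codes == g].mean() for g in (0, 1)])
    ss_period = float(b * np.sum(n_per * (period_mean - grand) ** 2))
    ss_subj_within = float(b * np.sum(
        (subj_means - period_mean[period_codes]) ** 2))
    ss_group = float(n_s * np.sum((group_means - grand) ** 2))
    cell = np.array([Y[period_codes == g].mean(axis=0) for g in (0, 1)])
    ss_inter = float(np.sum(
        n_per[:, None] * (cell - period_mean[:, None]
                          - group_means[None, :] + grand) ** 2))
    ss_total = float(np.sum((Y - grand) ** 2))
    ss_resid = ss_total - ss_period - ss_subj_within - ss_group - ss_inter

    df_period = a - 1
    df_subj = n_s - a
    df_group = b - 1
    df_inter = (a - 1) * (b - 1)
    df_resid = (b - 1) * (n_s - a)

    ms = {
        "period": ss_period / df_period,
        "subjects_within": ss_subj_within / df_subj,
        "group": ss_group / df_group,
        "period_x_group": ss_inter / df_inter,
        "residual": ss_resid / df_resid,
    }
    rows = []
    for effect, df1, df2, err in (
        ("period", df_period, df_subj, "subjects_within"),
        ("group", df_group, df_resid, "residual"),
        ("period_x_group", df_inter, df_resid, "residual"),
    ):
        if ms[err] > 0:
            f = ms[effect] / ms[err]
        elif abs(ms[effect]) < 1e-12:
            f = 0.0  # degenerate 0/0 design: no effect, no error
        else:
            f = np.inf
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        rows.append({"effect": effect, "df1": df1, "df2": df2, "F": f, "p": p})
    table = pd.DataFrame(rows).set_index("effect")

    contrasts = []
    for g, col in enumerate(group_cpue.columns):
        before = Y[period_codes == 0, g]
        after = Y[period_codes == 1, g]
        tt = stats.ttest_ind(before, after, equal_var=False)
        contrasts.append({
            "group": col,
            "mean_before": before.mean(),
            "mean_after": after.mean(),
            "t": float(tt.statistic),
            "p": float(tt.pvalue),
        })
    return RmAnovaResult(table=table,
                         contrasts=pd.DataFrame(contrasts).set_index("group"))
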