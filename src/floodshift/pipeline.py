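"""End-to-end pipeline: hydrograph and catches in, driver reports out.

Chains the stages exactly as the analysis prescribes: segment the stage
record into flood-pulse cycles, compute and standardize the seven
hydrological metrics, ordinate cycles by PCA and scan PC1 with STARS;
build the CPUE matrix, filter common species, ordinate taxonomic structure
(square root -> Bray-Curtis -> PCoA) and, when functional labels are
available, life-history and trophic structure (group sums -> Hellinger ->
PCA); scan each dominant axis with STARS at the stricter biological
significance; fix each change point from its own STARS result, run the AICc
response-function selection on every series, and compare response types
between hydrology and each assemblage structure to label its shift
extrinsic or internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .assemblage import cpue, filter_common, functional_structure, taxonomic_structure
from .config import RunConfig
from .drivers import DriverReport, compare_drivers
from .hydrology import StageSeries, hydro_feature_matrix, segment_cycles
from .multivariate import OrdinationResult, pca
from .regime import AnnualSeries, ShiftResult, StarsParams, stars
from .response import ModelComparison, select_best

__all__ = [
    "SeriesAnalysis", "PipelineResult",
    "series_from_scores", "analyse_series", "run_pipeline",
]

NON_SEGMENTED = ("null", "linear", "sigmoid")


@dataclass
class SeriesAnalysis:
    """STARS scan plus response-function selection of one annual series."""

    ordination: OrdinationResult | None
    series: AnnualSeries
    shifts: ShiftResult
    models: ModelComparison


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces.

    ``assemblage`` maps structure name (``taxonomic``, ``life_history``,
    ``trophic_level``) to its analysis; ``driver_reports`` holds the
    hydrology-vs-structure concordance per structure.
    """

    hydrology: SeriesAnalysis
    assemblage: dict
    driver_reports: dict

    @property
    def driver_report(self) -> DriverReport:
        """The taxonomic-structure report (the headline comparison)."""
        key = "taxonomic" if "taxonomic" in self.driver_reports else \
            next(iter(self.driver_reports))
        return self.driver_reports[key]


def series_from_scores(scores: pd.DataFrame, axis: str | int = 0,
                       name: str | None = None) -> AnnualSeries:
    """Turn one ordination axis (rows = cycles) into an annual series."""
    col = scores.columns[axis] if isinstance(axis, int) else axis
    s = scores[col]
    return AnnualSeries(labels=tuple(s.index), values=s.to_numpy(dtype=float),
                        name=name or str(col))


def _shift_year(label) -> float:
    return (float(str(label).split("-")[0].split("–")[0])
            if isinstance(label, str) else float(label))


def analyse_series(series: AnnualSeries, params: StarsParams,
                   ordination: OrdinationResult | None = None,
                   tau: float | None = None) -> SeriesAnalysis:
    """STARS scan followed by response-function selection at the shift moment.

    The change point is fixed at ``tau`` when given (e.g. the consensus
    moment across several series), otherwise at the series' own first
    confirmed shift; with no change point only the families without one are
    ranked.
    """
    shifts = stars(series, params)
    if tau is None and shifts.shifts:
        tau = _shift_year(shifts.shifts[0])
    if tau is not None:
        models = select_best(series, tau=tau)
    else:
        models = select_best(series, tau=None, families=NON_SEGMENTED)
    return SeriesAnalysis(ordination=ordination, series=series,
                          shifts=shifts, models=models)


def run_pipeline(stage: StageSeries, catch: pd.DataFrame, effort: pd.DataFrame,
                 labels: pd.DataFrame | None = None,
                 config: RunConfig | None = None,
                 bio_significance: float = 0.01,
                 consensus_tau: bool = False) -> PipelineResult:
    """Run the full hydrology-vs-assemblage comparison.

    Hydrology uses the configured STARS significance (0.05 by default);
    biological series use the stricter ``bio_significance`` (0.01).  With a
    label table the life-history and trophic functional structures are
    analysed alongside the taxonomic one.  ``consensus_tau=True`` fixes the
    most frequent first-shift year across all series in every regression
    instead of each series' own shift.
    """
    cfg = config or RunConfig()
    cycles = [c for c in segment_cycles(stage, cfg) if c.usable]

    features = hydro_feature_matrix(cycles, cfg)
    hydro_ord = pca(features, center=True, scale=False)
    hydro_params = StarsParams(significance=cfg.stars_significance,
                               cutoff=cfg.stars_window, prewhiten=cfg.prewhiten)
    bio_params = StarsParams(significance=bio_significance,
                             cutoff=cfg.stars_window, prewhiten=cfg.prewhiten)

    matrix = cpue(catch, effort, cycles)
    common = filter_common(matrix, cfg.common_species_cpue_threshold)

    to_scan = [("hydrology", hydro_ord,
                series_from_scores(hydro_ord.scores, 0, "hydrology_pc1"),
                hydro_params)]
    tax_ord = taxonomic_structure(common)
    to_scan.append(("taxonomic", tax_ord,
                    series_from_scores(tax_ord.scores, 0, "taxonomic_pco1"),
                    bio_params))
    if labels is not None:
        for scheme in ("life_history", "trophic_level"):
            ordn = functional_structure(common, labels, scheme)
            to_scan.append((scheme, ordn,
                            series_from_scores(ordn.scores, 0, f"{scheme}_pc1"),
                            bio_params))

    scans = {name: stars(series, params)
             for name, _, series, params in to_scan}

    # optional consensus change point: the most frequent first-shift year
    # across all scanned series, fixed in every regression (ties -> earliest)
    tau_common = None
    if consensus_tau:
        first_years = [_shift_year(s.shifts[0])
                       for s in scans.values() if s.shifts]
        if first_years:
            counts = pd.Series(first_years).value_counts()
            tau_common = float(min(counts[counts == counts.max()].index))

    analyses = {}
    for name, ordn, series, params in to_scan:
        own = scans[name]
        tau = tau_common
        if tau is None and own.shifts:
            tau = _shift_year(own.shifts[0])
        if tau is not None:
            models = select_best(series, tau=tau)
        else:
            models = select_best(series, tau=None, families=NON_SEGMENTED)
        analyses[name] = SeriesAnalysis(ordination=ordn, series=series,
                                        shifts=own, models=models)
    hydrology = analyses.pop("hydrology")
    assemblage = analyses

    driver_reports = {
        name: compare_drivers(hydrology.models, hydrology.shifts,
                              a.models, a.shifts)
        for name, a in assemblage.items()
    }
    return PipelineResult(hydrology=hydrology, assemblage=assemblage,
                          driver_reports=driver_reports)
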