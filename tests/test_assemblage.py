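import warnings

import numpy as np
import pandas as pd
import pytest

from floodshift import (
    anomaly, assign_trophic, cpue, diversity, filter_common,
    functional_structure, life_history_pca, rm_anova, taxonomic_structure,
)
from floodshift.assemblage import aggregate_groups
from floodshift.synth import gen_trait_table


@pytest.fixture(scope="module")
def survey_cpue(synthetic_survey):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cpue(synthetic_survey["catch"], synthetic_survey["effort"],
                    synthetic_survey["cycles"])


class TestCpue:
    def test_counts_divided_by_effort(self, synthetic_survey):
        cycles = synthetic_survey["cycles"][:1]
        catch = pd.DataFrame({
            "date": [cycles[0].dates[5]] * 2,
            "species_id": ["sp1", "sp1"],
            "count": [10, 20],
        })
        effort = pd.DataFrame({"effort_m2": [1000.0]},
                              index=pd.Index([cycles[0].cycle_id], name="cycle_id"))
        m = cpue(catch, effort, cycles)
        assert m.loc[cycles[0].cycle_id, "sp1"] == pytest.approx(0.03)

    def test_unobserved_species_zero(self, survey_cpue, synthetic_survey):
        truth = synthetic_survey["truth"]
        assert (survey_cpue >= 0).all().all()
        assert set(survey_cpue.index) == {c.cycle_id for c in
                                          synthetic_survey["cycles"]}

    def test_doubling_effort_halves_cpue(self, synthetic_survey):
        cycles = synthetic_survey["cycles"]
        eff = synthetic_survey["effort"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = cpue(synthetic_survey["catch"], eff, cycles)
            double = cpue(synthetic_survey["catch"], eff * 2.0, cycles)
        assert np.allclose(double.to_numpy(), base.to_numpy() / 2.0)

    def test_catch_outside_cycles_excluded_with_warning(self, synthetic_survey):
        cycles = synthetic_survey["cycles"][:2]
        catch = pd.DataFrame({
            "date": [cycles[0].dates[0], pd.Timestamp("1980-01-01")],
            "species_id": ["sp1", "sp1"],
            "count": [5, 99],
        })
        effort = pd.DataFrame(
            {"effort_m2": [100.0, 100.0]},
            index=pd.Index([c.cycle_id for c in cycles], name="cycle_id"))
        with pytest.warns(UserWarning, match="excluded 99"):
            m = cpue(catch, effort, cycles)
        assert m.sum().sum() == pytest.approx(0.05)


class TestFilterCommon:
    def test_species_below_threshold_removed(self):
        m = pd.DataFrame({"rare": [0.005, 0.004], "common": [0.5, 0.6]})
        out = filter_common(m, 0.01)
        assert list(out.columns) == ["common"]

    def test_all_above_threshold_unchanged(self):
        m = pd.DataFrame({"a": [0.5], "b": [0.2]})
        pd.testing.assert_frame_equal(filter_common(m, 0.01), m)

    def test_generator_seeds_known_common_species(self, survey_cpue,
                                                  synthetic_survey):
        """The simulated community seeds 97 of 196 species above the CPUE
        threshold; the filter recovers exactly the seeded set."""
        truth = synthetic_survey["truth"]
        out = filter_common(survey_cpue, 0.01)
        expected = {sp for sp, rec in truth["species"].items()
                    if not rec["rare"]}
        assert set(out.columns) == expected
        assert len(expected) == truth["n_common"] == 97

    def test_richness_never_increases_under_filtering(self, survey_cpue):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            before = diversity(survey_cpue)["richness"]
            after = diversity(filter_common(survey_cpue, 0.01))["richness"]
        assert (after <= before).all()


class TestDiversity:
    def test_equal_abundances_maximal_evenness(self):
        m = pd.DataFrame([[0.1, 0.1, 0.1, 0.1]], index=["c1"])
        d = diversity(m)
        assert d.loc["c1", "richness"] == 4
        assert d.loc["c1", "shannon"] == pytest.approx(np.log(4))
        assert d.loc["c1", "evenness"] == pytest.approx(1.0)

    def test_single_species_evenness_missing(self):
        d = diversity(pd.DataFrame([[0.3, 0.0]], index=["c1"]))
        assert d.loc["c1", "richness"] == 1
        assert np.isnan(d.loc["c1", "evenness"])

    def test_direct_summation_example(self):
        d = diversity(pd.DataFrame([[0.5, 0.25, 0.25]], index=["c1"]))
        assert d.loc["c1", "shannon"] == pytest.approx(1.5 * np.log(2), abs=1e-9)
        assert d.loc["c1", "evenness"] == pytest.approx(
            1.5 * np.log(2) / np.log(3), abs=1e-4)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="no catch"):
            diversity(pd.DataFrame([[0.0, 0.0]], index=["c1"]))


class TestAnomaly:
    def test_centering_identity(self):
        s = pd.Series([0.1, 0.2, 0.3, 0.3], index=list("abcd"))
        out = anomaly(s, baseline=["a", "b", "c"])
        assert out.loc[list("abc")].sum() == pytest.approx(0.0)

    def test_step_series(self):
        s = pd.Series([0.1] * 4 + [0.3] * 3, index=range(7))
        out = anomaly(s, baseline=[0, 1, 2, 3])
        assert np.allclose(out[4:], 0.2)

    def test_missing_baseline_year_rejected(self):
        s = pd.Series([0.1], index=["a"])
        with pytest.raises(ValueError, match="absent"):
            anomaly(s, baseline=["zz"])


class TestStructures:
    def test_identical_composition_identical_scores(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]] * 2 + [[3.0, 1.0, 0.5]],
                         index=["c1", "c2", "c3"])
        res = taxonomic_structure(m)
        assert np.allclose(res.scores.loc["c1"], res.scores.loc["c2"],
                           atol=1e-10)

    def test_species_permutation_invariance(self, survey_cpue):
        common = filter_common(survey_cpue, 0.01)
        base = taxonomic_structure(common)
        shuffled = common[list(common.columns[::-1])]
        perm = taxonomic_structure(shuffled)
        assert np.allclose(base.scores.to_numpy(), perm.scores.to_numpy(),
                           atol=1e-8)

    def test_step_community_separates_periods_on_axis1(self, survey_cpue,
                                                       synthetic_survey):
        """With a regime change in group CPUE at tau, the pre/post groups of
        cycles separate along the first taxonomic axis (positive silhouette)."""
        truth = synthetic_survey["truth"]
        common = filter_common(survey_cpue, 0.01)
        res = taxonomic_structure(common)
        s = res.scores.iloc[:, 0].to_numpy()
        tau = truth["tau_index"]
        pre, post = s[:tau], s[tau:]
        gap = abs(pre.mean() - post.mean())
        spread = pre.std() + post.std()
        assert gap > spread  # crude silhouette > 0

    def test_functional_structure_group_relabel_invariance(self, survey_cpue,
                                                           synthetic_survey):
        common = filter_common(survey_cpue, 0.01)
        labels = synthetic_survey["labels"].loc[common.columns]
        base = functional_structure(common, labels, "life_history")
        renamed = labels.copy()
        renamed["life_history"] = renamed["life_history"].map(
            lambda g: f"group-{g}")
        out = functional_structure(common, renamed, "life_history")
        assert np.allclose(np.abs(base.scores.to_numpy()),
                           np.abs(out.scores.to_numpy()), atol=1e-8)

    def test_unlabeled_species_rejected(self, survey_cpue, synthetic_survey):
        common = filter_common(survey_cpue, 0.01)
        labels = synthetic_survey["labels"].drop(common.columns[0])
        with pytest.raises(ValueError, match="lacking"):
            functional_structure(common, labels, "life_history")

    def test_five_groups_at_most_four_informative_axes(self, survey_cpue,
                                                       synthetic_survey):
        """Hellinger rows lie on the unit sphere, so five groups leave at
        most four axes carrying real compositional variance."""
        common = filter_common(survey_cpue, 0.01)
        res = functional_structure(common, synthetic_survey["labels"],
                                   "life_history")
        assert res.scores.shape[0] == len(common.index)
        assert res.proportion_explained[4] < 0.01


class TestLifeHistoryPca:
    def test_two_archetypes_oppose_on_axis1(self):
        traits = pd.DataFrame({
            "max_sl_mm": [300.0, 310.0],
            "maturation_sl_mm": [180.0, 170.0],
            "fecundity": [100.0, 100000.0],
            "oocyte_diam_mm": [2.5, 1.0],
            "parental_care_score": [4.0, 0.0],
        }, index=["equilibrium", "periodic"])
        res, labels = life_history_pca(traits)
        s = res.scores["PC1"]
        assert s["equilibrium"] * s["periodic"] < 0

    def test_cluster_recovery_from_archetypes(self):
        """200 species drawn from the five strategy archetypes at ~4:1
        between:within separation: >=90% get their generating label back."""
        rng = np.random.default_rng(20170110)
        groups = np.repeat(["ES", "EL", "IS", "PL", "PS"], 40)
        labels = pd.Series(groups, index=[f"sp{i:03d}" for i in range(200)])
        traits, _ = gen_trait_table(labels, seed=20170110)
        _, suggested = life_history_pca(traits)
        agree = (suggested == labels).mean()
        assert agree >= 0.90

    def test_duplicated_species_identical_scores(self):
        rng = np.random.default_rng(1)
        labels = pd.Series(["PS"] * 5 + ["EL"] * 5,
                           index=[f"sp{i}" for i in range(10)])
        traits, _ = gen_trait_table(labels, seed=3)
        traits = pd.concat([traits, traits.iloc[[0]].rename(
            index={traits.index[0]: "dup"})])
        res, _ = life_history_pca(traits)
        assert np.allclose(res.scores.iloc[0], res.scores.loc["dup"],
                           atol=1e-10)

    def test_size_unit_invariance(self):
        """Log + z-score makes suggested labels invariant to mm vs cm."""
        labels = pd.Series(np.repeat(["ES", "EL", "IS", "PL", "PS"], 10),
                           index=[f"sp{i}" for i in range(50)])
        traits, _ = gen_trait_table(labels, seed=5)
        cm = traits.copy()
        cm[["max_sl_mm", "maturation_sl_mm"]] /= 10.0
        _, a = life_history_pca(traits, sl_cut_mm=200.0)
        _, b = life_history_pca(cm, sl_cut_mm=20.0)
        assert (a == b).all()

    def test_nonpositive_trait_rejected(self):
        traits = pd.DataFrame({
            "max_sl_mm": [100.0, -5.0], "maturation_sl_mm": [60.0, 50.0],
            "fecundity": [500.0, 600.0], "oocyte_diam_mm": [1.0, 1.0],
            "parental_care_score": [0.0, 1.0],
        }, index=["a", "b"])
        with pytest.raises(ValueError, match="positive"):
            life_history_pca(traits)


class TestAssignTrophic:
    def _diet(self, **shares):
        cats = ["detritus", "algae", "plant", "invertebrate", "plankton",
                "fish", "other"]
        row = {c: shares.get(c, 0.0) for c in cats}
        return pd.DataFrame([row], index=["sp"])

    def test_pure_detritivore_level_1(self):
        assert assign_trophic(self._diet(detritus=1.0)).iloc[0] == 1.0

    def test_even_plant_animal_split_omnivore(self):
        d = self._diet(plant=0.5, invertebrate=0.5)
        assert assign_trophic(d).iloc[0] == 1.5

    def test_dominant_piscivore_level_3(self):
        d = self._diet(fish=0.7, invertebrate=0.3)
        assert assign_trophic(d).iloc[0] == 3.0

    def test_dominant_invertivore_level_2(self):
        d = self._diet(invertebrate=0.5, plankton=0.2, plant=0.3)
        assert assign_trophic(d).iloc[0] == 2.0

    def test_empty_diet_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_trophic(self._diet())


class TestRmAnova:
    def _table(self, rng, n_cycles=10, groups=4, effect=None):
        idx = [f"{2000 + i}-{2001 + i}" for i in range(n_cycles)]
        Y = pd.DataFrame(rng.normal(1.0, 0.3, (n_cycles, groups)), index=idx,
                         columns=[f"g{j}" for j in range(groups)])
        if effect is not None:
            Y.iloc[n_cycles // 2:, 0] += effect
        return Y

    def test_identical_periods_f_near_zero(self):
        idx = [f"{2000 + i}-{2001 + i}" for i in range(8)]
        pattern = np.tile([1.0, 2.0, 3.0], (4, 1))
        Y = pd.DataFrame(np.vstack([pattern, pattern]), index=idx)
        res = rm_anova(Y, split=2004)
        assert res.interaction["F"] == pytest.approx(0.0, abs=1e-20)
        assert res.table.loc["period", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_hand_worked_sums_of_squares(self):
        """Balanced 2-group, 2-period toy table: F from explicit textbook
        mixed-design sums of squares."""
        idx = ["2000-2001", "2001-2002", "2005-2006", "2006-2007"]
        Y = pd.DataFrame([[1.0, 2.0], [2.0, 3.0], [5.0, 4.0], [6.0, 5.0]],
                         index=idx, columns=["g1", "g2"])
        res = rm_anova(Y, split=2005)
        # hand: grand=3.5; period means 2.0/5.0 -> SS_A=2*2*(1.5^2)*2=18
        # subj means 1.5,2.5,4.5,5.5 -> SS_S(A)=2*(0.5^2*4)=2
        # group means 3.5,3.5 -> SS_B=0; cells [[1.5,2.5],[5.5,4.5]]
        # SS_AB=2*(0.5^2*4)=2; SS_total=22 -> SS_resid=0
        assert res.table.loc["period", "F"] == pytest.approx(18.0 / 1.0)
        assert res.table.loc["period", "df1"] == 1
        assert res.table.loc["period", "df2"] == 2
        assert res.interaction["df1"] == 1 and res.interaction["df2"] == 2
        assert res.interaction["F"] > 1e10  # zero residual error

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        Y = self._table(rng)
        mine = rm_anova(Y, split=2005)
        long = Y.reset_index().melt(id_vars="index", var_name="group",
                                    value_name="cpue")
        long["period"] = np.where(
            long["index"].str.slice(0, 4).astype(int) < 2005, "b", "a")
        theirs = pg.mixed_anova(data=long, dv="cpue", within="group",
                                subject="index", between="period")
        assert mine.interaction["F"] == pytest.approx(
            theirs.loc[theirs.Source == "Interaction", "F"].iloc[0], abs=1e-9)
        assert mine.table.loc["period", "F"] == pytest.approx(
            theirs.loc[theirs.Source == "period", "F"].iloc[0], abs=1e-9)

    def test_injected_step_contrast_detected(self):
        """A 5-sigma step in one group is flagged by its contrast in >=95%
        of replicates."""
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            Y = self._table(rng, effect=1.5)  # 5 x sd(0.3)
            res = rm_anova(Y, split=2005)
            hits += res.contrasts.loc["g0", "p"] < 0.05
        assert hits >= 57

    def test_single_cycle_period_rejected(self):
        rng = np.random.default_rng(0)
        Y = self._table(rng, n_cycles=5)
        with pytest.raises(ValueError, match="at least 2"):
            rm_anova(Y, split=2001)


class TestAggregateGroups:
    def test_group_sums(self, survey_cpue, synthetic_survey):
        common = filter_common(survey_cpue, 0.01)
        labels = synthetic_survey["labels"]
        grouped = aggregate_groups(common, labels, "life_history")
        assert grouped.shape[1] == 5
        assert np.allclose(grouped.sum(axis=1), common.sum(axis=1))
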