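"""Diversity, ordination, stability and summary metrics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutstrain import (FeatureTable, bray_curtis, chao1, pcoa,
                       prevalence_curve, shannon, stability_analysis,
                       top_taxa_summary)
from gutstrain.metrics import (age_diversity_correlation, aitchison,
                               alpha_diversity, clr_transform)
from gutstrain.tables import DistanceMatrix

from conftest import make_cohort, make_table


class TestChao1:
    def test_hand_value(self):
        assert chao1([5, 1, 1, 2]) == pytest.approx(6.0)

    def test_no_singletons_or_doubletons(self):
        assert chao1([5, 5, 3]) == 3.0

    def test_all_zero(self):
        assert chao1([0, 0, 0]) == 0.0

    def test_f2_zero_bias_correction(self):
        # f1=3, f2=0 -> S + f1(f1-1)/2
        assert chao1([1, 1, 1, 5]) == pytest.approx(4 + 3 * 2 / 2)

    def test_relative_input_degrades_with_warning(self):
        with pytest.warns(UserWarning, match="observed richness"):
            assert chao1([0.5, 0.5]) == 2.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chao1([-1, 2])

    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=1,
                    max_size=40))
    @settings(derandomize=True, max_examples=100)
    def test_at_least_observed_richness(self, counts):
        assert chao1(counts) >= (np.asarray(counts) > 0).sum()


class TestShannon:
    def test_uniform(self):
        assert shannon([0.25] * 4) == pytest.approx(np.log(4))

    def test_single_feature(self):
        assert shannon([1.0, 0.0]) == 0.0

    def test_hand_value(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2,
                    max_size=20))
    @settings(derandomize=True, max_examples=100)
    def test_uniform_is_maximal(self, p):
        assert shannon(p) <= np.log(len(p)) + 1e-12


class TestBetaDiversity:
    def test_identical_samples_zero(self):
        t = make_table({"a": [0.5, 0.5], "b": [0.5, 0.5]})
        assert bray_curtis(t).values[0, 1] == 0.0
        assert aitchison(t).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports(self):
        t = make_table({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        t = make_table({"a": [0.5, 0.0], "b": [0.5, 0.5], "c": [0.0, 0.5]})
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.5)

    def test_bray_curtis_bounded(self, small_tables):
        _, rel = small_tables
        d = bray_curtis(rel).values
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()

    def test_bad_pseudocount(self, small_tables):
        _, rel = small_tables
        with pytest.raises(ValueError):
            clr_transform(rel, pseudocount=-1)


class TestPcoa:
    def test_collinear_points_one_axis(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        d = np.abs(pts - pts.T)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d), n_axes=1)
        assert res.explained[0] == pytest.approx(1.0)

    def test_distance_round_trip(self):
        pts = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d), n_axes=2)
        c = res.coordinates.values
        recon = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        assert np.allclose(recon, d, atol=1e-9)

    def test_separated_clusters_anova(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, size=(10, 2)),
                         rng.normal(5, 0.1, size=(10, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(20)]
        groups = pd.Series(["case"] * 10 + ["control"] * 10, index=ids)
        res = pcoa(DistanceMatrix(ids, d), n_axes=2, groups=groups)
        assert res.anova_p < 0.05

    def test_axes_beyond_rank_rejected(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        d = np.abs(pts - pts.T)
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(["a", "b", "c"], d), n_axes=2)

    def test_explained_fractions_sum_below_one(self, small_tables):
        _, rel = small_tables
        sub = rel.subset_samples(rel.sample_ids[:30])
        res = pcoa(aitchison(sub.to_relative()), n_axes=5)
        assert res.explained.sum() <= 1 + 1e-9

    def test_agrees_with_skbio(self):
        import skbio
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(12)]
        ours = pcoa(DistanceMatrix(ids, d), n_axes=3)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, ids))
        assert np.allclose(np.abs(ours.coordinates.values),
                           np.abs(theirs.samples.values[:, :3]), atol=1e-8)


class TestAgeCorrelation:
    def _cohort_with_ages(self, ages):
        infants = [(f"I{i}", "control") for i in range(len(ages))]
        samples = [(f"S{i}", f"I{i}", a, "control") for i, a in enumerate(ages)]
        return make_cohort(infants, samples)

    @staticmethod
    def _ragged_counts():
        # samples with growing richness: Shannon = ln(1)..ln(5), all distinct
        feats = list("abcde")
        vals = {f: [1.0 if i >= j else 0.0 for i in range(5)]
                for j, f in enumerate(feats)}
        return make_table(vals, kind="counts")

    def test_perfectly_linear_index(self):
        # choose sample ages equal to each sample's Shannon index -> r = 1
        t = self._ragged_counts()
        div = alpha_diversity(t)
        cohort = self._cohort_with_ages(list(div["shannon"]))
        res = age_diversity_correlation(t, cohort).set_index("index")
        assert res.loc["shannon", "r"] == pytest.approx(1.0)

    def test_reversed_ages_negate_r(self):
        t = self._ragged_counts()
        div = alpha_diversity(t)
        cohort = self._cohort_with_ages([2.0 - s for s in div["shannon"]])
        res = age_diversity_correlation(t, cohort).set_index("index")
        assert res.loc["shannon", "r"] == pytest.approx(-1.0)

    def test_too_few_samples(self):
        t = make_table({"a": [0.5, 0.5], "b": [0.5, 0.5]})
        cohort = self._cohort_with_ages([1.0, 2.0])
        with pytest.raises(ValueError):
            age_diversity_correlation(t, cohort)

    def test_diversity_increases_with_age_in_synthetic_cohort(
            self, small_tables, small_cohort):
        counts, _ = small_tables
        res = age_diversity_correlation(counts, small_cohort).set_index("index")
        assert res.loc["shannon", "r"] > 0
        assert res.loc["chao1", "r"] > 0


class TestStability:
    def test_identical_profiles_zero_within(self):
        cohort = make_cohort(
            [("I1", "control"), ("I2", "control")],
            [("s1", "I1", 0.5, "control"), ("s2", "I1", 1.0, "control"),
             ("s3", "I2", 0.5, "control"), ("s4", "I2", 1.0, "control")])
        t = make_table({"a": [0.5, 0.5, 0.1, 0.9], "b": [0.5, 0.5, 0.9, 0.1]})
        t.data.columns = ["s1", "s2", "s3", "s4"]
        res = stability_analysis(t, cohort)
        row = res[res["transition"] == "0.5 months -> 1 month"].iloc[0]
        # infant I1 has identical profiles -> its within distance is 0
        assert row["mean_within"] <= 0.5  # mean over I1 (0) and I2 (1)
        assert row["n_within"] == 2

    def test_within_less_than_between_in_synthetic_cohort(
            self, small_tables, small_cohort):
        _, rel = small_tables
        res = stability_analysis(rel, small_cohort)
        ok = res.dropna(subset=["p_within_vs_between"])
        assert (ok["mean_within"] < ok["mean_between"]).all()
        assert (ok["p_within_vs_between"] < 1e-3).any()

    def test_closest_to_target_sample_used(self):
        # I1 has two samples in the 1-month bin [0.75, 1.5); 1.05 is closer
        # to the 1.0-month target than 1.4, so 1.05 is the representative.
        cohort = make_cohort(
            [("I1", "control"), ("I2", "control")],
            [("a_far", "I1", 1.4, "control"), ("b_near", "I1", 1.05, "control"),
             ("c", "I1", 2.0, "control"),
             ("d", "I2", 1.0, "control"), ("e", "I2", 2.0, "control")])
        t = make_table({"x": [0.0, 1.0, 1.0, 1.0, 1.0],
                        "y": [1.0, 0.0, 0.0, 0.0, 0.0]})
        t.data.columns = ["a_far", "b_near", "c", "d", "e"]
        res = stability_analysis(t, cohort)
        row = res[res["transition"] == "1 month -> 2 months"].iloc[0]
        # with b_near (identical to c) chosen, I1's within distance is 0
        assert row["mean_within"] == pytest.approx(0.0)


class TestSummaries:
    def test_k_equals_n_features(self):
        t = make_table({"a": [0.6, 0.2], "b": [0.4, 0.8]})
        out = top_taxa_summary(t, k=2)
        assert (out.loc["Others"] == 0).all()

    def test_column_sums_preserved(self, small_tables):
        _, rel = small_tables
        out = top_taxa_summary(rel, k=5)
        assert np.allclose(out.sum(axis=0), rel.data.sum(axis=0))

    def test_expected_membership(self):
        t = make_table({"big": [0.7, 0.7], "mid": [0.2, 0.2], "small": [0.1, 0.1]})
        out = top_taxa_summary(t, k=2)
        assert list(out.index) == ["big", "mid", "Others"]

    def test_k_too_large(self):
        t = make_table({"a": [1.0]})
        with pytest.raises(ValueError):
            top_taxa_summary(t, k=2)


class TestPrevalence:
    def test_absent_feature_zero(self, small_tables, small_cohort):
        _, rel = small_tables
        rel2 = FeatureTable(rel.data.copy(), kind="relative")
        rel2.data.loc[rel2.feature_ids[0]] = 0.0
        prev = prevalence_curve(rel2, small_cohort, rel2.feature_ids[0],
                                check := "group")
        assert np.nansum(prev.values) == 0.0

    def test_monotone_in_threshold(self, small_tables, small_cohort):
        _, rel = small_tables
        feat = "Escherichia_coli"
        p0 = prevalence_curve(rel, small_cohort, feat, detection_threshold=0.0)
        p1 = prevalence_curve(rel, small_cohort, feat, detection_threshold=0.001)
        assert (p1.fillna(0).values <= p0.fillna(0).values + 1e-12).all()

    def test_planted_subspecies_emerges_late(self, small_tables, small_cohort):
        _, rel = small_tables
        prev = prevalence_curve(rel, small_cohort,
                                "Bifidobacterium_longum_subsp_infantis",
                                detection_threshold=0.001)
        early = prev.loc[["birth", "0.5 months", "1 month"]].fillna(0)
        late = prev.loc[["9 months", "12 months"]]
        assert float(early.values.max()) <= 0.1
        assert np.nanmax(late.values) > 0.1

    def test_unknown_feature(self, small_tables, small_cohort):
        _, rel = small_tables
        with pytest.raises(KeyError):
            prevalence_curve(rel, small_cohort, "no_such_taxon")
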