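"""Nutrient cascade, niche classification and trait discretization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from symphy import trait_tables as tt


class TestFoodTypeSummary:
    @pytest.mark.parametrize(
        "amounts, expected",
        [([2.0, 4.0], 3.0), ([5.0], 5.0), ([1.0, 2.0, 100.0], 2.0)],
    )
    def test_median_across_examples(self, amounts, expected):
        ex = [{"B5": a} for a in amounts]
        out = tt.summarize_food_type("fruit", ex, [1.0] * len(ex))
        assert out.per_nutrient_amount["B5"] == pytest.approx(expected)

    def test_empty_examples_raise(self):
        with pytest.raises(tt.MissingFoodError):
            tt.summarize_food_type("fruit", [], [])

    def test_item_weight_is_mean_of_example_weights(self):
        out = tt.summarize_food_type("seed", [{"fat": 1}, {"fat": 2}],
                                     [2.0, 4.0])
        assert out.item_weight == pytest.approx(3.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e6), min_size=3, max_size=9),
           st.floats(1e3, 1e9))
    def test_median_robust_to_one_outlier(self, amounts, outlier):
        base = sorted(amounts)
        med0 = np.median(base)
        corrupted = base[:-1] + [base[-1] + outlier]
        med1 = np.median(corrupted)
        # replacing one value moves the median at most one order statistic
        assert med1 <= np.partition(base, len(base) - 1).max() + outlier
        assert med0 <= med1


class TestStandardization:
    @pytest.mark.parametrize(
        "amounts, weight, expected",
        [({"B5": 10.0}, 5.0, {"B5": 2.0}),
         ({"B5": 0.0}, 3.0, {"B5": 0.0}),
         ({"B5": 10.0, "fat": 4.0}, 2.0, {"B5": 5.0, "fat": 2.0})],
    )
    def test_per_gram_division(self, amounts, weight, expected):
        food = tt.FoodTypeNutrients("x", amounts, weight, 1)
        assert tt.standardize_per_gram(food) == pytest.approx(expected)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            tt.FoodTypeNutrients("x", {"B5": 1.0}, 0.0, 1)


class TestSpeciesProfile:
    def test_median_of_adult_and_juvenile(self):
        rec = tt.SpeciesDietRecord("sp", "fam", ["leaf"], ["root"])
        foods = {"leaf": {"B5": 2.0}, "root": {"B5": 4.0}}
        assert tt.species_profile(rec, foods)["B5"] == pytest.approx(3.0)

    def test_nested_medians(self):
        rec = tt.SpeciesDietRecord("sp", "fam", ["a", "b"], ["c"])
        foods = {"a": {"B5": 1.0}, "b": {"B5": 3.0}, "c": {"B5": 3.0}}
        # adult median(1, 3) = 2; species median(2, 3) = 2.5
        assert tt.species_profile(rec, foods)["B5"] == pytest.approx(2.5)

    def test_omnivores_average_instead_of_median(self):
        rec = tt.SpeciesDietRecord("sp", "fam", ["a", "b", "c"], [],
                                   omnivore=True)
        foods = {"a": {"B5": 1.0}, "b": {"B5": 2.0}, "c": {"B5": 6.0}}
        assert tt.species_profile(rec, foods)["B5"] == pytest.approx(3.0)

    def test_unknown_food_named_in_error(self):
        rec = tt.SpeciesDietRecord("sp", "fam", ["mystery"], [])
        with pytest.raises(tt.MissingFoodError, match="mystery"):
            tt.species_profile(rec, {"leaf": {"B5": 1.0}})


class TestFamilyProfile:
    @pytest.mark.parametrize(
        "values, expected",
        [([2.0, 4.0, 9.0], 4.0), ([7.0], 7.0), ([1.0, 2.0, 3.0, 4.0], 2.5)],
    )
    def test_median_across_species(self, values, expected):
        profs = [{"B5": v} for v in values]
        assert tt.family_profile(profs)["B5"] == pytest.approx(expected)

    def test_all_missing_nutrient_becomes_nan(self):
        profs = [{"B5": 1.0, "B9": np.nan}, {"B5": 2.0}]
        assert np.isnan(tt.family_profile(profs)["B9"])

    def test_species_order_does_not_matter(self):
        profs = [{"B5": v} for v in (5.0, 1.0, 3.0)]
        assert tt.family_profile(profs) == tt.family_profile(profs[::-1])


class TestMaskAndZTransform:
    def test_sparse_nutrient_dropped_strictly_above_threshold(self):
        tab = pd.DataFrame({
            "a": [1.0] * 13 + [np.nan] * 7,     # 35% missing -> dropped
            "b": [1.0] * 20,                     # 0% -> kept
            "c": [1.0] * 14 + [np.nan] * 6,     # exactly 30% -> kept
        })
        kept, dropped = tt.mask_sparse_nutrients(tab, ["a", "b", "c"], 0.30)
        assert dropped == ["a"] and kept == ["b", "c"]

    def test_z_transform_uses_sample_sd(self):
        out = tt.z_transform(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])

    def test_z_transform_skips_missing(self):
        out = tt.z_transform(np.array([1.0, np.nan, 3.0]))
        np.testing.assert_allclose(out[[0, 2]],
                                   [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert np.isnan(out[1])

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            tt.z_transform(np.array([2.0, 2.0, 2.0]))


class TestDiscretization:
    def make_table(self):
        return pd.DataFrame({
            "family": list("abcd"),
            "n_sampled": [4, 4, 4, 2],
            "n_obligate": [3, 2, 0, 2],
            "B5": [1.0, 2.0, 3.0, 4.0],
        })

    def test_obligate_strictly_above_half(self):
        out = tt.discretize_traits(self.make_table(), ["B5"])
        flags = dict(zip(out["family"], out["obligate"]))
        assert flags == {"a": 1, "b": 0, "c": 0, "d": 1}  # 2/4 is NOT obligate

    def test_median_split_marks_lower_half_low(self):
        out = tt.discretize_traits(self.make_table(), ["B5"])
        low = dict(zip(out["family"], out["B5_low_q50"]))
        assert low == {"a": 1.0, "b": 1.0, "c": 0.0, "d": 0.0}

    def test_both_quantile_codings_emitted(self):
        out = tt.discretize_traits(self.make_table(), ["B5"])
        assert {"B5_low_q25", "B5_low_q50"} <= set(out.columns)

    def test_unsampled_family_excluded(self):
        tab = self.make_table()
        tab.loc[0, "n_sampled"] = 0
        out = tt.discretize_traits(tab, ["B5"])
        assert "a" not in set(out["family"])


class TestNicheClassification:
    def test_any_omnivorous_species_makes_family_omnivore(self):
        assert tt.classify_family_niche(["phloem", "omnivore"]) == "omnivore"

    def test_specialist_requires_majority(self):
        assert tt.classify_family_niche(["blood"] * 3 + ["herbivore"]) == "blood"
        assert tt.classify_family_niche(["blood", "herbivore"]) == "omnivore"

    def test_unknown_only_is_other(self):
        assert tt.classify_family_niche([]) == "other"


class TestBuildFamilyTable:
    def make_inputs(self):
        foods = pd.DataFrame({
            "food_type": ["leaf", "leaf", "blood"],
            "example": ["l1", "l2", "b1"],
            "weight_g": [2.0, 4.0, 1.0],
            "B5": [2.0, 4.0, 0.5],
            "fat": [1.0, 3.0, 8.0],
        })
        species = pd.DataFrame({
            "species": ["s1", "s2", "s3"],
            "family": ["Fam1", "Fam1", "Fam2"],
            "adult_foods": ["leaf", "leaf", "blood"],
            "juvenile_foods": ["leaf", "", "blood"],
            "omnivore": [0, 0, 0],
            "obligate_status": ["non_obligate", "unresolved", "obligate"],
            "niche": ["herbivore", "herbivore", "blood"],
        })
        families = pd.DataFrame({
            "family": ["Fam1", "Fam2"],
            "species_richness": [120, 8],
            "family_age": [150.0, 90.0],
            "metabolism": ["holo", "hemi"],
        })
        return foods, species, families

    def test_pipeline_is_deterministic(self):
        f, s, fam = self.make_inputs()
        a = tt.build_family_table(f, s, fam).table
        b = tt.build_family_table(f, s, fam).table
        pd.testing.assert_frame_equal(a, b)

    def test_unresolved_species_excluded_from_proportion(self):
        f, s, fam = self.make_inputs()
        out = tt.build_family_table(f, s, fam).table.set_index("family")
        assert out.loc["Fam1", "n_sampled"] == 1  # s2 unresolved
        assert out.loc["Fam2", "n_obligate"] == 1

    def test_example_order_invariance(self):
        f, s, fam = self.make_inputs()
        a = tt.build_family_table(f, s, fam).table
        b = tt.build_family_table(f.iloc[::-1].reset_index(drop=True), s,
                                  fam).table
        pd.testing.assert_frame_equal(a, b)

    def test_nutrient_cascade_value(self):
        f, s, fam = self.make_inputs()
        out = tt.build_family_table(f, s, fam, z_scores=False).table
        # leaf: median(2,4)=3 per item, mean weight 3 g -> 1.0 per gram
        assert out.set_index("family").loc["Fam1", "B5"] == pytest.approx(1.0)
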