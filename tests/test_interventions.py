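import pytest

from mnsim.composition import (
    PER_100G,
    PER_DAY,
    NutrientVector,
    UnknownFoodError,
)
from mnsim.interventions import (
    BiofortificationSpec,
    BundleError,
    FoodSwapSpec,
    FortificantAddition,
    FortificationSpec,
    InterventionError,
    ScenarioBundle,
    SupplementSpec,
    apply_biofortification,
    apply_fortification,
    apply_supplement,
    compose_bundle,
)


class TestFortificantAddition:
    def test_oil_50_iu_per_g(self):
        add = FortificantAddition("retinyl_palmitate", 50.0, "IU/g")
        assert add.per_100g().get("vitamin_a") == pytest.approx(1500.0)

    def test_flour_folic_acid_g_per_t(self):
        add = FortificantAddition("folic_acid", 2.6, "g/t")
        assert add.per_100g().get("folate") == pytest.approx(260.0)

    def test_ferrous_fumarate_compound_vs_elemental(self):
        compound = FortificantAddition("ferrous_fumarate", 60.0, "g/t")
        elemental = FortificantAddition("ferrous_fumarate", 60.0, "g/t", elemental_equivalent=True)
        assert compound.per_100g().get("iron") == pytest.approx(6.0 * 0.328)
        assert elemental.per_100g().get("iron") == pytest.approx(6.0)

    def test_kio3_level(self):
        add = FortificantAddition("KIO3", 35.0, "mg/kg")
        # 35 mg KIO3/kg -> ~20.75 µg I per g salt
        assert add.per_100g().get("iodine") == pytest.approx(2075.46, abs=0.1)

    def test_retinyl_palmitate_mg_per_kg(self):
        add = FortificantAddition("retinyl_palmitate", 10.0, "mg/kg")
        assert add.per_100g().get("vitamin_a") == pytest.approx(550.0)

    def test_untracked_vitamin_contributes_nothing(self):
        add = FortificantAddition("riboflavin", 4.5, "mg/kg")
        assert add.per_100g() == NutrientVector.zero(PER_100G)

    def test_unknown_fortificant_rejected(self):
        with pytest.raises(InterventionError, match="unknown fortificant"):
            FortificantAddition("unobtainium", 1.0, "g/t")

    def test_unknown_unit_rejected(self):
        with pytest.raises(InterventionError):
            FortificantAddition("folic_acid", 1.0, "oz/gal")


class TestApplyFortification:
    def test_vehicle_gains_other_foods_untouched(self, small_table):
        spec = FortificationSpec("oil", (FortificantAddition("retinyl_palmitate", 50.0, "IU/g"),))
        fortified = apply_fortification(small_table, spec)
        assert fortified["oil"].composition.get("vitamin_a") == pytest.approx(100.0 + 1500.0)
        assert fortified["riceA"] == small_table["riceA"]
        # original table unmodified
        assert small_table["oil"].composition.get("vitamin_a") == pytest.approx(100.0)

    def test_level_zero_leaves_table_unchanged(self, small_table):
        spec = FortificationSpec("oil", (FortificantAddition("retinyl_palmitate", 0.0, "IU/g"),))
        assert apply_fortification(small_table, spec) == small_table

    def test_missing_vehicle_errors(self, small_table):
        spec = FortificationSpec("ghost", (FortificantAddition("folic_acid", 2.6, "g/t"),))
        with pytest.raises(UnknownFoodError, match="ghost"):
            apply_fortification(small_table, spec)


class TestApplyBiofortification:
    def test_replacement_identical_noop(self, small_table):
        spec = BiofortificationSpec("riceA", small_table["riceA"].composition)
        assert apply_biofortification(small_table, spec) == small_table

    def test_replacement_semantics_and_idempotence(self, small_table):
        replacement = NutrientVector({"vitamin_a": 50.0}, basis=PER_100G)
        spec = BiofortificationSpec("riceA", replacement)
        once = apply_biofortification(small_table, spec)
        twice = apply_biofortification(once, spec)
        assert once["riceA"].composition == replacement
        assert once == twice

    def test_missing_target_errors(self, small_table):
        spec = BiofortificationSpec("ghost", NutrientVector.zero(PER_100G))
        with pytest.raises(UnknownFoodError):
            apply_biofortification(small_table, spec)


class TestApplySupplement:
    def test_empty_supplement_unchanged(self):
        intake = NutrientVector({"iron": 10.9}, basis=PER_DAY)
        spec = SupplementSpec("none", NutrientVector.zero(PER_DAY))
        assert apply_supplement(intake, spec) == intake

    def test_ifa_iron_on_printed_row(self):
        intake = NutrientVector({"iron": 10.9}, basis=PER_DAY)
        ifa = SupplementSpec("IFA", NutrientVector({"iron": 60.0, "folate": 400.0}, basis=PER_DAY))
        assert apply_supplement(intake, ifa).get("iron") == pytest.approx(70.9)

    def test_ifa_folate_on_printed_row(self):
        intake = NutrientVector({"folate": 749.0}, basis=PER_DAY)
        ifa = SupplementSpec("IFA", NutrientVector({"folate": 400.0}, basis=PER_DAY))
        assert apply_supplement(intake, ifa).get("folate") == pytest.approx(1149.0)


class TestBundle:
    def test_two_fortifications_on_one_vehicle_conflict(self, simple_scenario):
        a = FortificationSpec("oil", (FortificantAddition("retinyl_palmitate", 50.0, "IU/g"),))
        b = FortificationSpec("oil", (FortificantAddition("folic_acid", 2.6, "g/t"),))
        with pytest.raises(BundleError):
            ScenarioBundle(simple_scenario, (a, b))

    def test_no_layers_gives_base_and_empty_contributions(self, simple_scenario, small_table):
        result = compose_bundle(ScenarioBundle(simple_scenario, ()), small_table)
        assert result.total == result.base
        assert dict(result.contributions) == {}

    def test_contributions_sum_to_total_minus_base(self, simple_scenario, small_table):
        layers = (
            FortificationSpec("oil", (FortificantAddition("retinyl_palmitate", 50.0, "IU/g"),)),
            SupplementSpec("IFA", NutrientVector({"iron": 60.0, "folate": 400.0}, basis=PER_DAY)),
            FoodSwapSpec("add", food_id="fish", grams=76.0),
        )
        result = compose_bundle(ScenarioBundle(simple_scenario, layers), small_table)
        for nutrient in result.total.amounts:
            delta = result.total.get(nutrient) - result.base.get(nutrient)
            summed = sum(c[nutrient] for c in result.contributions.values())
            assert summed == pytest.approx(delta, abs=1e-9)
            for contribution in result.contributions.values():
                assert contribution[nutrient] >= -1e-12  # additive layers

    def test_monotonicity_of_additive_layers(self, simple_scenario, small_table):
        base = compose_bundle(ScenarioBundle(simple_scenario, ()), small_table).total
        layers = (
            FortificationSpec("riceA", (FortificantAddition("ferrous_fumarate", 60.0, "g/t"),)),
            FoodSwapSpec("add", food_id="oil", grams=10.0),
            SupplementSpec("s", NutrientVector({"folate": 400.0}, basis=PER_DAY)),
        )
        total = compose_bundle(ScenarioBundle(simple_scenario, layers), small_table).total
        for nutrient in total.amounts:
            assert total.get(nutrient) >= base.get(nutrient) - 1e-12

    def test_disjoint_layers_commute(self, simple_scenario, small_table):
        a = FortificationSpec("oil", (FortificantAddition("retinyl_palmitate", 50.0, "IU/g"),))
        b = FortificationSpec("riceA", (FortificantAddition("folic_acid", 2.6, "g/t"),))
        ab = compose_bundle(ScenarioBundle(simple_scenario, (a, b)), small_table).total
        ba = compose_bundle(ScenarioBundle(simple_scenario, (b, a)), small_table).total
        assert ab.approx_equal(ba, rel=1e-12)

    def test_fortification_idempotent_at_table_level(self, small_table):
        spec = FortificationSpec("oil", (FortificantAddition("retinyl_palmitate", 50.0, "IU/g"),))
        once = apply_fortification(small_table, spec)
        # replacement semantics for re-applying the same programme: fortifying
        # the already-fortified table again adds again, so the bundle validator
        # forbids double layers; idempotence holds at the bundle level.
        assert once != apply_fortification(once, spec)

    def test_swap_add_requires_known_food(self, simple_scenario, small_table):
        bundle = ScenarioBundle(
            simple_scenario, (FoodSwapSpec("add", food_id="ghost", grams=10.0),)
        )
        with pytest.raises(UnknownFoodError):
            compose_bundle(bundle, small_table)


class TestSpecValidation:
    def test_swap_add_needs_positive_grams(self):
        with pytest.raises(InterventionError):
            FoodSwapSpec("add", food_id="x", grams=0.0)

    def test_swap_unknown_action(self):
        with pytest.raises(InterventionError):
            FoodSwapSpec("remove", food_id="x", grams=1.0)

    def test_supplement_schedule_validated(self):
        with pytest.raises(InterventionError):
            SupplementSpec("x", NutrientVector.zero(PER_DAY), schedule="weekly")

    def test_compliance_bounds(self):
        with pytest.raises(InterventionError):
            FortificationSpec("oil", (), compliance=1.5)
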