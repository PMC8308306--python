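import pytest

from mnsim.composition import (
    PER_100G,
    CompositionTable,
    FoodItem,
    NutrientVector,
)
from mnsim.diet import NPNL, DietScenario, Dish, MealPlan
from mnsim.fixtures import build_fixture


@pytest.fixture
def small_table() -> CompositionTable:
    """Tiny composition table used by unit tests."""
    return CompositionTable(
        [
            FoodItem(
                "riceA",
                "rice",
                "cooked",
                NutrientVector({"iron": 10.0, "folate": 20.0}, basis=PER_100G),
            ),
            FoodItem(
                "oil",
                "oil",
                "cooked",
                NutrientVector({"vitamin_a": 100.0}, basis=PER_100G),
                tags=frozenset({"fortification-vehicle"}),
            ),
            FoodItem(
                "fish",
                "fish",
                "cooked",
                NutrientVector({"iron": 2.0, "zinc": 1.0, "niacin": 4.0}, basis=PER_100G),
            ),
        ]
    )


@pytest.fixture
def simple_scenario() -> DietScenario:
    dishes = {
        "rice_dish": Dish("rice_dish", (("riceA", 150.0),)),
        "mixed_dish": Dish("mixed_dish", (("riceA", 50.0), ("oil", 10.0), ("fish", 80.0))),
        "oily_dish": Dish("oily_dish", (("oil", 20.0),)),
    }
    plan = MealPlan(
        (
            ("breakfast", (("rice_dish", 1.0),)),
            ("lunch", (("mixed_dish", 1.0), ("oily_dish", 1.0))),
            ("dinner", (("rice_dish", 1.0),)),
        )
    )
    return DietScenario(country="benin", setting="urban", group=NPNL, plan=plan, dishes=dishes)


@pytest.fixture(scope="session")
def benin_urban_npnl():
    return build_fixture("benin", "urban", "NPNL")


@pytest.fixture(scope="session")
def ghana_urban_pl():
    return build_fixture("ghana", "urban", "PL")
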