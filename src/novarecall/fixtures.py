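"""Fixture food databases.

Two scales are provided:

``mini``
    A hand-written ~25-item database that exercises every item kind
    (individual, grouped, preparation), every question type, all four Nova
    groups and five recipes — including a cooked-rice dish that
    disaggregates into rice, oil, onion, garlic and salt.  Recipe
    proportions are arbitrary but fixed.

``paper-shape``
    A programmatically generated database whose structural counts match a
    full-scale instrument: 526 food items (347 individual/grouped + 179
    culinary preparations) reachable through 57 key, 190 type-and-amount,
    47 added-item, 19 preparation and 82 detail questions (395 food
    questions in total).  Labels and compositions are seeded-random; the
    refiner questions here refine presentation only (their options do not
    re-bind items — the mini fixture covers re-binding).
"""

from __future__ import annotations

import numpy as np

from .database import (
    CompositionEntry,
    FoodDatabase,
    FoodItem,
    PortionOption,
    Recipe,
    RecipeIngredient,
    validate_database,
)
from .errors import ContractError
from .questions import Option, QuestionGraph, QuestionNode, Trigger

PAPER_SHAPE_COUNTS = {
    "questions_key": 57,
    "questions_type_amount": 190,
    "questions_added_item": 47,
    "questions_preparation": 19,
    "questions_detail": 82,
    "total_food_questions": 395,
    "items_individual_grouped": 347,
    "items_preparation": 179,
    "items_total": 526,
    "recipes": 179,
}


def generate_fixture(scale: str, seed: int = 0) -> FoodDatabase:
    """Build a validated fixture database at the given scale."""
    if scale == "mini":
        return mini_database()
    if scale == "paper-shape":
        return paper_shape_database(seed)
    raise ContractError(f"unknown fixture scale {scale!r} (use 'mini' or 'paper-shape')")


# ---------------------------------------------------------------------------
# mini fixture
# ---------------------------------------------------------------------------


def mini_database() -> FoodDatabase:
    comp = {}

    def c(code, kcal, protein, carb, fat, nova, sub):
        comp[code] = CompositionEntry(code, kcal, protein, carb, fat, nova, sub)

    # per 100 g
    c("C_RICE_RAW", 360.0, 7.0, 79.0, 0.7, 1, "grains")
    c("C_OIL", 884.0, 0.0, 0.0, 100.0, 2, "plant_oils")
    c("C_ONION", 40.0, 1.2, 9.0, 0.1, 1, "vegetables")
    c("C_GARLIC", 130.0, 6.4, 28.0, 0.2, 1, "vegetables")
    c("C_SALT", 0.0, 0.0, 0.0, 0.0, 2, "salt")
    c("C_BEANS_RAW", 330.0, 20.0, 60.0, 1.3, 1, "legumes")
    c("C_FISH_FRESH", 100.0, 20.0, 0.0, 2.5, 1, "fish")
    c("C_FISH_GRILLED", 120.0, 24.0, 0.0, 3.0, 1, "fish")
    c("C_FISH_CANNED", 190.0, 22.0, 0.0, 11.0, 3, "canned_fish")
    c("C_WHEAT_FLOUR", 360.0, 10.0, 75.0, 1.4, 1, "grains")
    c("C_MILK_WHOLE", 61.0, 3.2, 4.6, 3.5, 1, "dairy")
    c("C_MILK_SKIM", 35.0, 3.4, 4.9, 0.2, 1, "dairy")
    c("C_COFFEE", 2.0, 0.1, 0.3, 0.0, 1, "beverages")
    c("C_SUGAR", 387.0, 0.0, 100.0, 0.0, 2, "sugar")
    c("C_HBREAD_HOME", 330.0, 5.0, 65.0, 6.0, 3, "breads")
    c("C_HBREAD_BAKERY", 340.0, 5.5, 68.0, 6.0, 3, "breads")
    c("C_HBREAD_PACKED", 350.0, 4.5, 70.0, 7.0, 4, "packaged_breads")
    c("C_APPLE", 52.0, 0.3, 14.0, 0.2, 1, "fruits")
    c("C_BANANA", 89.0, 1.1, 23.0, 0.3, 1, "fruits")
    c("C_ZUCCHINI", 17.0, 1.2, 3.1, 0.3, 1, "vegetables")
    c("C_CARROT", 41.0, 0.9, 10.0, 0.2, 1, "vegetables")
    c("C_COLA", 42.0, 0.0, 10.6, 0.0, 4, "soft_drinks")
    c("C_CHEESE", 350.0, 25.0, 2.0, 27.0, 3, "cheeses")
    c("C_EGG", 143.0, 12.6, 0.7, 9.5, 1, "eggs")
    c("C_BUTTER", 717.0, 0.9, 0.1, 81.0, 2, "animal_fats")
    c("C_CAKE_PACKED", 410.0, 5.0, 55.0, 18.0, 4, "packaged_cakes")
    c("C_BREAD_ROLL", 300.0, 9.0, 58.0, 3.0, 3, "breads")
    c("C_BREAD_PACKED", 265.0, 9.0, 49.0, 3.5, 4, "packaged_breads")
    c("C_BREAD_WHOLE", 250.0, 11.0, 43.0, 3.5, 3, "breads")

    portions = {
        p.portion_id: p
        for p in [
            PortionOption("spoon_rice", "serving spoon", 90.0),
            PortionOption("ladle_beans", "ladle", 140.0),
            PortionOption("fillet", "fish fillet", 120.0),
            PortionOption("can_fish", "small can", 130.0),
            PortionOption("glass", "glass", 200.0),
            PortionOption("cup_coffee", "small cup", 50.0),
            PortionOption("slice_hbread", "slice", 50.0),
            PortionOption("unit_apple", "one apple", 130.0),
            PortionOption("unit_banana", "one banana", 90.0),
            PortionOption("slice_veg", "serving", 80.0),
            PortionOption("unit_carrot", "one carrot", 70.0),
            PortionOption("can_soda", "can", 350.0),
            PortionOption("slice_cheese", "slice", 30.0),
            PortionOption("slice_cake", "slice", 80.0),
            PortionOption("slice_bread", "slice", 50.0),
            PortionOption("unit_egg", "one egg", 50.0),
            PortionOption("tsp", "teaspoon", 5.0),
        ]
    }

    items = {}

    def item(item_id, label, key, kind, code=None, nova=None, sub=None,
             members=(), rep=None):
        items[item_id] = FoodItem(
            item_id=item_id, label=label, key_question_id=key, kind=kind,
            food_code=code, member_labels=tuple(members),
            representative_label=rep, nova_group=nova, nova_subgroup=sub)

    item("cooked_rice", "cooked white rice", "kq_rice", "preparation")
    item("cooked_beans", "cooked beans", "kq_beans", "preparation")
    item("grilled_fish", "grilled fresh fish", "kq_fish", "individual",
         "C_FISH_GRILLED", 1, "fish")
    item("fried_fish", "breaded fried fish", "kq_fish", "preparation")
    item("canned_fish", "canned fish", "kq_fish", "individual",
         "C_FISH_CANNED", 3, "canned_fish")
    item("whole_milk", "whole milk", "kq_milk", "individual", "C_MILK_WHOLE", 1, "dairy")
    item("skimmed_milk", "skimmed milk", "kq_milk", "individual", "C_MILK_SKIM", 1, "dairy")
    item("coffee", "brewed coffee", "kq_coffee", "individual", "C_COFFEE", 1, "beverages")
    item("sugar", "table sugar", "kq_coffee", "individual", "C_SUGAR", 2, "sugar")
    item("honey_bread_homemade", "honey bread, homemade", "kq_honey_bread",
         "individual", "C_HBREAD_HOME", 3, "breads")
    item("honey_bread_bakery", "honey bread, bakery", "kq_honey_bread",
         "individual", "C_HBREAD_BAKERY", 3, "breads")
    item("honey_bread_packed", "honey bread, branded packed", "kq_honey_bread",
         "individual", "C_HBREAD_PACKED", 4, "packaged_breads")
    item("apple", "apple", "kq_fruit", "individual", "C_APPLE", 1, "fruits")
    item("banana", "banana", "kq_fruit", "individual", "C_BANANA", 1, "fruits")
    item("squash_zucchini_eggplant", "squash, zucchini or eggplant",
         "kq_vegetables", "grouped", "C_ZUCCHINI", 1, "vegetables",
         members=("squash", "zucchini", "eggplant"), rep="zucchini")
    item("carrot", "carrot", "kq_vegetables", "individual", "C_CARROT", 1, "vegetables")
    item("cola", "cola soft drink", "kq_soda", "individual", "C_COLA", 4, "soft_drinks")
    item("cheese", "cheese", "kq_cheese", "individual", "C_CHEESE", 3, "cheeses")
    item("cake_homemade", "cake, homemade", "kq_cake", "preparation")
    item("cake_packed", "cake, packaged", "kq_cake", "individual",
         "C_CAKE_PACKED", 4, "packaged_cakes")
    item("french_roll", "french roll", "kq_bread", "individual",
         "C_BREAD_ROLL", 3, "breads")
    item("packed_sliced_bread", "packaged sliced bread", "kq_bread", "individual",
         "C_BREAD_PACKED", 4, "packaged_breads")
    item("wholegrain_bread", "whole-grain bread", "kq_bread", "individual",
         "C_BREAD_WHOLE", 3, "breads")
    item("boiled_egg", "boiled egg", "kq_eggs", "individual", "C_EGG", 1, "eggs")
    item("scrambled_egg", "scrambled egg", "kq_eggs", "preparation")

    recipes = {
        "cooked_rice": Recipe("cooked_rice", (
            RecipeIngredient("C_RICE_RAW", 0.88),
            RecipeIngredient("C_OIL", 0.05),
            RecipeIngredient("C_ONION", 0.04),
            RecipeIngredient("C_GARLIC", 0.02),
            RecipeIngredient("C_SALT", 0.01),
        )),
        "cooked_beans": Recipe("cooked_beans", (
            RecipeIngredient("C_BEANS_RAW", 0.90),
            RecipeIngredient("C_OIL", 0.05),
            RecipeIngredient("C_ONION", 0.03),
            RecipeIngredient("C_GARLIC", 0.015),
            RecipeIngredient("C_SALT", 0.005),
        )),
        "fried_fish": Recipe("fried_fish", (
            RecipeIngredient("C_FISH_FRESH", 0.80),
            RecipeIngredient("C_OIL", 0.12),
            RecipeIngredient("C_WHEAT_FLOUR", 0.08),
        ), source="adapted"),
        "cake_homemade": Recipe("cake_homemade", (
            RecipeIngredient("C_WHEAT_FLOUR", 0.35),
            RecipeIngredient("C_SUGAR", 0.25),
            RecipeIngredient("C_EGG", 0.20),
            RecipeIngredient("C_BUTTER", 0.15),
            RecipeIngredient("C_MILK_WHOLE", 0.05),
        )),
        "scrambled_egg": Recipe("scrambled_egg", (
            RecipeIngredient("C_EGG", 0.90),
            RecipeIngredient("C_OIL", 0.07),
            RecipeIngredient("C_SALT", 0.03),
        )),
    }

    yes_no = (Option("yes", "Yes"), Option("no", "No"))
    nodes = [
        QuestionNode("rq_restriction", "restriction",
                     "Do you follow a food restriction or special diet?",
                     options=(Option("none", "No restriction"),
                              Option("vegetarian", "Vegetarian"),
                              Option("vegan", "Vegan"),
                              Option("lactose_free", "Lactose-free"),
                              Option("gluten_free", "Gluten-free"))),
        QuestionNode("kq_rice", "key", "Did you eat rice yesterday?", options=yes_no),
        QuestionNode("ta_rice", "type_amount", "Which rice, and how much?",
                     options=(Option("cooked_rice", "cooked white rice",
                                     item_id="cooked_rice", portion_id="spoon_rice"),),
                     trigger=Trigger("kq_rice", ("yes",))),
        QuestionNode("kq_beans", "key", "Did you eat beans yesterday?", options=yes_no),
        QuestionNode("ta_beans", "type_amount", "How much beans?",
                     options=(Option("cooked_beans", "cooked beans",
                                     item_id="cooked_beans", portion_id="ladle_beans"),),
                     trigger=Trigger("kq_beans", ("yes",))),
        QuestionNode("kq_fish", "key", "Did you eat fish yesterday?", options=yes_no),
        QuestionNode("ta_fish", "type_amount", "Which fish, and how much?",
                     options=(Option("fresh_fish",
                                     "fresh fish (salmon, tuna, sardine, hake, tilapia)",
                                     portion_id="fillet"),
                              Option("canned_fish", "canned fish",
                                     item_id="canned_fish", portion_id="can_fish")),
                     trigger=Trigger("kq_fish", ("yes",))),
        QuestionNode("pr_fish", "preparation", "How was the fresh fish prepared?",
                     options=(Option("grilled", "grilled or roasted",
                                     item_id="grilled_fish"),
                              Option("fried", "breaded and fried",
                                     item_id="fried_fish")),
                     trigger=Trigger("ta_fish", ("fresh_fish",)),
                     impute_field="preparation", subject="fresh_fish"),
        QuestionNode("kq_milk", "key", "Did you drink milk yesterday?",
                     options=yes_no,
                     warning=("Attention! DO NOT include milk added to porridge or "
                              "breakfast cereal here so as not to duplicate what you "
                              "ate. If that's the case, change your answer above to "
                              "'no'.")),
        QuestionNode("ta_milk", "type_amount", "Which milk, and how much?",
                     options=(Option("whole_milk", "whole milk",
                                     item_id="whole_milk", portion_id="glass"),
                              Option("skimmed_milk", "skimmed milk",
                                     item_id="skimmed_milk", portion_id="glass")),
                     trigger=Trigger("kq_milk", ("yes",))),
        QuestionNode("kq_coffee", "key", "Did you drink coffee yesterday?", options=yes_no),
        QuestionNode("ta_coffee", "type_amount", "How much coffee?",
                     options=(Option("coffee", "brewed coffee",
                                     item_id="coffee", portion_id="cup_coffee"),),
                     trigger=Trigger("kq_coffee", ("yes",))),
        QuestionNode("ai_coffee_sugar", "added_item",
                     "Did you add sugar to the coffee?",
                     options=(Option("sugar", "sugar (teaspoons)",
                                     item_id="sugar", portion_id="tsp"),
                              Option("no_sugar", "no sugar")),
                     trigger=Trigger("ta_coffee", ("coffee",))),
        QuestionNode("kq_honey_bread", "key", "Did you eat honey bread yesterday?",
                     options=yes_no),
        QuestionNode("ta_honey_bread", "type_amount", "How much honey bread?",
                     options=(Option("honey_bread", "honey bread",
                                     portion_id="slice_hbread"),),
                     trigger=Trigger("kq_honey_bread", ("yes",))),
        QuestionNode("dt_honey_bread_source", "detail",
                     "What was the origin of the honey bread?",
                     options=(Option("homemade", "homemade",
                                     item_id="honey_bread_homemade"),
                              Option("bakery", "bought at a bakery",
                                     item_id="honey_bread_bakery"),
                              Option("packed", "branded packed",
                                     item_id="honey_bread_packed")),
                     trigger=Trigger("ta_honey_bread", ("honey_bread",)),
                     impute_field="source", subject="honey_bread"),
        QuestionNode("kq_fruit", "key", "Did you eat fruit yesterday?", options=yes_no),
        QuestionNode("ta_fruit", "type_amount", "Which fruit, and how much?",
                     options=(Option("apple", "apple", item_id="apple",
                                     portion_id="unit_apple"),
                              Option("banana", "banana", item_id="banana",
                                     portion_id="unit_banana")),
                     trigger=Trigger("kq_fruit", ("yes",))),
        QuestionNode("kq_vegetables", "key", "Did you eat vegetables yesterday?",
                     options=yes_no),
        QuestionNode("ta_vegetables", "type_amount", "Which vegetables, and how much?",
                     options=(Option("squash_zucchini_eggplant",
                                     "squash, zucchini or eggplant",
                                     item_id="squash_zucchini_eggplant",
                                     portion_id="slice_veg"),
                              Option("carrot", "carrot", item_id="carrot",
                                     portion_id="unit_carrot")),
                     trigger=Trigger("kq_vegetables", ("yes",))),
        QuestionNode("kq_soda", "key", "Did you drink soft drinks yesterday?",
                     options=yes_no),
        QuestionNode("ta_soda", "type_amount", "How much soft drink?",
                     options=(Option("cola", "cola", item_id="cola",
                                     portion_id="can_soda"),),
                     trigger=Trigger("kq_soda", ("yes",))),
        QuestionNode("kq_cheese", "key", "Did you eat cheese yesterday?", options=yes_no),
        QuestionNode("ta_cheese", "type_amount", "How much cheese?",
                     options=(Option("cheese", "cheese", item_id="cheese",
                                     portion_id="slice_cheese"),),
                     trigger=Trigger("kq_cheese", ("yes",))),
        QuestionNode("kq_cake", "key", "Did you eat cake yesterday?", options=yes_no),
        QuestionNode("ta_cake", "type_amount", "How much cake?",
                     options=(Option("cake", "cake", portion_id="slice_cake"),),
                     trigger=Trigger("kq_cake", ("yes",))),
        QuestionNode("dt_cake_origin", "detail",
                     "Was the cake homemade or purchased ready-to-eat?",
                     options=(Option("homemade", "homemade", item_id="cake_homemade"),
                              Option("purchased", "purchased ready-to-eat",
                                     item_id="cake_packed")),
                     trigger=Trigger("ta_cake", ("cake",)),
                     impute_field="source", subject="cake"),
        QuestionNode("kq_bread", "key", "Did you eat bread yesterday?", options=yes_no),
        QuestionNode("ta_bread", "type_amount", "Which bread, and how much?",
                     options=(Option("french_roll", "french roll",
                                     item_id="french_roll", portion_id="slice_bread"),
                              Option("packed_sliced_bread", "packaged sliced bread",
                                     item_id="packed_sliced_bread",
                                     portion_id="slice_bread"),
                              Option("wholegrain_bread", "whole-grain bread",
                                     item_id="wholegrain_bread",
                                     portion_id="slice_bread")),
                     trigger=Trigger("kq_bread", ("yes",))),
        QuestionNode("kq_eggs", "key", "Did you eat eggs yesterday?", options=yes_no),
        QuestionNode("ta_eggs", "type_amount", "How many eggs?",
                     options=(Option("egg", "egg", portion_id="unit_egg"),),
                     trigger=Trigger("kq_eggs", ("yes",))),
        QuestionNode("pr_eggs", "preparation", "How were the eggs prepared?",
                     options=(Option("boiled", "boiled", item_id="boiled_egg"),
                              Option("scrambled", "scrambled",
                                     item_id="scrambled_egg")),
                     trigger=Trigger("ta_eggs", ("egg",)),
                     impute_field="preparation", subject="egg"),
        QuestionNode("uq_amount", "usual_intake",
                     "Was the overall amount of food you ate yesterday about usual?",
                     options=(Option("usual", "about usual"),
                              Option("less", "less than usual"),
                              Option("more", "more than usual"))),
        QuestionNode("uq_typical", "usual_intake",
                     "Does yesterday's intake represent your typical daily intake?",
                     options=(Option("typical", "yes, typical"),
                              Option("not_typical", "no, not typical"))),
        QuestionNode("sq_supplement", "supplement",
                     "Did you take any vitamin or mineral supplement yesterday?",
                     options=yes_no),
    ]

    graph = QuestionGraph(nodes)
    counts = {
        "items_total": len(items),
        "items_preparation": sum(1 for i in items.values() if i.kind == "preparation"),
        "recipes": len(recipes),
        "questions_key": 13,
        "total_food_questions": 13 + 13 + 1 + 2 + 2,
    }
    counts["items_individual_grouped"] = counts["items_total"] - counts["items_preparation"]
    db = FoodDatabase(items=items, recipes=recipes, composition=comp,
                      portions=portions, graph=graph, expected_counts=counts)
    validate_database(db)
    return db


# ---------------------------------------------------------------------------
# paper-shape fixture
# ---------------------------------------------------------------------------

_N_KEY = 57
_N_TYPE_AMOUNT = 190
_N_ADDED = 47
_N_PREP_Q = 19
_N_DETAIL = 82
_N_ITEMS = 526
_N_PREP_ITEMS = 179
_N_GROUPED = 60
_N_INGREDIENTS = 40


def paper_shape_database(seed: int = 0) -> FoodDatabase:
    rng = np.random.default_rng(seed)

    # ingredient pool + compositions ------------------------------------
    comp: dict[str, CompositionEntry] = {}

    def random_entry(code: str) -> CompositionEntry:
        protein = float(np.round(rng.uniform(0, 25), 2))
        carb = float(np.round(rng.uniform(0, 70), 2))
        fat = float(np.round(rng.uniform(0, 30), 2))
        macro = 4 * protein + 4 * carb + 9 * fat
        energy = float(np.round(macro * rng.uniform(0.9, 1.1), 1))
        nova = int(rng.integers(1, 5))
        return CompositionEntry(code, energy, protein, carb, fat, nova,
                                f"sg{nova}_{int(rng.integers(1, 4))}")

    ingredient_codes = [f"ING_{i:03d}" for i in range(_N_INGREDIENTS)]
    for code in ingredient_codes:
        comp[code] = random_entry(code)

    # question-tree shape ------------------------------------------------
    ta_per_key = np.ones(_N_KEY, dtype=int)
    for k in rng.integers(0, _N_KEY, _N_TYPE_AMOUNT - _N_KEY):
        ta_per_key[k] += 1
    items_per_ta = np.ones(_N_TYPE_AMOUNT, dtype=int)
    for k in rng.integers(0, _N_TYPE_AMOUNT, _N_ITEMS - _N_TYPE_AMOUNT):
        items_per_ta[k] += 1

    kinds = np.array(["individual"] * _N_ITEMS, dtype=object)
    prep_idx = rng.choice(_N_ITEMS, _N_PREP_ITEMS, replace=False)
    kinds[prep_idx] = "preparation"
    remaining = np.setdiff1d(np.arange(_N_ITEMS), prep_idx)
    grouped_idx = rng.choice(remaining, _N_GROUPED, replace=False)
    kinds[grouped_idx] = "grouped"

    portions = {
        f"P_{i:02d}": PortionOption(f"P_{i:02d}", f"portion {i}",
                                    float(g))
        for i, g in enumerate([5, 10, 15, 30, 50, 60, 80, 100, 130, 150, 200, 350])
    }
    portion_ids = sorted(portions)

    items: dict[str, FoodItem] = {}
    recipes: dict[str, Recipe] = {}
    nodes: list[QuestionNode] = []
    yes_no = (Option("yes", "Yes"), Option("no", "No"))

    nodes.append(QuestionNode(
        "rq_restriction", "restriction", "Any food restriction or special diet?",
        options=(Option("none", "none"), Option("vegetarian", "vegetarian"),
                 Option("vegan", "vegan"))))

    ta_nodes: list[QuestionNode] = []
    item_counter = 0
    ta_counter = 0
    for k in range(_N_KEY):
        key_id = f"kq_{k:02d}"
        nodes.append(QuestionNode(key_id, "key",
                                  f"Did you eat food group {k} yesterday?",
                                  options=yes_no))
        for _ in range(ta_per_key[k]):
            ta_id = f"ta_{ta_counter:03d}"
            options = []
            for _ in range(items_per_ta[ta_counter]):
                item_id = f"item_{item_counter:03d}"
                kind = str(kinds[item_counter])
                if kind == "preparation":
                    m = int(rng.integers(2, 7))
                    codes = list(rng.choice(ingredient_codes, m, replace=False))
                    weights = rng.random(m) + 0.1
                    weights = weights / weights.sum()
                    recipes[item_id] = Recipe(item_id, tuple(
                        RecipeIngredient(code, float(w))
                        for code, w in zip(codes, weights)),
                        source="adapted" if rng.random() < 0.056 else "standard")
                    items[item_id] = FoodItem(item_id, f"dish {item_counter}",
                                              key_id, "preparation")
                else:
                    code = f"F_{item_counter:03d}"
                    comp[code] = random_entry(code)
                    if kind == "grouped":
                        members = tuple(f"food {item_counter}{suffix}"
                                        for suffix in "abc")
                        items[item_id] = FoodItem(
                            item_id, f"grouped food {item_counter}", key_id,
                            "grouped", food_code=code, member_labels=members,
                            representative_label=members[0],
                            nova_group=comp[code].nova_group,
                            nova_subgroup=comp[code].nova_subgroup)
                    else:
                        items[item_id] = FoodItem(
                            item_id, f"food {item_counter}", key_id,
                            "individual", food_code=code,
                            nova_group=comp[code].nova_group,
                            nova_subgroup=comp[code].nova_subgroup)
                options.append(Option(
                    f"opt_{item_counter:03d}", items[item_id].label,
                    item_id=item_id,
                    portion_id=portion_ids[int(rng.integers(0, len(portion_ids)))]))
                item_counter += 1
            node = QuestionNode(ta_id, "type_amount",
                                f"Which, and how much? ({ta_id})",
                                options=tuple(options),
                                trigger=Trigger(key_id, ("yes",)),
                                warning=("Attention! DO NOT report this food again "
                                         "under another question.")
                                if rng.random() < 0.1 else None)
            nodes.append(node)
            ta_nodes.append(node)
            ta_counter += 1

    # refiner + added-item questions ------------------------------------
    all_slots = [(node, option) for node in ta_nodes for option in node.options]
    slot_idx = rng.choice(len(all_slots), _N_PREP_Q + _N_DETAIL, replace=False)
    refiner_levels = (("raw", "cooked", "roasted"), ("grilled", "fried"),
                      ("plain", "with_sauce", "breaded", "stewed"))
    for j, idx in enumerate(slot_idx):
        parent, option = all_slots[idx]
        if j < _N_PREP_Q:
            qid, qtype, fieldname = f"pr_{j:02d}", "preparation", "preparation"
        else:
            qid, qtype = f"dt_{j - _N_PREP_Q:02d}", "detail"
            fieldname = "source" if rng.random() < 0.5 else "type"
        levels = refiner_levels[int(rng.integers(0, len(refiner_levels)))]
        nodes.append(QuestionNode(
            qid, qtype, f"More detail about {option.label}?",
            options=tuple(Option(lv, lv) for lv in levels),
            trigger=Trigger(parent.question_id, (option.option_id,)),
            impute_field=fieldname, subject=option.item_id))

    added_parents = rng.choice(len(ta_nodes), _N_ADDED, replace=False)
    for j, idx in enumerate(added_parents):
        parent = ta_nodes[idx]
        reuse = parent.options[0]
        nodes.append(QuestionNode(
            f"ai_{j:02d}", "added_item",
            f"Did you add anything to {reuse.label}?",
            options=(Option("added", f"added {reuse.label}", item_id=reuse.item_id,
                            grams=5.0),
                     Option("nothing", "nothing added")),
            trigger=Trigger(parent.question_id, None)))

    nodes.append(QuestionNode(
        "uq_amount", "usual_intake", "Was the amount eaten about usual?",
        options=(Option("usual", "about usual"), Option("less", "less"),
                 Option("more", "more"))))
    nodes.append(QuestionNode(
        "uq_typical", "usual_intake", "Was yesterday typical?",
        options=(Option("typical", "typical"), Option("not_typical", "not typical"))))
    nodes.append(QuestionNode(
        "sq_supplement", "supplement", "Any vitamin or mineral supplement?",
        options=yes_no))

    graph = QuestionGraph(nodes)
    db = FoodDatabase(items=items, recipes=recipes, composition=comp,
                      portions=portions, graph=graph,
                      expected_counts=dict(PAPER_SHAPE_COUNTS))
    validate_database(db)
    return db
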