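"""Food database bundle: schema, validation and I/O.

The recall engine is backed by a long-format database that couples every
selectable food item with its composition-table food code, its Nova
food-processing group (1 unprocessed/minimally processed, 2 processed
culinary ingredient, 3 processed, 4 ultra-processed) and, for culinary
preparations, a standardized recipe that disaggregates the dish into
ingredient mass fractions.

On disk a database is a directory bundle::

    items.csv        item_id,label,key_question_id,kind,food_code,
                     member_labels,representative_label,nova_group,nova_subgroup
    recipes.csv      item_id,food_code,mass_fraction,source       (long format)
    composition.csv  food_code,energy_kcal_per_100g,protein_g,carb_g,fat_g,
                     nova_group,nova_subgroup
    portions.csv     portion_id,label,grams
    questions.json   the question graph
    manifest.yaml    schema_version + optional expected counts

CSV files are UTF-8 with a header row and '.' decimal separator.  Energy may
alternatively be supplied as ``energy_kj_per_100g``; it is converted to kcal
(factor 4.184) at load with a logged note.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import json
import pandas as pd
import yaml

from .errors import IntegrityError, SchemaError
from .questions import QuestionGraph, count_questions

logger = logging.getLogger(__name__)

KCAL_PER_KJ = 1.0 / 4.184
ITEM_KINDS = ("individual", "grouped", "preparation")
NOVA_GROUPS = (1, 2, 3, 4)
#: kcal per gram of protein / carbohydrate / fat (Atwater factors)
ATWATER = {"protein_g": 4.0, "carb_g": 4.0, "fat_g": 9.0}
SCHEMA_VERSION = 1

_BUNDLE_FILES = ("items.csv", "recipes.csv", "composition.csv", "portions.csv",
                 "questions.json", "manifest.yaml")


@dataclass(frozen=True)
class FoodItem:
    item_id: str
    label: str
    key_question_id: str
    kind: str  # individual | grouped | preparation
    food_code: Optional[str] = None
    member_labels: tuple[str, ...] = ()
    representative_label: Optional[str] = None
    nova_group: Optional[int] = None
    nova_subgroup: Optional[str] = None


@dataclass(frozen=True)
class RecipeIngredient:
    food_code: str
    mass_fraction: float  # fraction of prepared-dish mass, unitless


@dataclass(frozen=True)
class Recipe:
    item_id: str
    ingredients: tuple[RecipeIngredient, ...]
    source: str = "standard"  # standard | adapted


@dataclass(frozen=True)
class CompositionEntry:
    food_code: str
    energy_kcal_per_100g: float
    protein_g: float
    carb_g: float
    fat_g: float
    nova_group: int
    nova_subgroup: str = ""


@dataclass(frozen=True)
class PortionOption:
    portion_id: str
    label: str
    grams: float


@dataclass
class FoodDatabase:
    items: dict[str, FoodItem]
    recipes: dict[str, Recipe]  # keyed by item_id
    composition: dict[str, CompositionEntry]
    portions: dict[str, PortionOption]
    graph: QuestionGraph
    schema_version: int = SCHEMA_VERSION
    expected_counts: Optional[dict] = None
    warnings: list[str] = field(default_factory=list)

    def option_grams(self, option) -> Optional[float]:
        """Mass of one unit of an option: inline grams, else portion lookup."""
        if option.grams is not None:
            return float(option.grams)
        if option.portion_id is not None:
            portion = self.portions.get(option.portion_id)
            if portion is None:
                raise IntegrityError(f"unknown portion {option.portion_id!r}")
            return portion.grams
        return None


@dataclass
class CountReport:
    items_by_kind: dict[str, int]
    items_total: int
    recipes: int
    questions_by_type: dict[str, int]
    total_food_questions: int
    mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_database(db: FoodDatabase) -> list[str]:
    """Check every schema invariant; return warnings, raise on violations."""
    warnings: list[str] = []

    for item in db.items.values():
        if item.kind not in ITEM_KINDS:
            raise SchemaError("items.csv", item.item_id, f"unknown kind {item.kind!r}")
        if item.kind == "preparation":
            if item.food_code:
                raise SchemaError("items.csv", item.item_id,
                                  "preparation items carry no food_code")
            if item.nova_group is not None:
                raise SchemaError(
                    "items.csv", item.item_id,
                    "preparation items carry no Nova group (it comes from ingredients)")
            if item.item_id not in db.recipes:
                raise IntegrityError(
                    f"preparation item {item.item_id!r} has no recipe")
        else:
            if not item.food_code:
                raise SchemaError("items.csv", item.item_id, "food_code required")
            if item.food_code not in db.composition:
                raise IntegrityError(
                    f"item {item.item_id!r} cites unknown food_code {item.food_code!r}")
            if item.nova_group not in NOVA_GROUPS:
                raise SchemaError("items.csv", item.item_id,
                                  f"nova_group must be one of {NOVA_GROUPS}")
        if item.kind == "grouped":
            if len(item.member_labels) < 2:
                raise SchemaError("items.csv", item.item_id,
                                  "grouped items need at least 2 member labels")
            if item.representative_label not in item.member_labels:
                raise SchemaError(
                    "items.csv", item.item_id,
                    "representative_label must be one of member_labels "
                    "(its food_code stands for the whole group)")
        if item.key_question_id not in db.graph or db.graph[item.key_question_id].qtype != "key":
            raise IntegrityError(
                f"item {item.item_id!r} cites unknown key question "
                f"{item.key_question_id!r}")

    for recipe in db.recipes.values():
        if recipe.item_id not in db.items:
            raise IntegrityError(f"recipe for unknown item {recipe.item_id!r}")
        if db.items[recipe.item_id].kind != "preparation":
            raise SchemaError("recipes.csv", recipe.item_id,
                              "recipes may only reference preparation items")
        if not recipe.ingredients:
            raise SchemaError("recipes.csv", recipe.item_id, "recipe has no ingredients")
        total = sum(i.mass_fraction for i in recipe.ingredients)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            # load-time normalization already happened; only possible if the
            # database was assembled in memory
            raise SchemaError("recipes.csv", recipe.item_id,
                              f"mass fractions sum to {total}, not 1")
        for ing in recipe.ingredients:
            if ing.mass_fraction <= 0:
                raise SchemaError("recipes.csv", recipe.item_id,
                                  f"non-positive mass fraction for {ing.food_code!r}")
            entry = db.composition.get(ing.food_code)
            if entry is None:
                raise IntegrityError(
                    f"recipe {recipe.item_id!r} cites unknown food_code "
                    f"{ing.food_code!r}")
            if entry.nova_group not in NOVA_GROUPS:
                raise IntegrityError(
                    f"ingredient {ing.food_code!r} lacks a Nova assignment")

    for entry in db.composition.values():
        if entry.energy_kcal_per_100g < 0:
            raise SchemaError("composition.csv", entry.food_code, "negative energy")
        macros = {"protein_g": entry.protein_g, "carb_g": entry.carb_g,
                  "fat_g": entry.fat_g}
        if all(v is not None and not math.isnan(v) for v in macros.values()):
            macro_kcal = sum(ATWATER[k] * v for k, v in macros.items())
            stated = entry.energy_kcal_per_100g
            if stated > 0 and abs(macro_kcal - stated) > 0.30 * stated:
                warnings.append(
                    f"composition.csv: {entry.food_code}: macronutrient energy "
                    f"{macro_kcal:.1f} kcal deviates >30% from stated {stated:.1f} kcal")

    for portion in db.portions.values():
        if portion.grams <= 0:
            raise SchemaError("portions.csv", portion.portion_id, "grams must be positive")

    _validate_graph_bindings(db)
    for msg in warnings:
        logger.warning(msg)
    db.warnings = warnings
    return warnings


def _validate_graph_bindings(db: FoodDatabase) -> None:
    """Options must bind existing items/portions; every item must be reachable
    from exactly one key question."""
    bound_key: dict[str, set[str]] = {}
    for node in db.graph.ordered():
        key = db.graph.key_question_of(node)
        for option in node.options:
            if option.item_id is not None:
                if option.item_id not in db.items:
                    raise IntegrityError(
                        f"question {node.question_id!r} option {option.option_id!r} "
                        f"binds unknown item {option.item_id!r}")
                if key is not None:
                    bound_key.setdefault(option.item_id, set()).add(key.question_id)
            if option.portion_id is not None and option.portion_id not in db.portions:
                raise IntegrityError(
                    f"question {node.question_id!r} option {option.option_id!r} "
                    f"cites unknown portion {option.portion_id!r}")
    for item in db.items.values():
        keys = bound_key.get(item.item_id, set())
        if not keys:
            raise IntegrityError(f"item {item.item_id!r} unreachable from any key question")
        if keys != {item.key_question_id}:
            raise IntegrityError(
                f"item {item.item_id!r} reachable from key questions {sorted(keys)} "
                f"but declares {item.key_question_id!r}")


def validate_counts(db: FoodDatabase, expected: Optional[dict] = None) -> CountReport:
    """Report structural counts and flag mismatches against the expected-count
    manifest (the database's own manifest, unless ``expected`` is supplied)."""
    by_kind = {kind: 0 for kind in ITEM_KINDS}
    for item in db.items.values():
        by_kind[item.kind] += 1
    qcounts = count_questions(db.graph)
    qby = {qt: qcounts[qt] for qt in
           ("restriction", "key", "type_amount", "added_item", "preparation",
            "detail", "usual_intake", "supplement")}
    report = CountReport(
        items_by_kind=by_kind,
        items_total=len(db.items),
        recipes=len(db.recipes),
        questions_by_type=qby,
        total_food_questions=qcounts["total_food"],
    )
    expected = expected if expected is not None else (db.expected_counts or {})
    actual_flat = {
        "items_total": report.items_total,
        "items_individual_grouped": by_kind["individual"] + by_kind["grouped"],
        "items_preparation": by_kind["preparation"],
        "recipes": report.recipes,
        "total_food_questions": report.total_food_questions,
        **{f"questions_{qt}": n for qt, n in qby.items()},
    }
    for name, want in expected.items():
        got = actual_flat.get(name)
        if got is None:
            report.mismatches.append(f"manifest expects unknown count {name!r}")
        elif got != want:
            report.mismatches.append(f"{name}: expected {want}, found {got}")
    return report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def load_database(path) -> FoodDatabase:
    """Load and fully validate a database bundle directory."""
    root = Path(path)
    for name in _BUNDLE_FILES:
        if not (root / name).exists():
            raise SchemaError(str(root), name, "bundle file missing")

    with open(root / "manifest.yaml", "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh) or {}
    schema_version = int(manifest.get("schema_version", SCHEMA_VERSION))
    if schema_version != SCHEMA_VERSION:
        raise SchemaError("manifest.yaml", "schema_version",
                          f"unsupported schema version {schema_version}")

    with open(root / "questions.json", "r", encoding="utf-8") as fh:
        graph = QuestionGraph.from_payload(json.load(fh))

    comp_df = pd.read_csv(root / "composition.csv", dtype={"food_code": str})
    if "energy_kcal_per_100g" not in comp_df.columns:
        if "energy_kj_per_100g" in comp_df.columns:
            logger.info("composition.csv: converting energy from kJ to kcal (/4.184)")
            comp_df["energy_kcal_per_100g"] = comp_df["energy_kj_per_100g"] * KCAL_PER_KJ
        else:
            raise SchemaError("composition.csv", "<header>",
                              "energy_kcal_per_100g (or energy_kj_per_100g) required")
    composition: dict[str, CompositionEntry] = {}
    for row in comp_df.itertuples(index=False):
        code = str(row.food_code)
        if code in composition:
            raise SchemaError("composition.csv", code, "duplicate food_code")
        composition[code] = CompositionEntry(
            food_code=code,
            energy_kcal_per_100g=float(row.energy_kcal_per_100g),
            protein_g=float(row.protein_g),
            carb_g=float(row.carb_g),
            fat_g=float(row.fat_g),
            nova_group=int(row.nova_group),
            nova_subgroup=_opt_str(getattr(row, "nova_subgroup", "")) or "",
        )

    items_df = pd.read_csv(root / "items.csv", dtype=str)
    items: dict[str, FoodItem] = {}
    for row in items_df.itertuples(index=False):
        item_id = str(row.item_id)
        if item_id in items:
            raise SchemaError("items.csv", item_id, "duplicate item_id")
        members = _opt_str(getattr(row, "member_labels", None))
        nova = _opt_str(getattr(row, "nova_group", None))
        items[item_id] = FoodItem(
            item_id=item_id,
            label=str(row.label),
            key_question_id=str(row.key_question_id),
            kind=str(row.kind),
            food_code=_opt_str(getattr(row, "food_code", None)),
            member_labels=tuple(members.split("|")) if members else (),
            representative_label=_opt_str(getattr(row, "representative_label", None)),
            nova_group=int(nova) if nova else None,
            nova_subgroup=_opt_str(getattr(row, "nova_subgroup", None)),
        )

    recipes_df = pd.read_csv(root / "recipes.csv", dtype={"item_id": str, "food_code": str})
    recipes: dict[str, Recipe] = {}
    for item_id, group in recipes_df.groupby("item_id", sort=False):
        ingredients = [
            RecipeIngredient(food_code=str(r.food_code), mass_fraction=float(r.mass_fraction))
            for r in group.itertuples(index=False)
        ]
        for ing in ingredients:
            if ing.mass_fraction <= 0:
                raise SchemaError("recipes.csv", str(item_id),
                                  f"non-positive mass fraction for {ing.food_code!r}")
        total = sum(i.mass_fraction for i in ingredients)
        if total <= 0:
            raise SchemaError("recipes.csv", str(item_id), "zero total mass fraction")
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            logger.warning("recipes.csv: %s: mass fractions sum to %.6f; normalizing to 1",
                           item_id, total)
            ingredients = [
                RecipeIngredient(i.food_code, i.mass_fraction / total) for i in ingredients
            ]
        sources = set(group["source"]) if "source" in group else {"standard"}
        if len(sources) > 1:
            raise SchemaError("recipes.csv", str(item_id), "inconsistent recipe source")
        recipes[str(item_id)] = Recipe(
            item_id=str(item_id),
            ingredients=tuple(ingredients),
            source=str(next(iter(sources))),
        )

    portions_df = pd.read_csv(root / "portions.csv", dtype={"portion_id": str})
    portions = {
        str(r.portion_id): PortionOption(str(r.portion_id), str(r.label), float(r.grams))
        for r in portions_df.itertuples(index=False)
    }

    db = FoodDatabase(
        items=items,
        recipes=recipes,
        composition=composition,
        portions=portions,
        graph=graph,
        schema_version=schema_version,
        expected_counts=manifest.get("expected_counts"),
    )
    validate_database(db)
    return db


def write_database(db: FoodDatabase, path) -> None:
    """Write the bundle; ``load_database(write_database(db))`` round-trips
    field-for-field (after normalization)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    items_rows = [
        {
            "item_id": it.item_id,
            "label": it.label,
            "key_question_id": it.key_question_id,
            "kind": it.kind,
            "food_code": it.food_code or "",
            "member_labels": "|".join(it.member_labels),
            "representative_label": it.representative_label or "",
            "nova_group": it.nova_group if it.nova_group is not None else "",
            "nova_subgroup": it.nova_subgroup or "",
        }
        for it in db.items.values()
    ]
    pd.DataFrame(items_rows).to_csv(root / "items.csv", index=False)

    recipe_rows = [
        {"item_id": r.item_id, "food_code": ing.food_code,
         "mass_fraction": repr(ing.mass_fraction), "source": r.source}
        for r in db.recipes.values()
        for ing in r.ingredients
    ]
    pd.DataFrame(recipe_rows,
                 columns=["item_id", "food_code", "mass_fraction", "source"]
                 ).to_csv(root / "recipes.csv", index=False)

    comp_rows = [
        {"food_code": c.food_code, "energy_kcal_per_100g": repr(c.energy_kcal_per_100g),
         "protein_g": repr(c.protein_g), "carb_g": repr(c.carb_g),
         "fat_g": repr(c.fat_g), "nova_group": c.nova_group,
         "nova_subgroup": c.nova_subgroup}
        for c in db.composition.values()
    ]
    pd.DataFrame(comp_rows).to_csv(root / "composition.csv", index=False)

    portion_rows = [
        {"portion_id": p.portion_id, "label": p.label, "grams": repr(p.grams)}
        for p in db.portions.values()
    ]
    pd.DataFrame(portion_rows,
                 columns=["portion_id", "label", "grams"]
                 ).to_csv(root / "portions.csv", index=False)

    with open(root / "questions.json", "w", encoding="utf-8") as fh:
        json.dump(db.graph.to_payload(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = {"schema_version": db.schema_version}
    if db.expected_counts:
        manifest["expected_counts"] = db.expected_counts
    with open(root / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
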