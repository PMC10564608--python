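"""Turn completed recall sessions into long-format consumption records.

Processing pipeline per reported food::

    portion conversion -> imputation of missing refiner fields ->
    recipe disaggregation (preparations) -> composition + Nova attachment

Missing type/source/preparation answers are imputed by *fractional
allocation*: the reported amount is distributed among all options of the
skipped question following a population answer distribution (e.g. a 100 g
honey-bread report with unknown origin becomes 20.4 g homemade + 28.0 g
bakery + 51.6 g branded-packed under shares 0.204/0.280/0.516).  Mass is
conserved exactly through both imputation and disaggregation.

The final per-participant summary is the relative energy contribution of
the four Nova groups (% of total energy intake).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .database import FoodDatabase
from .errors import ContractError, ImputationError, IntegrityError, ProcessingError
from .questions import IMPUTE_FIELDS, QuestionNode, RecallSession, REFINER_QTYPES

NOVA_GROUPS = (1, 2, 3, 4)


@dataclass(frozen=True)
class PopulationDistribution:
    """Answer shares observed in a reference population for one imputable
    field of one food (shares are fractions over the option ids and must
    sum to 1)."""

    item_id: str
    field: str  # type | source | preparation
    shares: tuple[tuple[str, float], ...]  # (option_id, fraction), ordered

    def __post_init__(self):
        if self.field not in IMPUTE_FIELDS:
            raise ContractError(f"unknown imputable field {self.field!r}")
        total = sum(s for _, s in self.shares)
        if any(s < 0 for _, s in self.shares):
            raise ContractError("population shares must be non-negative")
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ContractError(f"population shares sum to {total}, not 1")


class DistributionTable:
    """Lookup of population distributions keyed by (item/subject id, field)."""

    def __init__(self, distributions: Iterable[PopulationDistribution] = ()):
        self._table: dict[tuple[str, str], PopulationDistribution] = {}
        for dist in distributions:
            self._table[(dist.item_id, dist.field)] = dist

    def get(self, item_id: str, field_name: str) -> Optional[PopulationDistribution]:
        return self._table.get((item_id, field_name))

    def __len__(self):
        return len(self._table)

    @classmethod
    def from_csv(cls, path) -> "DistributionTable":
        df = pd.read_csv(path, dtype={"item_id": str, "field": str, "option_id": str})
        dists = []
        for (item_id, field_name), group in df.groupby(["item_id", "field"], sort=False):
            dists.append(PopulationDistribution(
                item_id=str(item_id), field=str(field_name),
                shares=tuple((str(r.option_id), float(r.share))
                             for r in group.itertuples(index=False))))
        return cls(dists)

    def to_csv(self, path) -> None:
        rows = [
            {"item_id": d.item_id, "field": d.field, "option_id": oid, "share": share}
            for d in self._table.values()
            for oid, share in d.shares
        ]
        pd.DataFrame(rows, columns=["item_id", "field", "option_id", "share"]
                     ).to_csv(path, index=False)


@dataclass(frozen=True)
class ConsumedRecord:
    """One long-format output row: a consumed food or recipe ingredient with
    its mass, energy and Nova assignment."""

    participant_id: str
    source_item_id: str
    resolved_code: str
    grams: float
    energy_kcal: float
    nova_group: int
    nova_subgroup: str = ""
    imputed: bool = False


@dataclass
class NovaShareVector:
    """Relative energy contribution (% of total energy) of the four Nova
    groups for one participant.  ``defined`` is False for zero-energy
    recalls (shares are then None)."""

    participant_id: str
    total_energy_kcal: float
    share_pct: Optional[dict[int, float]]
    defined: bool = True


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def impute_missing(
    item_id: str,
    field_name: str,
    grams: float,
    dist: PopulationDistribution,
) -> list[tuple[str, float]]:
    """Distribute a reported amount over the options of a skipped field.

    Grams are allocated proportionally to the population shares; the final
    option takes the remainder so the output masses sum to the input mass
    exactly (to the last bit).
    """
    if grams <= 0:
        raise ContractError("imputation requires a positive amount")
    if (dist.item_id, dist.field) != (item_id, field_name):
        raise ContractError(
            f"distribution is for {(dist.item_id, dist.field)}, "
            f"not {(item_id, field_name)}")
    out: list[tuple[str, float]] = []
    for option_id, share in dist.shares[:-1]:
        out.append((option_id, grams * share))
    last_option, _ = dist.shares[-1]
    out.append((last_option, grams - math.fsum(g for _, g in out)))
    return out


def disaggregate(item_id: str, grams: float, db: FoodDatabase) -> list[tuple[str, float]]:
    """Replace a culinary preparation by its recipe ingredients.

    Ingredient mass = dish mass x recipe mass fraction; the last ingredient
    takes the remainder so total mass is conserved exactly.
    """
    item = db.items.get(item_id)
    if item is None:
        raise IntegrityError(f"unknown item {item_id!r}")
    if item.kind != "preparation":
        raise ContractError(f"item {item_id!r} is {item.kind}, not a preparation")
    recipe = db.recipes.get(item_id)
    if recipe is None:
        raise IntegrityError(f"preparation {item_id!r} has no recipe")
    out: list[tuple[str, float]] = []
    allocated = 0.0
    for ing in recipe.ingredients[:-1]:
        g = grams * ing.mass_fraction
        out.append((ing.food_code, g))
        allocated += g
    out.append((recipe.ingredients[-1].food_code, grams - allocated))
    return out


def _records_for_item(
    db: FoodDatabase,
    participant_id: str,
    source_item_id: str,
    item_id: str,
    grams: float,
    imputed: bool,
) -> list[ConsumedRecord]:
    item = db.items[item_id]
    if item.kind == "preparation":
        records = []
        for code, g in disaggregate(item_id, grams, db):
            entry = db.composition[code]
            records.append(ConsumedRecord(
                participant_id=participant_id,
                source_item_id=source_item_id,
                resolved_code=code,
                grams=g,
                energy_kcal=g * entry.energy_kcal_per_100g / 100.0,
                nova_group=entry.nova_group,
                nova_subgroup=entry.nova_subgroup,
                imputed=imputed,
            ))
        return records
    entry = db.composition[item.food_code]
    return [ConsumedRecord(
        participant_id=participant_id,
        source_item_id=source_item_id,
        resolved_code=item.food_code,
        grams=grams,
        energy_kcal=grams * entry.energy_kcal_per_100g / 100.0,
        nova_group=item.nova_group if item.nova_group is not None else entry.nova_group,
        nova_subgroup=item.nova_subgroup or entry.nova_subgroup,
        imputed=imputed,
    )]


# ---------------------------------------------------------------------------
# session processing
# ---------------------------------------------------------------------------


def _refiners_for(db: FoodDatabase, node: QuestionNode, option_id: str) -> list[QuestionNode]:
    """Preparation/detail children of ``node`` triggered by ``option_id``."""
    out = []
    for child in db.graph.children[node.question_id]:
        if child.qtype not in REFINER_QTYPES:
            continue
        if child.trigger.option_ids is None or option_id in child.trigger.option_ids:
            out.append(child)
    return out


def process_session(
    session: RecallSession,
    db: FoodDatabase,
    dists: Optional[DistributionTable] = None,
    *,
    fallback: str = "error",
) -> list[ConsumedRecord]:
    """Resolve a completed session into consumption records.

    ``fallback`` controls what happens when a refiner was skipped but no
    population distribution exists: ``"error"`` (default) raises
    :class:`ImputationError`; ``"uniform"`` splits equally across the
    refiner's options.  Supplement answers are retained on the session but
    contribute no records (they carry no energy).
    """
    if session.status != "complete":
        raise ContractError("process_session requires a finalized session")
    if fallback not in ("error", "uniform"):
        raise ContractError(f"unknown imputation fallback {fallback!r}")
    dists = dists or DistributionTable()
    records: list[ConsumedRecord] = []

    for node in db.graph.ordered():
        if node.qtype not in ("type_amount", "added_item"):
            continue
        answer = session.answers.get(node.question_id)
        if answer is None or answer.skipped:
            continue
        for option in node.options:
            if option.option_id not in answer.option_ids:
                continue
            units = answer.amounts.get(option.option_id, 1.0)
            if units <= 0:
                continue
            unit_grams = db.option_grams(option)
            if option.item_id is None and not _refiners_for(db, node, option.option_id):
                # presentation-only option (e.g. "nothing added")
                continue
            if unit_grams is None:
                raise ProcessingError(
                    f"question {node.question_id!r} option {option.option_id!r} "
                    "has no portion; amount cannot be resolved")
            grams = units * unit_grams
            records.extend(_resolve_report(
                db, session, dists, fallback, node, option, grams))
    return records


def _resolve_report(db, session, dists, fallback, node, option, grams):
    """Resolve one (option, grams) report, walking its refiner if any."""
    participant = session.participant_id
    refiners = [r for r in _refiners_for(db, node, option.option_id)
                if any(o.item_id for o in r.options) or r.impute_field]
    refiner = refiners[0] if refiners else None

    if refiner is None:
        return _records_for_item(db, participant, option.item_id, option.item_id,
                                 grams, imputed=False)

    answer = session.answers.get(refiner.question_id)
    if answer is not None and not answer.skipped and answer.option_ids:
        selected = answer.option_ids[0]
        target = next((o for o in refiner.options if o.option_id == selected), None)
        item_id = (target.item_id if target and target.item_id else option.item_id)
        if item_id is None:
            raise ProcessingError(
                f"refiner {refiner.question_id!r} option {selected!r} resolves "
                "to no item")
        return _records_for_item(db, participant, item_id, item_id, grams,
                                 imputed=False)

    # refiner missing -> fractional allocation over its options
    subject = refiner.subject or option.item_id
    dist = dists.get(subject, refiner.impute_field) if subject and refiner.impute_field else None
    if dist is None:
        if fallback == "error":
            raise ImputationError(
                f"no population distribution for ({subject!r}, "
                f"{refiner.impute_field!r}) and fallback not configured")
        share = 1.0 / len(refiner.options)
        dist = PopulationDistribution(
            item_id=subject or refiner.question_id,
            field=refiner.impute_field or "type",
            shares=tuple((o.option_id, share) for o in refiner.options[:-1])
            + ((refiner.options[-1].option_id,
                1.0 - share * (len(refiner.options) - 1)),))
    records = []
    option_by_id = {o.option_id: o for o in refiner.options}
    for option_id, g in impute_missing(dist.item_id, dist.field, grams, dist):
        target = option_by_id.get(option_id)
        item_id = (target.item_id if target and target.item_id else option.item_id)
        if item_id is None:
            raise ProcessingError(
                f"refiner {refiner.question_id!r} option {option_id!r} resolves "
                "to no item during imputation")
        records.extend(_records_for_item(db, participant, item_id, item_id, g,
                                         imputed=True))
    return records


def nova_shares(records: Sequence[ConsumedRecord],
                participant_id: Optional[str] = None) -> NovaShareVector:
    """Relative energy contribution of the four Nova groups (% of energy)."""
    participants = {r.participant_id for r in records}
    if participant_id is None:
        if len(participants) > 1:
            raise ContractError(
                f"records span several participants: {sorted(participants)}")
        participant_id = next(iter(participants), "")
    elif participants - {participant_id}:
        raise ContractError("records do not all belong to the stated participant")

    energy = {g: 0.0 for g in NOVA_GROUPS}
    for record in records:
        energy[record.nova_group] += record.energy_kcal
    total = sum(energy.values())
    if total <= 0:
        return NovaShareVector(participant_id, 0.0, None, defined=False)
    shares = {g: 100.0 * e / total for g, e in energy.items()}
    return NovaShareVector(participant_id, total, shares)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def records_to_frame(records: Sequence[ConsumedRecord],
                     recall_date: str = "") -> pd.DataFrame:
    """Long-format output table (one row per consumed food/ingredient)."""
    return pd.DataFrame(
        [{
            "participant_id": r.participant_id,
            "recall_date": recall_date,
            "source_item_id": r.source_item_id,
            "resolved_code": r.resolved_code,
            "grams": r.grams,
            "energy_kcal": r.energy_kcal,
            "nova_group": r.nova_group,
            "nova_subgroup": r.nova_subgroup,
            "imputed": r.imputed,
        } for r in records],
        columns=["participant_id", "recall_date", "source_item_id", "resolved_code",
                 "grams", "energy_kcal", "nova_group", "nova_subgroup", "imputed"])


def shares_to_frame(shares: Iterable[NovaShareVector],
                    tool: str = "novarecall") -> pd.DataFrame:
    """Long paired-shares layout: participant_id, tool, nova_group, share_pct.

    Zero-energy (undefined) participants are excluded with their flag kept
    out of the table; they are reported by the caller.
    """
    rows = []
    for vec in shares:
        if not vec.defined:
            continue
        for g in NOVA_GROUPS:
            rows.append({"participant_id": vec.participant_id, "tool": tool,
                         "nova_group": g, "share_pct": vec.share_pct[g]})
    return pd.DataFrame(rows, columns=["participant_id", "tool", "nova_group",
                                       "share_pct"])


def process_cohort(
    sessions: Sequence[RecallSession],
    db: FoodDatabase,
    dists: Optional[DistributionTable] = None,
    *,
    fallback: str = "error",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Process many sessions; returns (records frame, shares frame, ids of
    zero-energy participants excluded from the shares table)."""
    all_records: list[ConsumedRecord] = []
    vectors: list[NovaShareVector] = []
    excluded: list[str] = []
    for session in sessions:
        records = process_session(session, db, dists, fallback=fallback)
        all_records.extend(records)
        vec = nova_shares(records, session.participant_id)
        if vec.defined:
            vectors.append(vec)
        else:
            excluded.append(session.participant_id)
    return records_to_frame(all_records), shares_to_frame(vectors), excluded
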