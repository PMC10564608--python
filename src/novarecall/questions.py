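"""Branching 24-h recall questionnaire: graph representation and execution.

The recall instrument is a directed acyclic graph of close-ended questions.
Top-level *key* questions ("Did you eat fish yesterday?") are yes/no; a
positive answer triggers *type-and-amount* questions, which may in turn
trigger *added-item* questions (sugar in coffee), *preparation* questions
(raw / grilled / fried) and *detail* questions (homemade vs. purchased).
Around the food questions sit a dietary-restriction question, two
usual-intake questions and a supplement question.

A participant's traversal of the graph is a :class:`RecallSession`.  The
engine is deterministic: identical answer sequences always produce identical
question sequences, and answering a question never retracts a previously
shown, already-answered one.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ContractError, IncompleteSessionError, SchemaError, StateError

QTYPES = (
    "restriction",
    "key",
    "type_amount",
    "added_item",
    "preparation",
    "detail",
    "usual_intake",
    "supplement",
)
#: Question types counted as "food questions" (the concatenated recall body).
FOOD_QTYPES = ("key", "type_amount", "added_item", "preparation", "detail")
#: Question types that may not be skipped by the respondent.
MANDATORY_QTYPES = ("restriction", "key", "usual_intake", "supplement")
#: Question types whose skipped answers are imputable downstream.
REFINER_QTYPES = ("preparation", "detail")

IMPUTE_FIELDS = ("type", "source", "preparation")


@dataclass(frozen=True)
class Option:
    """One selectable answer.

    ``item_id`` binds the option to a food item; ``portion_id`` (resolved
    against the database portion table) or an inline ``grams`` value gives
    the mass of one reported unit.
    """

    option_id: str
    label: str
    item_id: Optional[str] = None
    portion_id: Optional[str] = None
    grams: Optional[float] = None


@dataclass(frozen=True)
class Trigger:
    """Activation condition: the parent question was answered with one of
    ``option_ids`` (``None`` = any selected option)."""

    parent_id: str
    option_ids: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class QuestionNode:
    question_id: str
    qtype: str
    prompt: str
    options: tuple[Option, ...] = ()
    trigger: Optional[Trigger] = None
    warning: Optional[str] = None
    #: for preparation/detail refiners: which imputable field they capture
    impute_field: Optional[str] = None
    #: conceptual food identifier used to look up population distributions
    #: when this refiner is skipped (e.g. "honey_bread")
    subject: Optional[str] = None

    def __post_init__(self):
        if self.qtype not in QTYPES:
            raise SchemaError("questions", self.question_id, f"unknown qtype {self.qtype!r}")
        if self.impute_field is not None and self.impute_field not in IMPUTE_FIELDS:
            raise SchemaError(
                "questions", self.question_id, f"unknown impute_field {self.impute_field!r}"
            )


class QuestionGraph:
    """Validated, ordered question graph.

    Node order is: root questions in manifest order, each immediately
    followed (depth-first) by its follow-ups — exactly the order the
    instrument presents them.
    """

    def __init__(self, nodes: Sequence[QuestionNode]):
        self.nodes: dict[str, QuestionNode] = {}
        for node in nodes:
            if node.question_id in self.nodes:
                raise SchemaError("questions", node.question_id, "duplicate question_id")
            self.nodes[node.question_id] = node
        self.children: dict[str, list[QuestionNode]] = {qid: [] for qid in self.nodes}
        roots: list[QuestionNode] = []
        for node in nodes:
            if node.trigger is None:
                roots.append(node)
            else:
                parent = node.trigger.parent_id
                if parent not in self.nodes:
                    raise SchemaError(
                        "questions", node.question_id, f"trigger parent {parent!r} unknown"
                    )
                self.children[parent].append(node)
        self._roots = roots
        self._ordered = self._order()
        self._validate()

    # -- construction ------------------------------------------------------

    def _order(self) -> list[QuestionNode]:
        ordered: list[QuestionNode] = []
        seen: set[str] = set()

        def visit(node: QuestionNode, stack: tuple[str, ...]):
            if node.question_id in stack:
                raise SchemaError("questions", node.question_id, "cycle in trigger chain")
            if node.question_id in seen:
                raise SchemaError(
                    "questions", node.question_id, "reachable via more than one trigger chain"
                )
            seen.add(node.question_id)
            ordered.append(node)
            for child in self.children[node.question_id]:
                visit(child, stack + (node.question_id,))

        for root in self._roots:
            visit(root, ())
        if len(ordered) != len(self.nodes):
            orphans = sorted(set(self.nodes) - seen)
            raise SchemaError("questions", orphans[0], "unreachable from any root")
        return ordered

    def _validate(self):
        for node in self.nodes.values():
            if node.qtype == "key":
                ids = {o.option_id for o in node.options}
                if ids != {"yes", "no"}:
                    raise SchemaError(
                        "questions", node.question_id, "key question must offer exactly yes/no"
                    )
            if node.trigger is not None and node.trigger.option_ids is not None:
                parent = self.nodes[node.trigger.parent_id]
                known = {o.option_id for o in parent.options}
                for oid in node.trigger.option_ids:
                    if oid not in known:
                        raise SchemaError(
                            "questions",
                            node.question_id,
                            f"trigger option {oid!r} not offered by parent",
                        )

    # -- queries -----------------------------------------------------------

    def ordered(self) -> list[QuestionNode]:
        return list(self._ordered)

    def roots(self) -> list[QuestionNode]:
        return list(self._roots)

    def __getitem__(self, question_id: str) -> QuestionNode:
        return self.nodes[question_id]

    def __contains__(self, question_id: str) -> bool:
        return question_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def key_question_of(self, node: QuestionNode) -> Optional[QuestionNode]:
        """The key question owning ``node`` (itself, if it is one)."""
        current = node
        while current is not None:
            if current.qtype == "key":
                return current
            if current.trigger is None:
                return None
            current = self.nodes[current.trigger.parent_id]
        return None

    # -- (de)serialization -------------------------------------------------

    def to_payload(self) -> dict:
        def node_payload(n: QuestionNode) -> dict:
            d = {
                "question_id": n.question_id,
                "qtype": n.qtype,
                "prompt": n.prompt,
                "options": [
                    {k: v for k, v in asdict(o).items() if v is not None} for o in n.options
                ],
            }
            if n.trigger is not None:
                d["trigger"] = {
                    "parent_id": n.trigger.parent_id,
                    "option_ids": list(n.trigger.option_ids)
                    if n.trigger.option_ids is not None
                    else None,
                }
            for attr in ("warning", "impute_field", "subject"):
                if getattr(n, attr) is not None:
                    d[attr] = getattr(n, attr)
            return d

        return {"nodes": [node_payload(n) for n in self._ordered]}

    @classmethod
    def from_payload(cls, payload: Mapping) -> "QuestionGraph":
        nodes = []
        for raw in payload["nodes"]:
            trigger = None
            if raw.get("trigger") is not None:
                oids = raw["trigger"].get("option_ids")
                trigger = Trigger(
                    raw["trigger"]["parent_id"],
                    tuple(oids) if oids is not None else None,
                )
            options = tuple(
                Option(
                    option_id=o["option_id"],
                    label=o.get("label", o["option_id"]),
                    item_id=o.get("item_id"),
                    portion_id=o.get("portion_id"),
                    grams=o.get("grams"),
                )
                for o in raw.get("options", [])
            )
            nodes.append(
                QuestionNode(
                    question_id=raw["question_id"],
                    qtype=raw["qtype"],
                    prompt=raw.get("prompt", ""),
                    options=options,
                    trigger=trigger,
                    warning=raw.get("warning"),
                    impute_field=raw.get("impute_field"),
                    subject=raw.get("subject"),
                )
            )
        return cls(nodes)


@dataclass
class Answer:
    """One recorded answer: selected options, per-option amounts in units of
    the option's portion, or an explicit skip."""

    option_ids: tuple[str, ...] = ()
    amounts: dict[str, float] = field(default_factory=dict)
    skipped: bool = False


@dataclass
class RecallSession:
    participant_id: str
    recall_date: str = ""
    answers: dict[str, Answer] = field(default_factory=dict)
    status: str = "in_progress"

    # -- convenience flags (populated at finalization) ---------------------
    usual_intake_flags: dict[str, str] = field(default_factory=dict)
    supplement_flag: Optional[str] = None
    restriction_flags: tuple[str, ...] = ()

    def to_payload(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "recall_date": self.recall_date,
            "status": self.status,
            "answers": [
                {
                    "question_id": qid,
                    "option_ids": list(a.option_ids),
                    "amounts": a.amounts,
                    "skipped": a.skipped,
                }
                for qid, a in self.answers.items()
            ],
            "usual_intake_flags": self.usual_intake_flags,
            "supplement_flag": self.supplement_flag,
            "restriction_flags": list(self.restriction_flags),
        }

    @classmethod
    def from_payload(cls, payload: Mapping) -> "RecallSession":
        session = cls(
            participant_id=payload["participant_id"],
            recall_date=payload.get("recall_date", ""),
            status=payload.get("status", "in_progress"),
        )
        for raw in payload.get("answers", []):
            session.answers[raw["question_id"]] = Answer(
                option_ids=tuple(raw.get("option_ids", ())),
                amounts={k: float(v) for k, v in raw.get("amounts", {}).items()},
                skipped=bool(raw.get("skipped", False)),
            )
        session.usual_intake_flags = dict(payload.get("usual_intake_flags", {}))
        session.supplement_flag = payload.get("supplement_flag")
        session.restriction_flags = tuple(payload.get("restriction_flags", ()))
        return session


def load_sessions(path) -> list[RecallSession]:
    """Read sessions from a JSON file (a list of session payloads)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return [RecallSession.from_payload(p) for p in data]


def save_sessions(sessions: Iterable[RecallSession], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([s.to_payload() for s in sessions], fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# engine operations
# ---------------------------------------------------------------------------


def is_triggered(graph: QuestionGraph, session: RecallSession, node: QuestionNode) -> bool:
    """True iff the node's activation condition is satisfied by the session's
    recorded answers (root nodes are always triggered)."""
    if node.trigger is None:
        return True
    parent_answer = session.answers.get(node.trigger.parent_id)
    if parent_answer is None or parent_answer.skipped:
        return False
    selected = set(parent_answer.option_ids)
    if node.trigger.option_ids is None:
        parent = graph[node.trigger.parent_id]
        if parent.qtype == "key":
            return "yes" in selected
        return bool(selected)
    return bool(selected & set(node.trigger.option_ids))


def next_questions(graph: QuestionGraph, session: RecallSession) -> list[QuestionNode]:
    """All triggered, not-yet-answered questions, in presentation order.

    An empty return means the session may be finalized.  Also verifies the
    session invariant that no answer exists for an untriggered node.
    """
    if session.status != "in_progress":
        raise ContractError("next_questions requires an in-progress session")
    pending = []
    for node in graph.ordered():
        triggered = is_triggered(graph, session, node)
        if node.question_id in session.answers:
            if not triggered:
                raise StateError(
                    f"answer recorded for untriggered question {node.question_id!r}"
                )
            continue
        if triggered:
            pending.append(node)
    return pending


def record_answer(
    graph: QuestionGraph,
    session: RecallSession,
    question_id: str,
    option_ids: Sequence[str] = (),
    amounts: Optional[Mapping[str, float]] = None,
    skipped: bool = False,
) -> None:
    """Record (or revise) an answer.

    Revising an earlier answer invalidates any downstream answers whose
    triggers are no longer satisfied, so the session invariant holds at all
    times.
    """
    if session.status != "in_progress":
        raise ContractError("cannot answer questions in a finalized session")
    if question_id not in graph:
        raise StateError(f"unknown question {question_id!r}")
    node = graph[question_id]
    if not is_triggered(graph, session, node):
        raise StateError(f"question {question_id!r} is not triggered by prior answers")
    if skipped:
        if node.qtype in MANDATORY_QTYPES:
            raise StateError(f"{node.qtype} question {question_id!r} may not be skipped")
        session.answers[question_id] = Answer(skipped=True)
    else:
        known = {o.option_id for o in node.options}
        for oid in option_ids:
            if oid not in known:
                raise StateError(f"question {question_id!r} has no option {oid!r}")
        session.answers[question_id] = Answer(
            option_ids=tuple(option_ids),
            amounts={k: float(v) for k, v in (amounts or {}).items()},
        )
    _invalidate_untriggered(graph, session)


def _invalidate_untriggered(graph: QuestionGraph, session: RecallSession) -> None:
    # one ordered pass suffices: triggers only reference earlier nodes
    for node in graph.ordered():
        if node.question_id in session.answers and not is_triggered(graph, session, node):
            del session.answers[node.question_id]


def count_questions(graph: QuestionGraph) -> dict[str, int]:
    """Per-type question counts plus the food-question total
    (key + type_amount + added_item + preparation + detail)."""
    counts = Counter(node.qtype for node in graph.ordered())
    report = {qtype: counts.get(qtype, 0) for qtype in QTYPES}
    report["total_food"] = sum(report[q] for q in FOOD_QTYPES)
    report["total"] = len(graph)
    return report


def finalize_session(graph: QuestionGraph, session: RecallSession) -> RecallSession:
    """Close the session.

    Every triggered question must be answered or explicitly skipped
    (restriction, key, usual-intake and supplement questions cannot be
    skipped).  Skipped refiner questions remain recorded as missing for
    downstream imputation.
    """
    pending = next_questions(graph, session)
    if pending:
        raise IncompleteSessionError([n.question_id for n in pending])
    session.status = "complete"
    for node in graph.ordered():
        answer = session.answers.get(node.question_id)
        if answer is None or answer.skipped:
            continue
        if node.qtype == "usual_intake":
            session.usual_intake_flags[node.question_id] = (
                answer.option_ids[0] if answer.option_ids else ""
            )
        elif node.qtype == "supplement":
            session.supplement_flag = answer.option_ids[0] if answer.option_ids else None
        elif node.qtype == "restriction":
            session.restriction_flags = answer.option_ids
    return session
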