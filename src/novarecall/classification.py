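"""Multi-reviewer consensus workflow for Nova assignments.

Food items and recipe ingredients are classified into the four Nova groups
by several researchers working independently; items on which every reviewer
agrees (on both group and subgroup by default) receive that assignment,
while any pairwise disagreement shortlists the item for an expert panel,
whose decision is final.  The audit trail of reviewer assignments and panel
decisions is retained on each item's adjudication state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ContractError

NOVA_GROUPS = (1, 2, 3, 4)


@dataclass(frozen=True)
class ReviewerAssignment:
    reviewer_id: str
    item_or_code: str
    nova_group: int
    nova_subgroup: str = ""
    stage: str = "assign"  # audit label, e.g. assign / review

    def __post_init__(self):
        if self.nova_group not in NOVA_GROUPS:
            raise ContractError(f"nova_group must be in {NOVA_GROUPS}")


@dataclass(frozen=True)
class AdjudicationState:
    item_or_code: str
    assignments: tuple[ReviewerAssignment, ...]
    status: str  # consensus | shortlisted | panel_resolved
    final: Optional[tuple[int, str]] = None
    audit: tuple[str, ...] = field(default_factory=tuple)


def adjudicate(
    assignments: Sequence[ReviewerAssignment],
    *,
    require_subgroup: bool = True,
) -> AdjudicationState:
    """Resolve one item's reviewer assignments.

    Unanimity across all reviewers (group and, unless ``require_subgroup``
    is False, subgroup) yields ``consensus`` with the final label set; any
    pairwise disagreement yields ``shortlisted`` with the final unset.
    The result does not depend on reviewer order.
    """
    if len(assignments) < 2:
        raise ContractError("adjudication needs at least 2 reviewer assignments")
    items = {a.item_or_code for a in assignments}
    if len(items) > 1:
        raise ContractError(f"assignments mix items: {sorted(items)}")
    if require_subgroup:
        labels = {(a.nova_group, a.nova_subgroup) for a in assignments}
    else:
        labels = {(a.nova_group, None) for a in assignments}
    ordered = tuple(sorted(assignments, key=lambda a: (a.stage, a.reviewer_id)))
    audit = tuple(
        f"{a.stage}:{a.reviewer_id} -> group {a.nova_group} ({a.nova_subgroup})"
        for a in ordered)
    if len(labels) == 1:
        group, subgroup = next(iter(labels))
        if subgroup is None:  # group-only mode: keep the (agreed) first subgroup
            subgroup = ordered[0].nova_subgroup
        return AdjudicationState(
            item_or_code=next(iter(items)),
            assignments=ordered,
            status="consensus",
            final=(group, subgroup),
            audit=audit + ("consensus among all reviewers",))
    return AdjudicationState(
        item_or_code=next(iter(items)),
        assignments=ordered,
        status="shortlisted",
        final=None,
        audit=audit + ("pairwise disagreement: shortlisted for expert panel",))


def resolve_panel(
    state: AdjudicationState,
    panel_decision: tuple[int, str],
    panel_id: str = "expert_panel",
) -> AdjudicationState:
    """Apply the expert panel's decision to a shortlisted item."""
    if state.status != "shortlisted":
        raise ContractError(
            f"panel resolution applies to shortlisted items, not {state.status!r}")
    group, subgroup = panel_decision
    if group not in NOVA_GROUPS:
        raise ContractError(f"panel decision group must be in {NOVA_GROUPS}")
    return replace(
        state,
        status="panel_resolved",
        final=(int(group), str(subgroup)),
        audit=state.audit + (f"{panel_id} -> group {group} ({subgroup})",))


def adjudicate_table(
    assignments: Iterable[ReviewerAssignment],
    *,
    require_subgroup: bool = True,
) -> dict[str, AdjudicationState]:
    """Batch adjudication keyed by item; every item ends with a state."""
    by_item: dict[str, list[ReviewerAssignment]] = {}
    for a in assignments:
        by_item.setdefault(a.item_or_code, []).append(a)
    return {
        item: adjudicate(rows, require_subgroup=require_subgroup)
        for item, rows in by_item.items()
    }


def assignments_from_csv(path) -> list[ReviewerAssignment]:
    """Read reviewer assignments (reviewer_id, item, group, subgroup[, stage])."""
    df = pd.read_csv(path, dtype=str)
    return [
        ReviewerAssignment(
            reviewer_id=str(r.reviewer_id),
            item_or_code=str(r.item),
            nova_group=int(r.group),
            nova_subgroup=str(getattr(r, "subgroup", "") or ""),
            stage=str(getattr(r, "stage", "assign") or "assign"),
        )
        for r in df.itertuples(index=False)
    ]


def adjudication_report(states: dict[str, AdjudicationState]) -> pd.DataFrame:
    """Tabular adjudication report (status and final labels per item)."""
    rows = []
    for item, state in states.items():
        rows.append({
            "item": item,
            "status": state.status,
            "final_group": state.final[0] if state.final else "",
            "final_subgroup": state.final[1] if state.final else "",
            "n_reviewers": len(state.assignments),
        })
    return pd.DataFrame(rows, columns=["item", "status", "final_group",
                                       "final_subgroup", "n_reviewers"])
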