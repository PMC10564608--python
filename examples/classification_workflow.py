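"""The three-stage Nova classification workflow on a toy item set.

Four reviewers classify three foods; unanimous items reach consensus,
any pairwise disagreement shortlists the item for the expert panel.
"""

from novarecall import ReviewerAssignment, adjudicate_table, resolve_panel

assignments = [
    # everyone agrees: plain yogurt is minimally processed
    *[ReviewerAssignment(r, "plain_yogurt", 1, "dairy") for r in
      ("r1", "r2", "r3", "r4")],
    # group agreement but subgroup split: shortlisted
    ReviewerAssignment("r1", "coconut_milk", 1, "fruits"),
    ReviewerAssignment("r2", "coconut_milk", 1, "fruits"),
    ReviewerAssignment("r3", "coconut_milk", 1, "plant_beverages"),
    ReviewerAssignment("r4", "coconut_milk", 1, "fruits"),
    # group split between processed and ultra-processed: shortlisted
    ReviewerAssignment("r1", "flavored_cracker", 3, "breads"),
    ReviewerAssignment("r2", "flavored_cracker", 4, "packaged_snacks"),
]

states = adjudicate_table(assignments)
for item, state in states.items():
    print(f"{item:<18} {state.status:<12} final={state.final}")

print("\nafter the expert panel:")
for item, state in states.items():
    if state.status == "shortlisted":
        panel = {"coconut_milk": (1, "plant_beverages"),
                 "flavored_cracker": (4, "packaged_snacks")}[item]
        state = resolve_panel(state, panel)
    print(f"{item:<18} {state.status:<14} final={state.final}")
    # every item ends with exactly one final (group, subgroup)
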