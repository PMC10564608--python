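"""Question-engine behaviour: branching, determinism, finalization."""

import pytest

from novarecall import (
    IncompleteSessionError,
    RecallSession,
    StateError,
    count_questions,
    finalize_session,
    next_questions,
    record_answer,
)
from tests.conftest import all_no_session, answer_defaults


def pending_ids(db, session):
    return [n.question_id for n in next_questions(db.graph, session)]


def test_yes_on_key_question_reveals_type_amount(mini_db):
    session = RecallSession("p1")
    record_answer(mini_db.graph, session, "kq_fish", ("yes",))
    assert "ta_fish" in pending_ids(mini_db, session)


def test_no_on_key_question_hides_followups(mini_db):
    session = RecallSession("p1")
    record_answer(mini_db.graph, session, "kq_fish", ("no",))
    ids = pending_ids(mini_db, session)
    assert "ta_fish" not in ids and "pr_fish" not in ids


def test_fresh_fish_selection_triggers_preparation_question(mini_db):
    session = RecallSession("p1")
    record_answer(mini_db.graph, session, "kq_fish", ("yes",))
    record_answer(mini_db.graph, session, "ta_fish", ("fresh_fish",),
                  {"fresh_fish": 1.0})
    assert "pr_fish" in pending_ids(mini_db, session)
    # canned fish alone would not trigger it
    session2 = RecallSession("p2")
    record_answer(mini_db.graph, session2, "kq_fish", ("yes",))
    record_answer(mini_db.graph, session2, "ta_fish", ("canned_fish",),
                  {"canned_fish": 1.0})
    assert "pr_fish" not in pending_ids(mini_db, session2)


def test_answer_for_untriggered_question_rejected(mini_db):
    session = RecallSession("p1")
    with pytest.raises(StateError):
        record_answer(mini_db.graph, session, "ta_fish", ("canned_fish",))


def test_revision_invalidates_downstream_answers(mini_db):
    session = RecallSession("p1")
    record_answer(mini_db.graph, session, "kq_fish", ("yes",))
    record_answer(mini_db.graph, session, "ta_fish", ("fresh_fish",),
                  {"fresh_fish": 1.0})
    record_answer(mini_db.graph, session, "pr_fish", ("grilled",))
    record_answer(mini_db.graph, session, "kq_fish", ("no",))
    assert "ta_fish" not in session.answers
    assert "pr_fish" not in session.answers


def test_monotone_disclosure(mini_db):
    """Answering one question never removes another already-answered,
    still-triggered question from the record."""
    session = RecallSession("p1")
    record_answer(mini_db.graph, session, "kq_fish", ("yes",))
    record_answer(mini_db.graph, session, "kq_milk", ("yes",))
    before = set(session.answers)
    record_answer(mini_db.graph, session, "ta_milk", ("whole_milk",),
                  {"whole_milk": 1.0})
    assert before <= set(session.answers)


def test_identical_answer_sequences_yield_identical_question_sequences(mini_db):
    answers = [("kq_rice", ("yes",)), ("ta_rice", ("cooked_rice",)),
               ("kq_fish", ("yes",)), ("ta_fish", ("fresh_fish",))]
    trails = []
    for _ in range(2):
        session = RecallSession("p1")
        trail = [tuple(pending_ids(mini_db, session))]
        for qid, opts in answers:
            record_answer(mini_db.graph, session, qid, opts)
            trail.append(tuple(pending_ids(mini_db, session)))
        trails.append(trail)
    assert trails[0] == trails[1]


def test_warning_text_exposed_on_node(mini_db):
    node = mini_db.graph["kq_milk"]
    assert node.warning and "DO NOT include milk" in node.warning


def test_count_questions_mini(mini_db):
    counts = count_questions(mini_db.graph)
    assert counts["key"] == 13
    assert counts["total_food"] == 31
    assert counts["usual_intake"] == 2 and counts["supplement"] == 1


def test_count_questions_single_key_graph():
    from novarecall import Option, QuestionGraph, QuestionNode

    graph = QuestionGraph([QuestionNode(
        "kq", "key", "?", options=(Option("yes", "y"), Option("no", "n")))])
    counts = count_questions(graph)
    assert counts["key"] == 1 and counts["total_food"] == 1


def test_finalize_requires_mandatory_answers(mini_db):
    session = all_no_session(mini_db)
    del session.answers["sq_supplement"]
    with pytest.raises(IncompleteSessionError, match="sq_supplement"):
        finalize_session(mini_db.graph, session)


def test_finalize_with_skipped_refiner_records_missing(mini_db):
    session = all_no_session(mini_db, except_keys={"kq_eggs"})
    record_answer(mini_db.graph, session, "ta_eggs", ("egg",), {"egg": 2.0})
    record_answer(mini_db.graph, session, "pr_eggs", skipped=True)
    finalize_session(mini_db.graph, session)
    assert session.status == "complete"
    assert session.answers["pr_eggs"].skipped


def test_key_question_may_not_be_skipped(mini_db):
    session = RecallSession("p1")
    with pytest.raises(StateError):
        record_answer(mini_db.graph, session, "kq_fish", skipped=True)


def test_fully_answered_session_finalizes_and_sets_flags(mini_db):
    session = all_no_session(mini_db)
    finalize_session(mini_db.graph, session)
    assert session.status == "complete"
    assert session.supplement_flag == "no"
    assert session.usual_intake_flags == {"uq_amount": "usual",
                                          "uq_typical": "typical"}
    assert session.restriction_flags == ("none",)


def test_session_json_round_trip(mini_db, tmp_path):
    from novarecall import load_sessions, save_sessions

    session = all_no_session(mini_db, except_keys={"kq_fruit"})
    record_answer(mini_db.graph, session, "ta_fruit", ("apple",), {"apple": 1.0})
    finalize_session(mini_db.graph, session)
    save_sessions([session], tmp_path / "s.json")
    (loaded,) = load_sessions(tmp_path / "s.json")
    assert loaded.to_payload() == session.to_payload()


def test_answer_defaults_helper_covers_framing_questions(mini_db):
    session = RecallSession("p1")
    answer_defaults(mini_db.graph, session)
    assert {"rq_restriction", "uq_amount", "uq_typical", "sq_supplement"} <= set(
        session.answers)
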