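import pytest

from novarecall import (
    RecallSession,
    finalize_session,
    generate_fixture,
    record_answer,
)


@pytest.fixture(scope="session")
def mini_db():
    return generate_fixture("mini")


@pytest.fixture(scope="session")
def paper_db():
    return generate_fixture("paper-shape", seed=1)


def answer_defaults(graph, session):
    """Fill restriction / usual-intake / supplement answers."""
    record_answer(graph, session, "rq_restriction", ("none",))
    record_answer(graph, session, "uq_amount", ("usual",))
    record_answer(graph, session, "uq_typical", ("typical",))
    record_answer(graph, session, "sq_supplement", ("no",))


def all_no_session(db, participant_id="p1", except_keys=()):
    """A session answering 'no' to every key question except those listed
    (which get 'yes'); framing questions answered with defaults."""
    session = RecallSession(participant_id, "2020-10-01")
    graph = db.graph
    answer_defaults(graph, session)
    for node in graph.ordered():
        if node.qtype == "key":
            record_answer(graph, session, node.question_id,
                          ("yes",) if node.question_id in except_keys else ("no",))
    return session


@pytest.fixture
def honey_bread_session(mini_db):
    """100 g of honey bread reported with the origin question skipped."""
    session = all_no_session(mini_db, except_keys={"kq_honey_bread"})
    record_answer(mini_db.graph, session, "ta_honey_bread",
                  ("honey_bread",), {"honey_bread": 2.0})  # 2 x 50 g slices
    record_answer(mini_db.graph, session, "dt_honey_bread_source", skipped=True)
    return finalize_session(mini_db.graph, session)
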