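"""Recall processing: imputation, disaggregation, Nova shares."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from novarecall import (
    ConsumedRecord,
    ContractError,
    DistributionTable,
    ImputationError,
    PopulationDistribution,
    disaggregate,
    finalize_session,
    impute_missing,
    nova_shares,
    process_session,
    record_answer,
)
from tests.conftest import all_no_session

HONEY_BREAD_DIST = PopulationDistribution(
    "honey_bread", "source",
    (("homemade", 0.204), ("bakery", 0.280), ("packed", 0.516)))


class TestImputeMissing:
    def test_worked_example_100g_honey_bread(self):
        out = dict(impute_missing("honey_bread", "source", 100.0, HONEY_BREAD_DIST))
        assert out["homemade"] == pytest.approx(20.4)
        assert out["bakery"] == pytest.approx(28.0)
        assert out["packed"] == pytest.approx(51.6)
        assert math.fsum(out.values()) == 100.0  # conserved exactly

    def test_single_option_distribution(self):
        dist = PopulationDistribution("x", "type", (("a", 1.0),))
        assert impute_missing("x", "type", 50.0, dist) == [("a", 50.0)]

    @given(grams=st.floats(0.01, 5000),
           raw=st.lists(st.floats(0.01, 10), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_mass_conserved_exactly(self, grams, raw):
        total = sum(raw)
        shares = [w / total for w in raw[:-1]]
        shares.append(1.0 - sum(shares))
        dist = PopulationDistribution(
            "x", "type", tuple((f"o{i}", s) for i, s in enumerate(shares)))
        out = impute_missing("x", "type", grams, dist)
        assert math.fsum(g for _, g in out) == pytest.approx(grams, rel=1e-14)

    def test_mismatched_distribution_rejected(self):
        with pytest.raises(ContractError):
            impute_missing("other_item", "source", 10.0, HONEY_BREAD_DIST)


class TestDisaggregate:
    def test_cooked_rice_200g(self, mini_db):
        out = dict(disaggregate("cooked_rice", 200.0, mini_db))
        assert set(out) == {"C_RICE_RAW", "C_OIL", "C_ONION", "C_GARLIC", "C_SALT"}
        assert out["C_RICE_RAW"] == pytest.approx(176.0)
        assert math.fsum(out.values()) == 200.0

    def test_non_preparation_item_rejected(self, mini_db):
        with pytest.raises(ContractError):
            disaggregate("apple", 100.0, mini_db)

    @pytest.mark.parametrize("item_id", ["cooked_rice", "cooked_beans",
                                         "fried_fish", "cake_homemade",
                                         "scrambled_egg"])
    def test_dish_energy_equals_sum_of_ingredient_energies(self, mini_db, item_id):
        """Oracle: recompute the dish energy directly from the composition
        table and the recipe fractions, independent of the record pipeline."""
        grams = 137.5
        recipe = mini_db.recipes[item_id]
        oracle = sum(
            grams * ing.mass_fraction
            * mini_db.composition[ing.food_code].energy_kcal_per_100g / 100.0
            for ing in recipe.ingredients)
        pipeline = sum(
            g * mini_db.composition[code].energy_kcal_per_100g / 100.0
            for code, g in disaggregate(item_id, grams, mini_db))
        assert pipeline == pytest.approx(oracle, abs=1e-9)


class TestProcessSession:
    def test_single_apple(self, mini_db):
        session = all_no_session(mini_db, except_keys={"kq_fruit"})
        record_answer(mini_db.graph, session, "ta_fruit", ("apple",),
                      {"apple": 1.0})
        finalize_session(mini_db.graph, session)
        (record,) = process_session(session, mini_db)
        assert record.resolved_code == "C_APPLE"
        assert record.grams == 130.0  # one unit
        assert record.energy_kcal == pytest.approx(130.0 * 52.0 / 100.0)
        assert record.nova_group == 1 and not record.imputed

    def test_empty_session_yields_no_records(self, mini_db):
        session = all_no_session(mini_db)
        finalize_session(mini_db.graph, session)
        assert process_session(session, mini_db) == []

    def test_missing_source_yields_three_imputed_records(self, mini_db,
                                                         honey_bread_session):
        records = process_session(honey_bread_session, mini_db,
                                  DistributionTable([HONEY_BREAD_DIST]))
        assert len(records) == 3
        assert all(r.imputed for r in records)
        assert math.fsum(r.grams for r in records) == 100.0
        assert {r.nova_group for r in records} == {3, 4}

    def test_missing_distribution_raises_by_default(self, mini_db,
                                                    honey_bread_session):
        with pytest.raises(ImputationError, match="honey_bread"):
            process_session(honey_bread_session, mini_db, DistributionTable())

    def test_uniform_fallback_splits_equally(self, mini_db, honey_bread_session):
        records = process_session(honey_bread_session, mini_db,
                                  DistributionTable(), fallback="uniform")
        grams = sorted(r.grams for r in records)
        assert grams == pytest.approx([100 / 3] * 3)

    def test_answered_refiner_passes_through_unimputed(self, mini_db):
        session = all_no_session(mini_db, except_keys={"kq_honey_bread"})
        record_answer(mini_db.graph, session, "ta_honey_bread",
                      ("honey_bread",), {"honey_bread": 2.0})
        record_answer(mini_db.graph, session, "dt_honey_bread_source", ("bakery",))
        finalize_session(mini_db.graph, session)
        (record,) = process_session(session, mini_db,
                                    DistributionTable([HONEY_BREAD_DIST]))
        assert record.resolved_code == "C_HBREAD_BAKERY"
        assert not record.imputed

    def test_imputation_then_disaggregation_conserves_mass(self, mini_db):
        """Skipped cake origin: 50% homemade (a recipe) + 50% packaged."""
        session = all_no_session(mini_db, except_keys={"kq_cake"})
        record_answer(mini_db.graph, session, "ta_cake", ("cake",), {"cake": 1.0})
        record_answer(mini_db.graph, session, "dt_cake_origin", skipped=True)
        finalize_session(mini_db.graph, session)
        dist = PopulationDistribution("cake", "source",
                                      (("homemade", 0.5), ("purchased", 0.5)))
        records = process_session(session, mini_db, DistributionTable([dist]))
        assert math.fsum(r.grams for r in records) == pytest.approx(80.0, abs=1e-9)
        assert len(records) == 6  # 5 cake ingredients + 1 packaged cake
        assert all(r.imputed for r in records)

    def test_supplement_answer_contributes_no_records(self, mini_db):
        session = all_no_session(mini_db)
        record_answer(mini_db.graph, session, "sq_supplement", ("yes",))
        finalize_session(mini_db.graph, session)
        assert process_session(session, mini_db) == []
        assert session.supplement_flag == "yes"


class TestNovaShares:
    def test_all_group_one(self):
        records = [ConsumedRecord("p", "a", "c", 100, 50.0, 1)]
        vec = nova_shares(records)
        assert vec.share_pct == {1: 100.0, 2: 0.0, 3: 0.0, 4: 0.0}

    def test_hand_arithmetic_75_25(self):
        records = [ConsumedRecord("p", "a", "c1", 100, 300.0, 1),
                   ConsumedRecord("p", "b", "c2", 100, 100.0, 4)]
        vec = nova_shares(records)
        assert vec.share_pct[1] == pytest.approx(75.0)
        assert vec.share_pct[4] == pytest.approx(25.0)
        assert vec.total_energy_kcal == pytest.approx(400.0)

    def test_zero_energy_flagged_undefined(self):
        records = [ConsumedRecord("p", "a", "C_SALT", 10, 0.0, 2)]
        vec = nova_shares(records)
        assert not vec.defined and vec.share_pct is None

    def test_mixed_participants_rejected(self):
        records = [ConsumedRecord("p1", "a", "c", 1, 1.0, 1),
                   ConsumedRecord("p2", "a", "c", 1, 1.0, 1)]
        with pytest.raises(ContractError):
            nova_shares(records)

    @given(energies=st.lists(
        st.tuples(st.sampled_from([1, 2, 3, 4]), st.floats(0.1, 500)),
        min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shares_sum_to_100(self, energies):
        records = [ConsumedRecord("p", "a", "c", 10, e, g)
                   for g, e in energies]
        vec = nova_shares(records)
        assert sum(vec.share_pct.values()) == pytest.approx(100.0, abs=1e-6)
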