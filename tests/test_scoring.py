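"""Point-per-item scoring: level maxima, subdomain totals, oracle equivalence."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import cafescreen as cs
from cafescreen.errors import ResponseReferenceError
from tests.test_session import responses_with_counts


def brute_force_level_score(level_script, responses):
    """Independent per-item scorer: walk every ordered item and credit
    each metric separately, never touching the set arithmetic of the
    implementation under test."""
    imm = dly = rec = tab = cust = both = 0
    for order in level_script.orders:
        for item in order.item_ids:
            if item in responses.immediate_recall:
                imm += 1
            if item in responses.delayed_recall:
                dly += 1
            if item in responses.counter_selection:
                rec += 1
            seat = responses.service.get(item)
            if seat is not None:
                t_ok = seat[0] == order.table_index
                c_ok = seat[1] == order.customer_index
                tab += t_ok
                cust += c_ok
                both += t_ok and c_ok
    return imm, dly, rec, tab, cust, both


class TestLevelScoring:
    def test_level1_fully_correct_totals_10(self, script):
        lv = script.level(1)
        score = cs.score_level(lv, cs.ResponseSet.perfect(lv))
        assert score.total == 10
        assert score.max_total == 10

    def test_level5_fully_correct_totals_80(self, script):
        lv = script.level(5)
        score = cs.score_level(lv, cs.ResponseSet.perfect(lv))
        assert score.total == 80

    def test_level_maxima_ladder(self, script):
        maxima = [
            cs.score_level(lv, cs.ResponseSet.perfect(lv)).max_total
            for lv in script.levels
        ]
        assert maxima == [10, 20, 30, 40, 80]

    def test_one_of_two_items_correct_gives_5(self, script):
        lv = script.level(1)
        rs = responses_with_counts(lv, imm=1, dly=1, rec=1, served_ok=1)
        assert cs.score_level(lv, rs).total == 5

    def test_level_mismatch_rejected(self, script):
        with pytest.raises(ResponseReferenceError):
            cs.score_level(script.level(2), cs.ResponseSet.empty(1))

    def test_duplicate_claims_collapse(self, script):
        lv = script.level(1)
        item = lv.ordered_item_ids[0]
        rs = cs.ResponseSet(level=1, immediate_recall=(item, item, item))
        assert cs.score_level(lv, rs).points.immediate == 1

    def test_wrong_claims_never_go_negative(self, script):
        lv = script.level(1)
        rs = cs.ResponseSet(level=1, immediate_recall=("bogus_a", "bogus_b"))
        score = cs.score_level(lv, rs)
        assert score.points.immediate == 0
        assert score.total == 0


class TestAccuracies:
    def test_perfect_level(self, script):
        lv = script.level(3)
        assert cs.accuracies(cs.score_level(lv, cs.ResponseSet.perfect(lv))) == (1, 1, 1, 1)

    def test_no_attempt_level(self, script):
        lv = script.level(3)
        assert cs.accuracies(cs.score_level(lv, cs.ResponseSet.empty(3))) == (0, 0, 0, 0)

    def test_mixed_level2_ratios(self, script):
        lv = script.level(2)  # 4 items
        rs = responses_with_counts(lv, imm=2, dly=1, rec=3, served_ok=1)
        assert cs.accuracies(cs.score_level(lv, rs)) == (0.5, 0.25, 0.75, 0.25)

    def test_serving_accuracy_requires_table_and_customer(self, script):
        lv = script.level(2)
        items = lv.ordered_item_ids
        # serve all four items to the right table but swap the two seats
        service = {}
        for item in items:
            t, c = lv.seat_of(item)
            service[item] = (t, 3 - c)  # other seat at the same table
        rs = cs.ResponseSet(level=2, counter_selection=items, service=service)
        score = cs.score_level(lv, rs)
        assert score.points.table == 4
        assert score.points.customer == 0
        assert score.accuracy_serving == 0.0


class TestSessionScoring:
    def test_fully_correct_session_scores_180(self, script, perfect_log):
        score = cs.score_session(script, perfect_log)
        assert score.grand_total == 180
        assert score.immediate_total == 36
        assert score.delayed_total == 36
        assert score.recognition_total == 36
        assert score.spatial_combined_total == 72

    def test_all_empty_session_scores_0(self, script):
        log = cs.run_scripted_session(script, [cs.ResponseSet.empty(1)])
        score = cs.score_session(script, log)
        assert score.grand_total == 0
        assert score.levels_played == 1

    def test_total_minutes_from_last_event(self, script, perfect_log):
        score = cs.score_session(script, perfect_log)
        assert score.total_minutes == pytest.approx(perfect_log.events[-1].timestamp / 60)

    def test_additivity(self, script, perfect_log):
        score = cs.score_session(script, perfect_log)
        assert score.grand_total == sum(ls.total for ls in score.per_level)
        assert score.grand_total == (
            score.immediate_total + score.delayed_total + score.recognition_total
            + score.table_total + score.customer_total
        )

    def test_log_script_mismatch_rejected(self, menu, protocol, perfect_log):
        other = cs.generate_script(menu, protocol, seed=99)
        with pytest.raises(ResponseReferenceError):
            cs.score_session(other, perfect_log)


class TestOracleEquivalence:
    @pytest.mark.parametrize("level", [1, 2])
    def test_exhaustive_patterns_match_brute_force(self, script, level):
        """All 2^k correctness patterns per metric agree with the
        enumeration oracle on the small levels (k = 2 and 4)."""
        lv = script.level(level)
        items = lv.ordered_item_ids
        k = len(items)
        patterns = list(itertools.product([0, 1], repeat=k))
        for imm_pat in patterns:
            for srv_pat in patterns:
                claimed = tuple(it for it, bit in zip(items, imm_pat) if bit)
                service = {}
                for it, bit in zip(items, srv_pat):
                    t, c = lv.seat_of(it)
                    service[it] = (t, c) if bit else ((t % lv.config.n_tables) + 1, c)
                rs = cs.ResponseSet(
                    level=level,
                    immediate_recall=claimed,
                    delayed_recall=claimed,
                    counter_selection=tuple(service),
                    service=service,
                )
                score = cs.score_level(lv, rs)
                o_imm, o_dly, o_rec, o_tab, o_cust, o_both = brute_force_level_score(lv, rs)
                assert (
                    score.points.immediate, score.points.delayed,
                    score.points.recognition, score.points.table,
                    score.points.customer, score.n_served_correct,
                ) == (o_imm, o_dly, o_rec, o_tab, o_cust, o_both)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        counts=st.tuples(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6),
                         st.integers(0, 6), st.integers(0, 6)),
    )
    def test_random_counts_match_brute_force_on_level3(self, script, counts):
        lv = script.level(3)
        imm, dly, rec, srv_ok, srv_bad = counts
        rec = max(rec, min(6, srv_ok + srv_bad))
        srv_bad = min(srv_bad, 6 - srv_ok)
        rs = responses_with_counts(lv, imm, dly, rec, srv_ok, srv_bad)
        score = cs.score_level(lv, rs)
        o = brute_force_level_score(lv, rs)
        assert (score.points.immediate, score.points.delayed, score.points.recognition,
                score.points.table, score.points.customer, score.n_served_correct) == o


class TestMonotonicity:
    def test_correcting_a_claim_never_decreases_scores(self, script):
        lv = script.level(4)
        base = responses_with_counts(lv, imm=3, dly=2, rec=4, served_ok=2, served_bad=1)
        base_score = cs.score_level(lv, base)
        items = lv.ordered_item_ids
        # add a correct immediate claim
        better = cs.ResponseSet(
            level=4,
            immediate_recall=base.immediate_recall + (items[5],),
            delayed_recall=base.delayed_recall,
            counter_selection=base.counter_selection,
            service=dict(base.service),
        )
        b = cs.score_level(lv, better)
        assert b.points.immediate == base_score.points.immediate + 1
        assert b.points.delayed == base_score.points.delayed
        # fix a wrongly served item
        fixed_service = dict(base.service)
        wrong_item = items[2]  # the served_bad one
        fixed_service[wrong_item] = lv.seat_of(wrong_item)
        better2 = cs.ResponseSet(
            level=4,
            immediate_recall=base.immediate_recall,
            delayed_recall=base.delayed_recall,
            counter_selection=base.counter_selection,
            service=fixed_service,
        )
        b2 = cs.score_level(lv, better2)
        assert b2.points.table >= base_score.points.table
        assert b2.points.customer >= base_score.points.customer
        assert b2.n_served_correct == base_score.n_served_correct + 1
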