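"""Session state machine, event log, and discontinuation rule."""

import pytest
from hypothesis import given, settings, strategies as st

import cafescreen as cs
from cafescreen.errors import (
    IncompleteInputError,
    ProtocolOrderError,
    ResponseReferenceError,
)
from cafescreen.session import PHASE_ORDER, Phase, run_scripted_session


def responses_with_counts(level_script, imm, dly, rec, served_ok, served_bad=0):
    """Build responses hitting exact per-metric correct counts.

    Served items are taken from the counter picks, so ``served_ok +
    served_bad <= rec`` must hold.
    """
    items = level_script.ordered_item_ids
    assert served_ok + served_bad <= rec
    cfg = level_script.config
    service = {}
    for i in range(served_ok):
        service[items[i]] = level_script.seat_of(items[i])
    for i in range(served_ok, served_ok + served_bad):
        t, c = level_script.seat_of(items[i])
        wrong = [
            (tt, cc)
            for tt in range(1, cfg.n_tables + 1)
            for cc in range(1, cfg.customers_per_table + 1)
            if (tt, cc) != (t, c)
        ][0]
        service[items[i]] = wrong
    return cs.ResponseSet(
        level=level_script.level,
        immediate_recall=items[:imm],
        delayed_recall=items[:dly],
        counter_selection=items[:rec],
        service=service,
    )


class TestStateMachine:
    def test_start_positions_at_level1_presentation(self, script):
        state = cs.start_session(script)
        assert state.current_level == 1
        assert state.current_phase is Phase.PRESENTATION
        assert state.outcome is None
        assert state.events[0].phase is Phase.PRESENTATION
        assert state.events[0].timestamp == 0.0

    def test_in_order_submission_advances(self, script):
        state = cs.start_session(script)
        cs.submit_phase(state, Phase.PRESENTATION)
        cs.submit_phase(state, Phase.IMMEDIATE_RECALL, script.level(1).ordered_item_ids)
        assert state.current_phase is Phase.DISTRACTION

    def test_out_of_order_phase_rejected(self, script):
        state = cs.start_session(script)
        cs.submit_phase(state, Phase.PRESENTATION)
        with pytest.raises(ProtocolOrderError, match="immediate_recall"):
            cs.submit_phase(state, Phase.SERVICE, {})

    def test_counter_pick_outside_lineup_rejected(self, script):
        state = cs.start_session(script)
        for ph in (Phase.PRESENTATION, Phase.IMMEDIATE_RECALL, Phase.DISTRACTION,
                   Phase.DELAYED_RECALL):
            cs.submit_phase(state, ph, ())
        with pytest.raises(ResponseReferenceError, match="lineup"):
            cs.submit_phase(state, Phase.COUNTER_SELECTION, ("no_such_item",))

    def test_service_requires_counter_pick(self, script):
        state = cs.start_session(script)
        items = script.level(1).ordered_item_ids
        for ph, payload in (
            (Phase.PRESENTATION, None), (Phase.IMMEDIATE_RECALL, items),
            (Phase.DISTRACTION, None), (Phase.DELAYED_RECALL, items),
            (Phase.COUNTER_SELECTION, items[:1]),
        ):
            cs.submit_phase(state, ph, payload)
        with pytest.raises(ResponseReferenceError, match="not selected"):
            cs.submit_phase(state, Phase.SERVICE, {items[1]: (1, 1)})

    def test_finalize_before_level_end_rejected(self, script):
        state = cs.start_session(script)
        with pytest.raises(ProtocolOrderError):
            cs.finalize_level(state)


class TestDiscontinuationRule:
    def test_all_zero_accuracies_discontinue(self, script):
        log = run_scripted_session(script, [cs.ResponseSet.empty(1)])
        assert log.outcome.status == "discontinued"
        assert log.outcome.discontinued_at == 1

    def test_single_metric_at_threshold_continues(self, script):
        # level 4 (8 items): accuracies (3/8, 3/8, 5/8, 3/8) — only
        # recognition clears the bar, which is enough to continue
        lv = script.level(4)
        rs = responses_with_counts(lv, imm=3, dly=3, rec=5, served_ok=3)
        score = cs.score_level(lv, rs)
        accs = cs.accuracies(score)
        assert sum(a >= 0.5 for a in accs) == 1
        state = cs.start_session(script)
        state.current_level = 4
        state.phase_index = len(PHASE_ORDER) - 1
        state.responses[4] = {
            Phase.IMMEDIATE_RECALL: rs.immediate_recall,
            Phase.DELAYED_RECALL: rs.delayed_recall,
            Phase.COUNTER_SELECTION: rs.counter_selection,
            Phase.SERVICE: rs.service,
        }
        _, decision = cs.finalize_level(state)
        assert decision == "continue"

    def test_exactly_half_accuracy_continues(self, script):
        # strict inequality: 0.5 on every metric is not "below 50%"
        lv = script.level(2)
        rs = responses_with_counts(lv, imm=2, dly=2, rec=2, served_ok=2)
        assert cs.accuracies(cs.score_level(lv, rs)) == (0.5, 0.5, 0.5, 0.5)
        log = run_scripted_session(
            script,
            [rs if l.level == 2 else cs.ResponseSet.perfect(l) for l in script.levels],
        )
        assert log.outcome.completed

    def test_all_below_half_discontinues_midway(self, script):
        lv3 = script.level(3)  # 6 items: 2/6 everywhere is < 0.5 on all four
        weak = responses_with_counts(lv3, imm=2, dly=2, rec=2, served_ok=2)
        responses = [cs.ResponseSet.perfect(l) for l in script.levels[:2]] + [weak]
        log = run_scripted_session(script, responses)
        assert log.outcome.discontinued_at == 3
        assert log.levels_played == 3
        assert all(ev.level <= 3 for ev in log.events)

    def test_missing_continuing_level_raises(self, script, perfect_responses):
        with pytest.raises(IncompleteInputError, match="level 2"):
            run_scripted_session(script, perfect_responses[:1])


class TestSessionLog:
    def test_full_correct_session_completes_all_levels(self, perfect_log):
        assert perfect_log.outcome.completed
        assert perfect_log.levels_played == 5

    def test_replay_is_deterministic(self, script, perfect_responses):
        a = run_scripted_session(script, perfect_responses)
        b = run_scripted_session(script, perfect_responses)
        assert a == b

    def test_timestamps_nondecreasing(self, perfect_log):
        ts = [ev.timestamp for ev in perfect_log.events]
        assert ts == sorted(ts)

    def test_phase_transitions_legal(self, perfect_log):
        by_level: dict[int, list[Phase]] = {}
        # events[0] is the session-start marker at the level-1 presentation
        for ev in perfect_log.events[1:]:
            if ev.phase is not Phase.SESSION_END:
                by_level.setdefault(ev.level, []).append(ev.phase)
        for phases in by_level.values():
            assert phases == list(PHASE_ORDER)

    def test_distraction_advances_clock_120s(self, perfect_log):
        events = perfect_log.events
        for i, ev in enumerate(events):
            if ev.phase is Phase.DISTRACTION:
                prev = events[i - 1]
                assert ev.timestamp - prev.timestamp == pytest.approx(120.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        fracs=st.tuples(*[st.floats(0, 1) for _ in range(4)]),
    )
    def test_log_invariants_over_random_sessions(self, menu, protocol, seed, fracs):
        script = cs.generate_script(menu, protocol, seed)
        responses = []
        for lv in script.levels:
            k = lv.config.n_items
            imm, dly, rec, srv = (int(round(f * k)) for f in fracs)
            srv = min(srv, rec)
            responses.append(responses_with_counts(lv, imm, dly, rec, srv))
        log = run_scripted_session(script, responses)
        assert 1 <= log.levels_played <= 5
        ts = [ev.timestamp for ev in log.events]
        assert ts == sorted(ts)
        if log.outcome.discontinued_at is not None:
            assert all(ev.level <= log.outcome.discontinued_at for ev in log.events)


class TestDiscontinuationMonotonicity:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        counts=st.tuples(st.integers(0, 4), st.integers(0, 4), st.integers(0, 4),
                         st.integers(0, 4)),
        improve=st.integers(0, 3),
    )
    def test_improving_one_response_never_flips_continue_to_discontinue(
        self, script, counts, improve
    ):
        lv = script.level(2)  # 4 items
        imm, dly, rec, srv = counts
        srv = min(srv, rec)
        before = responses_with_counts(lv, imm, dly, rec, srv)

        def decision(rs):
            accs = cs.accuracies(cs.score_level(lv, rs))
            return "discontinue" if all(a < 0.5 for a in accs) else "continue"

        bumped = [imm, dly, rec, srv]
        bumped[improve] = min(4, bumped[improve] + 1)
        if improve < 3:
            bumped[3] = min(bumped[3], bumped[2])
        else:
            bumped[2] = max(bumped[2], bumped[3])
        after = responses_with_counts(lv, *bumped)
        if decision(before) == "continue":
            assert decision(after) == "continue"
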