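"""Day-time titration: cycle schedule, safety gating, pause/retry, Q1 loop."""

import pytest

from nivflow import (
    AirAmount,
    EventKind,
    InputError,
    ProtocolError,
    QuestionnaireResponse,
    VentilatorConfig,
)
from nivflow.tdt import (
    TdtEntryPath,
    TdtPhase,
    tdt_apply_q1,
    tdt_receive_bga,
    tdt_resume_after_pause,
    tdt_start,
)
from conftest import bga


def q1(amount, q4=None):
    return QuestionnaireResponse(q1_air_amount=amount, q4_more_comfortable=q4)


def start_state(record, config, entry=TdtEntryPath.AFTER_INI, now=0.0):
    return tdt_start(record, entry, config, now=now).state


class TestStart:
    def test_initiation_entry_keeps_incoming_config(self, new_record, config):
        state = start_state(new_record, config.with_ipap(18))
        assert state.config.ipap == 18
        assert state.cycle_count == 0

    def test_control_visit_loads_stored_night_config(self, recurring_record):
        state = start_state(recurring_record, None,
                            TdtEntryPath.CONTROL_VISIT_AFTER_FIRST_NIGHT)
        assert state.config == recurring_record.stored_night_config

    def test_control_visit_without_stored_config_fails(self, new_record):
        with pytest.raises(ProtocolError, match="stored night"):
            tdt_start(new_record, TdtEntryPath.CONTROL_VISIT_AFTER_FIRST_NIGHT, None)

    def test_bga_scheduled_at_minute_15_of_20(self, new_record, config):
        tr = tdt_start(new_record, TdtEntryPath.AFTER_INI, config, now=100.0)
        assert tr.state.bga_due_at == 115.0
        advisory = [e for e in tr.events if e.kind is EventKind.RECOMMENDATION][0]
        assert advisory.payload["cycle_minutes"] == 20.0
        assert advisory.payload["bga_minute"] == 15.0


class TestReceiveBga:
    def test_acidosis_aborts_with_physician_call(self, new_record, config):
        state = start_state(new_record, config)
        tr = tdt_receive_bga(state, bga(ph=7.30))
        assert tr.state.phase is TdtPhase.ABORTED
        advice = [e.payload.get("advice", "") for e in tr.events]
        assert any("physician" in a for a in advice)

    def test_alkalosis_pauses_thirty_minutes(self, new_record, config):
        state = start_state(new_record, config)
        tr = tdt_receive_bga(state, bga(ph=7.60, taken_at=15.0), now=15.0)
        assert tr.state.phase is TdtPhase.PAUSED_ALKALOSIS
        assert tr.state.pause_until == 45.0

    def test_safe_values_lead_to_questioning(self, new_record, config):
        state = start_state(new_record, config)
        tr = tdt_receive_bga(state, bga(ph=7.42, spo2=93))
        assert tr.state.phase is TdtPhase.QUESTIONING

    def test_out_of_cycle_sample_rejected(self, new_record, config):
        state = start_state(new_record, config, now=50.0)
        with pytest.raises(InputError):
            tdt_receive_bga(state, bga(taken_at=10.0))


class TestPauseResume:
    def _paused(self, record, config, ipap=18):
        state = start_state(record, config.with_ipap(ipap))
        return tdt_receive_bga(state, bga(ph=7.60), now=15.0).state

    def test_resume_lowers_ipap_by_two(self, new_record, config):
        paused = self._paused(new_record, config)
        tr = tdt_resume_after_pause(paused, bga(ph=7.50, taken_at=45.0),
                                    patient_approves=True, now=45.0)
        assert tr.state.phase is TdtPhase.VENTILATING
        assert tr.state.config.ipap == 16

    def test_persistent_alkalosis_aborts(self, new_record, config):
        paused = self._paused(new_record, config)
        tr = tdt_resume_after_pause(paused, bga(ph=7.58, taken_at=45.0),
                                    patient_approves=True, now=45.0)
        assert tr.state.phase is TdtPhase.ABORTED

    def test_patient_decline_aborts(self, new_record, config):
        paused = self._paused(new_record, config)
        tr = tdt_resume_after_pause(paused, bga(ph=7.50, taken_at=45.0),
                                    patient_approves=False, now=45.0)
        assert tr.state.phase is TdtPhase.ABORTED

    def test_no_exit_before_pause_elapses(self, new_record, config):
        paused = self._paused(new_record, config)
        with pytest.raises(ProtocolError, match="20 minutes remain"):
            tdt_resume_after_pause(paused, bga(ph=7.50, taken_at=25.0),
                                   patient_approves=True, now=25.0)

    def test_resume_respects_pressure_floor(self, new_record, config):
        paused = self._paused(new_record, config, ipap=8)  # epap 5 -> floor 7
        tr = tdt_resume_after_pause(paused, bga(ph=7.50, taken_at=45.0),
                                    patient_approves=True, now=45.0)
        assert tr.state.config.ipap == 7

    def test_resume_impossible_at_floor_aborts(self, new_record, config):
        """Recurring alkalosis with no room to lower IPAP cannot be handled
        by the protocol's restart rule and is referred to a physician."""
        paused = self._paused(new_record, config, ipap=7)  # already at floor
        tr = tdt_resume_after_pause(paused, bga(ph=7.50, taken_at=45.0),
                                    patient_approves=True, now=45.0)
        assert tr.state.phase is TdtPhase.ABORTED


class TestApplyQ1:
    def _questioning(self, record, config):
        state = start_state(record, config)
        return tdt_receive_bga(state, bga()).state

    def test_enough_ends_without_consuming_a_cycle(self, new_record, config):
        state = self._questioning(new_record, config)
        tr = tdt_apply_q1(state, q1(AirAmount.ENOUGH))
        assert tr.state.phase is TdtPhase.DONE
        assert tr.state.cycle_count == 0

    def test_three_adjustment_cycles_then_done(self, new_record, config):
        """A never-satisfied, always-approving patient gets exactly three
        pressure adjustments before the process terminates."""
        state = self._questioning(new_record, config)
        adjustments = 0
        while state.phase is not TdtPhase.DONE:
            tr = tdt_apply_q1(state, q1(AirAmount.TOO_LITTLE),
                              patient_approves_another_cycle=True)
            state = tr.state
            adjustments += 1
            if state.phase is TdtPhase.VENTILATING:
                state = tdt_receive_bga(state, bga(taken_at=state.bga_due_at),
                                        now=state.bga_due_at).state
        assert adjustments == 3
        assert state.cycle_count == 3
        assert state.config.ipap == 16 + 3 * 2

    def test_decline_ends_after_one_adjustment(self, new_record, config):
        state = self._questioning(new_record, config)
        tr = tdt_apply_q1(state, q1(AirAmount.TOO_LITTLE),
                          patient_approves_another_cycle=False)
        assert tr.state.phase is TdtPhase.DONE
        assert tr.state.cycle_count == 1

    def test_lowering_floored_at_epap_plus_two(self, new_record, config):
        state = self._questioning(new_record, config.with_ipap(8))
        tr = tdt_apply_q1(state, q1(AirAmount.TOO_MUCH))
        assert tr.state.config.ipap == 7

    def test_wrong_phase_rejected(self, new_record, config):
        state = start_state(new_record, config)
        with pytest.raises(ProtocolError):
            tdt_apply_q1(state, q1(AirAmount.ENOUGH))


BGA_CASES = {
    "safe": dict(ph=7.42, spo2=95),
    "acidotic": dict(ph=7.30, spo2=95),
    "hypoxemic": dict(ph=7.42, spo2=80),
    "alkalotic": dict(ph=7.60, spo2=95),
}


def walk_tdt(state, now, depth, on_state):
    """Exhaustively branch over all input categories at each decision point."""
    on_state(state, depth)
    if state.phase in (TdtPhase.DONE, TdtPhase.ABORTED):
        return
    assert depth < 40, "day-time titration failed to terminate"
    if state.phase is TdtPhase.VENTILATING:
        now = state.bga_due_at
        for kw in BGA_CASES.values():
            tr = tdt_receive_bga(state, bga(taken_at=now, **kw), now=now)
            walk_tdt(tr.state, now, depth + 1, on_state)
    elif state.phase is TdtPhase.PAUSED_ALKALOSIS:
        now = state.pause_until
        for ph in (7.50, 7.58):
            for approves in (True, False):
                tr = tdt_resume_after_pause(state, bga(ph=ph, taken_at=now),
                                            approves, now=now)
                walk_tdt(tr.state, now, depth + 1, on_state)
    elif state.phase is TdtPhase.QUESTIONING:
        for amount in AirAmount:
            for approves in (True, False):
                tr = tdt_apply_q1(state, q1(amount), approves, now=now)
                walk_tdt(tr.state, now, depth + 1, on_state)
    else:
        raise AssertionError(f"unexpected phase {state.phase}")


class TestExhaustiveWalk:
    def test_all_trajectories_terminate_within_three_cycles(self, new_record, config):
        terminal = {"count": 0}

        def check(state, depth):
            assert state.cycle_count <= 3
            assert state.config.ipap > state.config.epap
            if state.phase in (TdtPhase.DONE, TdtPhase.ABORTED):
                terminal["count"] += 1

        walk_tdt(start_state(new_record, config), 0.0, 0, check)
        assert terminal["count"] > 100  # rich trajectory tree fully explored
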