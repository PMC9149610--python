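"""Engine routing, hand-offs, event log and replay determinism."""

import re

import pytest

from nivflow import (
    AirAmount,
    AnswersInput,
    BgaInput,
    ClockAdvance,
    Disposition,
    EventKind,
    InputError,
    PatientRecord,
    PatientStatus,
    ProcessName,
    ProtocolError,
    QuestionnaireResponse,
    RoutingError,
    advance,
    new_session,
    replay,
    route_patient,
    session_to_json,
)
from nivflow.ini import IniState
from nivflow.patient import (
    ApprovalPolicy,
    ComfortPolicy,
    VirtualPatientParams,
    run_closed_loop,
)
from nivflow.tdt import TdtEntryPath, TdtPhase, TdtState
from nivflow.tnt import TntState
from conftest import bga


SATISFIED = QuestionnaireResponse(q1_air_amount=AirAmount.ENOUGH)


class TestRouting:
    def test_new_patient_enters_initiation(self, new_record):
        assert route_patient(new_record) is ProcessName.INI

    def test_recurring_patient_enters_night_titration(self, recurring_record):
        assert route_patient(recurring_record) is ProcessName.TNT

    def test_recurring_without_stored_config_rejected(self):
        record = PatientRecord.__new__(PatientRecord)
        object.__setattr__(record, "patient_id", "x")
        object.__setattr__(record, "status", PatientStatus.RECURRING)
        object.__setattr__(record, "paco2_history", ())
        object.__setattr__(record, "stored_night_config", None)
        with pytest.raises(RoutingError):
            route_patient(record)


class TestHandoffs:
    def test_initiation_done_starts_daytime_with_its_config(self, new_record):
        session = new_session(new_record)
        assert isinstance(session.process_state, IniState)
        session = advance(session, ClockAdvance(5))
        session = advance(session, AnswersInput(SATISFIED))
        assert session.active_process is ProcessName.TDT
        assert session.process_state.entry_path is TdtEntryPath.AFTER_INI
        assert session.process_state.config.ipap == 16

    def _to_tnt(self, record):
        session = new_session(record)
        session = advance(session, ClockAdvance(5))
        session = advance(session, AnswersInput(SATISFIED))
        session = advance(session, ClockAdvance(15))
        session = advance(session, BgaInput(bga(taken_at=session.clock)))
        session = advance(session, AnswersInput(SATISFIED))
        assert session.active_process is ProcessName.TNT
        return session

    def _through_night(self, session, night2=44.0):
        t0 = session.clock
        session = advance(session, BgaInput(bga(paco2=58.0, on_niv=False,
                                                taken_at=t0)))
        session = advance(session, ClockAdvance(240))
        session = advance(session, BgaInput(bga(paco2=50.0, taken_at=t0 + 240)))
        session = advance(session, ClockAdvance(240))
        session = advance(session, BgaInput(bga(paco2=night2, taken_at=t0 + 480)))
        return session

    def test_discharge_is_terminal(self, new_record):
        session = self._through_night(self._to_tnt(new_record))
        session = advance(session, AnswersInput(SATISFIED))
        assert session.disposition is Disposition.DISCHARGED
        assert session.active_process is None
        assert session.record.stored_night_config is not None
        with pytest.raises(ProtocolError):
            advance(session, ClockAdvance(1))

    def test_option_c_restarts_daytime_then_night(self, new_record):
        session = self._through_night(self._to_tnt(new_record), night2=53.0)
        session = advance(session, AnswersInput(SATISFIED))  # PaCO2 needs more
        assert session.active_process is ProcessName.TDT
        assert (session.process_state.entry_path
                is TdtEntryPath.AFTER_NIGHT_NEEDING_ADJUSTMENT)
        assert session.process_state.config.ipap == 18

    def test_clock_never_moves_backward(self, new_record):
        session = new_session(new_record)
        with pytest.raises(InputError):
            advance(session, ClockAdvance(-1))


class TestEventLog:
    def test_seq_contiguous_from_one(self, new_record):
        session = self._drive(new_record)
        assert [e.seq for e in session.events] == list(range(1, len(session.events) + 1))

    def _drive(self, record):
        session = new_session(record)
        session = advance(session, ClockAdvance(5))
        session = advance(session, AnswersInput(SATISFIED))
        return session

    def test_every_transition_appends_events(self, new_record):
        session = new_session(new_record)
        n = len(session.events)
        assert n >= 1
        session2 = advance(session, ClockAdvance(5))
        assert len(session2.events) > n
        # value semantics: the prior session is untouched
        assert len(session.events) == n


def process_sequence(session):
    return [e.payload["process"] for e in session.events
            if e.process is ProcessName.ENGINE
            and e.kind is EventKind.STATE_ENTERED and "process" in e.payload]


ROUTING_LANGUAGE_NEW = re.compile(r"^I D N (D N |N )*$")
ROUTING_LANGUAGE_RECURRING = re.compile(r"^N (D N |N )*$")


class TestTrajectories:
    def test_routing_language_and_replay_for_new_patient(self):
        params = VirtualPatientParams(comfort_policy=ComfortPolicy.WANTS_MORE_PRESSURE,
                                      ipap_target=22, co2_sensitivity=0.8,
                                      noise_sd_paco2=0.5, rng_seed=7)
        session = run_closed_loop(params)
        seq = " ".join({"INI": "I", "TDT": "D", "TNT": "N"}[p]
                       for p in process_sequence(session)) + " "
        assert ROUTING_LANGUAGE_NEW.match(seq)
        assert session_to_json(replay(session)) == session_to_json(session)

    def test_recurring_patient_skips_initiation(self, recurring_record):
        params = VirtualPatientParams(co2_sensitivity=1.0, noise_sd_paco2=0.0)
        session = run_closed_loop(params, record=recurring_record)
        seq = " ".join({"INI": "I", "TDT": "D", "TNT": "N"}[p]
                       for p in process_sequence(session)) + " "
        assert ROUTING_LANGUAGE_RECURRING.match(seq)
        assert session.disposition is Disposition.DISCHARGED
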