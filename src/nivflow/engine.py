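"""Workflow engine: routing, session clock, event log, record mutation.

The engine is a pure step function ``advance(session, input) -> session``
over immutable values. It routes new patients through INI -> TDT -> TNT and
recurring patients straight into TNT; night-time outcomes then either
discharge the patient (option a), repeat the night titration (option b) or
repeat the day-time and night-time titrations (option c). Every external
input and every internal transition is appended to the session's event log,
which is the source of truth: replaying the recorded inputs from a fresh
session reproduces the identical final state and event sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Union

from . import ini as ini_mod
from . import tdt as tdt_mod
from . import tnt as tnt_mod
from .ini import IniPhase, IniState
from .model import (
    DEFAULT_SETTINGS,
    AirAmount,
    AirSpeed,
    BloodGasSample,
    Disposition,
    EventDraft,
    EventKind,
    InputError,
    PatientRecord,
    PatientStatus,
    ProcessEvent,
    ProcessName,
    ProtocolError,
    ProtocolSettings,
    QuestionnaireResponse,
    RoutingError,
    Transition,
    update_paco2_history,
)
from .tdt import TdtEntryPath, TdtPhase, TdtState
from .tnt import TntOption, TntPhase, TntReason, TntState

ProcessState = Union[IniState, TdtState, TntState]


# ---------------------------------------------------------------------------
# External inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClockAdvance:
    """Move the session clock forward by ``minutes`` (never backward)."""

    minutes: float


@dataclass(frozen=True)
class BgaInput:
    """A blood-gas measurement; ``patient_approves`` is consulted only when
    the sample is the recheck that ends an alkalosis pause."""

    sample: BloodGasSample
    patient_approves: Optional[bool] = None


@dataclass(frozen=True)
class AnswersInput:
    """Questionnaire answers; ``approves_another_cycle`` is consulted only
    by the day-time titration loop."""

    answers: QuestionnaireResponse
    approves_another_cycle: bool = True


EngineInput = Union[ClockAdvance, BgaInput, AnswersInput]


# ---------------------------------------------------------------------------
# Session
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Session:
    session_id: str
    settings: ProtocolSettings
    initial_record: PatientRecord
    record: PatientRecord
    clock: float = 0.0
    active_process: Optional[ProcessName] = None
    process_state: Optional[ProcessState] = None
    events: tuple[ProcessEvent, ...] = ()
    disposition: Disposition = Disposition.IN_PROGRESS
    nights_completed: int = 0


def route_patient(record: PatientRecord) -> ProcessName:
    """First process for a patient: INI when new, TNT when recurring."""
    if record.status is PatientStatus.NEW:
        return ProcessName.INI
    if record.stored_night_config is None:
        raise RoutingError("recurring patient without a stored night configuration")
    return ProcessName.TNT


def _stamp(session: Session, process: ProcessName,
           drafts: Iterable[EventDraft]) -> tuple[ProcessEvent, ...]:
    seq = itertools.count(len(session.events) + 1)
    return tuple(ProcessEvent(seq=next(seq), at=session.clock, process=process,
                              kind=d.kind, payload=dict(d.payload)) for d in drafts)


def _append(session: Session, process: ProcessName,
            drafts: Iterable[EventDraft], **changes) -> Session:
    events = session.events + _stamp(session, process, drafts)
    return replace(session, events=events, **changes)


def new_session(record: PatientRecord, settings: ProtocolSettings = DEFAULT_SETTINGS,
                session_id: str = "session") -> Session:
    """Open a session and start the first process per the routing rule."""
    first = route_patient(record)
    session = Session(session_id=session_id, settings=settings,
                      initial_record=record, record=record)
    session = _append(session, ProcessName.ENGINE,
                      (EventDraft(EventKind.STATE_ENTERED,
                                  {"process": first.value,
                                   "patient": record.patient_id,
                                   "status": record.status.value}),))
    if first is ProcessName.INI:
        tr = ini_mod.ini_start(record, settings, now=session.clock)
        return _append(session, ProcessName.INI, tr.events,
                       active_process=ProcessName.INI, process_state=tr.state)
    tr = tnt_mod.tnt_start(record, record.stored_night_config, settings,
                           now=session.clock)
    return _append(session, ProcessName.TNT, tr.events,
                   active_process=ProcessName.TNT, process_state=tr.state)


# ---------------------------------------------------------------------------
# Process hand-offs
# ---------------------------------------------------------------------------

def _start_tdt(session: Session, entry_path: TdtEntryPath, config) -> Session:
    session = _append(session, ProcessName.ENGINE,
                      (EventDraft(EventKind.STATE_ENTERED, {"process": "TDT"}),))
    tr = tdt_mod.tdt_start(session.record, entry_path, config,
                           session.settings, now=session.clock)
    return _append(session, ProcessName.TDT, tr.events,
                   active_process=ProcessName.TDT, process_state=tr.state)


def _start_tnt(session: Session, config) -> Session:
    session = _append(session, ProcessName.ENGINE,
                      (EventDraft(EventKind.STATE_ENTERED, {"process": "TNT"}),))
    tr = tnt_mod.tnt_start(session.record, config, session.settings, now=session.clock)
    return _append(session, ProcessName.TNT, tr.events,
                   active_process=ProcessName.TNT, process_state=tr.state)


def _abort(session: Session, process: ProcessName) -> Session:
    session = _append(session, ProcessName.ENGINE,
                      (EventDraft(EventKind.TERMINATED,
                                  {"disposition": Disposition.ABORTED_PHYSICIAN.value}),))
    return replace(session, disposition=Disposition.ABORTED_PHYSICIAN,
                   active_process=None)


def _after_process_step(session: Session) -> Session:
    """Resolve hand-offs after a process reached a terminal phase."""
    state = session.process_state
    if isinstance(state, IniState) and state.phase is IniPhase.DONE:
        return _start_tdt(session, TdtEntryPath.AFTER_INI, state.config)
    if isinstance(state, TdtState):
        if state.phase is TdtPhase.ABORTED:
            return _abort(session, ProcessName.TDT)
        if state.phase is TdtPhase.DONE:
            return _start_tnt(session, state.config)
    if isinstance(state, TntState) and state.phase is TntPhase.ABORTED:
        return _abort(session, ProcessName.TNT)
    return session


# ---------------------------------------------------------------------------
# Input dispatch
# ---------------------------------------------------------------------------

def advance(session: Session, input: EngineInput) -> Session:
    """Apply one external input and return the successor session."""
    if session.disposition is not Disposition.IN_PROGRESS:
        raise ProtocolError(
            f"session already terminal ({session.disposition.value})")

    if isinstance(input, ClockAdvance):
        return _advance_clock(session, input)
    if isinstance(input, BgaInput):
        return _advance_bga(session, input)
    if isinstance(input, AnswersInput):
        return _advance_answers(session, input)
    raise InputError(f"unsupported input type {type(input).__name__}; expected "
                     "ClockAdvance, BgaInput or AnswersInput")


def _advance_clock(session: Session, input: ClockAdvance) -> Session:
    if input.minutes < 0:
        raise InputError("the session clock never moves backward")
    session = _append(session, ProcessName.ENGINE,
                      (EventDraft(EventKind.CLOCK_ADVANCED, {"minutes": input.minutes}),),
                      clock=session.clock + input.minutes)
    state = session.process_state
    if isinstance(state, TdtState):
        tr = tdt_mod.tdt_on_clock(state, session.clock)
        if tr.state is not state:
            session = _append(session, ProcessName.TDT, tr.events, process_state=tr.state)
    return session


def _record_sample(session: Session, sample: BloodGasSample) -> Session:
    return replace(session, record=update_paco2_history(session.record, sample))


def _advance_bga(session: Session, input: BgaInput) -> Session:
    state = session.process_state
    sample = input.sample
    measurement = EventDraft(EventKind.MEASUREMENT_RECORDED,
                             {"ph": sample.ph, "paco2": sample.paco2,
                              "spo2": sample.spo2, "taken_at": sample.taken_at,
                              "on_niv": sample.on_niv, "source": sample.source,
                              "patient_approves": input.patient_approves})

    if isinstance(state, TdtState):
        if state.phase is TdtPhase.PAUSED_ALKALOSIS:
            if input.patient_approves is None:
                raise InputError("the post-pause recheck requires the patient's "
                                 "approval decision")
            tr = tdt_mod.tdt_resume_after_pause(state, sample, input.patient_approves,
                                                session.settings, now=session.clock)
        else:
            tr = tdt_mod.tdt_receive_bga(state, sample, session.settings,
                                         now=session.clock)
        session = _record_sample(session, sample)
        session = _append(session, ProcessName.TDT, (measurement,) + tr.events,
                          process_state=tr.state)
        return _after_process_step(session)

    if isinstance(state, TntState):
        if state.phase is TntPhase.PAUSED_ALKALOSIS:
            if input.patient_approves is None:
                raise InputError("the post-pause recheck requires the patient's "
                                 "approval decision")
            tr = tnt_mod.tnt_resume_after_pause(state, sample, input.patient_approves,
                                                session.settings, now=session.clock)
        else:
            tr = tnt_mod.tnt_receive_sample(state, sample, session.settings,
                                            now=session.clock)
        session = _record_sample(session, sample)
        session = _append(session, ProcessName.TNT, (measurement,) + tr.events,
                          process_state=tr.state)
        return _after_process_step(session)

    raise ProtocolError("the initiation process takes no blood-gas input; "
                        "expected questionnaire answers or a clock advance")


def _advance_answers(session: Session, input: AnswersInput) -> Session:
    state = session.process_state
    answers = input.answers
    answer_event = EventDraft(EventKind.ANSWER_RECORDED,
                              {"q1": answers.q1_air_amount.value,
                               "q2": answers.q2_air_speed.value,
                               "q3": answers.q3_trigger_exhausting,
                               "q4": answers.q4_more_comfortable,
                               "approves_another_cycle": input.approves_another_cycle})

    if isinstance(state, IniState):
        tr = ini_mod.ini_apply_answers(state, answers, session.settings,
                                       now=session.clock)
        session = _append(session, ProcessName.INI, (answer_event,) + tr.events,
                          process_state=tr.state)
        return _after_process_step(session)

    if isinstance(state, TdtState):
        tr = tdt_mod.tdt_apply_q1(state, answers, input.approves_another_cycle,
                                  session.settings, now=session.clock)
        session = _append(session, ProcessName.TDT, (answer_event,) + tr.events,
                          process_state=tr.state)
        return _after_process_step(session)

    if isinstance(state, TntState):
        ev = tnt_mod.tnt_evaluate(state, session.record, answers,
                                  session.settings, now=session.clock)
        session = _append(session, ProcessName.TNT, (answer_event,) + ev.events,
                          process_state=ev.state,
                          nights_completed=session.nights_completed + 1)
        outcome = ev.outcome
        if outcome.option is TntOption.A_DISCHARGE:
            record = replace(session.record, stored_night_config=outcome.final_config)
            session = _append(session, ProcessName.ENGINE,
                              (EventDraft(EventKind.TERMINATED,
                                          {"disposition": Disposition.DISCHARGED.value}),),
                              record=record, disposition=Disposition.DISCHARGED,
                              active_process=None, process_state=ev.state)
            return session
        record = replace(session.record, stored_night_config=outcome.final_config)
        session = replace(session, record=record)
        if outcome.option is TntOption.B_REPEAT_TNT:
            return _start_tnt(session, outcome.final_config)
        return _start_tdt(session, TdtEntryPath.AFTER_NIGHT_NEEDING_ADJUSTMENT,
                          outcome.final_config)

    raise ProtocolError("no process is active")


# ---------------------------------------------------------------------------
# Replay
# ---------------------------------------------------------------------------

def extract_inputs(events: Iterable[ProcessEvent]) -> list[EngineInput]:
    """Reconstruct the external input sequence from an event log."""
    inputs: list[EngineInput] = []
    for ev in events:
        if ev.kind is EventKind.CLOCK_ADVANCED:
            inputs.append(ClockAdvance(minutes=ev.payload["minutes"]))
        elif ev.kind is EventKind.MEASUREMENT_RECORDED:
            p = ev.payload
            sample = BloodGasSample(ph=p["ph"], paco2=p["paco2"], spo2=p["spo2"],
                                    taken_at=p["taken_at"], on_niv=p["on_niv"],
                                    source=p.get("source", "arterial"))
            inputs.append(BgaInput(sample=sample,
                                   patient_approves=p.get("patient_approves")))
        elif ev.kind is EventKind.ANSWER_RECORDED and "approves_another_cycle" in ev.payload:
            p = ev.payload
            answers = QuestionnaireResponse(
                q1_air_amount=AirAmount(p["q1"]),
                q2_air_speed=AirSpeed(p["q2"]),
                q3_trigger_exhausting=p["q3"],
                q4_more_comfortable=p["q4"])
            inputs.append(AnswersInput(answers=answers,
                                       approves_another_cycle=p["approves_another_cycle"]))
    return inputs


def replay(session: Session) -> Session:
    """Re-run a session's recorded inputs from its initial record."""
    rebuilt = new_session(session.initial_record, session.settings,
                          session.session_id)
    for inp in extract_inputs(session.events):
        rebuilt = advance(rebuilt, inp)
    return rebuilt
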