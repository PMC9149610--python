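"""Day-time titration of NIV (TDT).

The goal is an optimal inspiratory pressure. The patient is ventilated in
20-minute cycles with a blood gas drawn at minute 15 of each cycle:

* hypoxemia (SpO2 < 85 %) or acidosis (pH < 7.35) aborts the process
  immediately with advice to call a physician;
* alkalosis (pH > 7.55) stops ventilation for a 30-minute pause; if a
  recheck shows pH <= 7.55 and the patient approves, the cycle restarts
  with IPAP lowered by 2 mbar, otherwise the process is aborted;
* within safety ranges the patient answers Q1 and IPAP is adjusted by
  2 mbar up or down accordingly.

The ventilation-and-parameter-change cycle repeats at most three times and
only while the patient approves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .model import (
    DEFAULT_SETTINGS,
    AirAmount,
    BloodGasSample,
    EventDraft,
    EventKind,
    InputError,
    PatientRecord,
    ProtocolError,
    ProtocolSettings,
    QuestionnaireResponse,
    SafetyAction,
    Transition,
    VentilatorConfig,
    config_payload,
)
from .safety import alkalosis_resolved, evaluate_safety


class TdtPhase(str, Enum):
    VENTILATING = "VENTILATING"
    AWAITING_BGA = "AWAITING_BGA"
    PAUSED_ALKALOSIS = "PAUSED_ALKALOSIS"
    QUESTIONING = "QUESTIONING"
    ABORTED = "ABORTED"
    DONE = "DONE"


class TdtEntryPath(str, Enum):
    AFTER_INI = "AFTER_INI"
    CONTROL_VISIT_AFTER_FIRST_NIGHT = "CONTROL_VISIT_AFTER_FIRST_NIGHT"
    AFTER_NIGHT_NEEDING_ADJUSTMENT = "AFTER_NIGHT_NEEDING_ADJUSTMENT"


@dataclass(frozen=True)
class TdtState:
    phase: TdtPhase
    config: VentilatorConfig
    entry_path: TdtEntryPath
    cycle_count: int = 0
    cycle_started_at: float = 0.0
    bga_due_at: float = 0.0
    pause_until: Optional[float] = None


def _fresh_cycle(state: TdtState, config: VentilatorConfig, now: float,
                 settings: ProtocolSettings) -> TdtState:
    return replace(state, phase=TdtPhase.VENTILATING, config=config,
                   cycle_started_at=now, bga_due_at=now + settings.tdt_bga_minute,
                   pause_until=None)


def tdt_start(record: PatientRecord, entry_path: TdtEntryPath,
              incoming_config: Optional[VentilatorConfig] = None,
              settings: ProtocolSettings = DEFAULT_SETTINGS,
              now: float = 0.0) -> Transition:
    """Start day-time titration.

    Control-visit follow-up patients are ventilated with the stored
    in-hospital night configuration; initiation patients keep the
    configuration from INI or from the preceding night.
    """
    if entry_path is TdtEntryPath.CONTROL_VISIT_AFTER_FIRST_NIGHT:
        config = record.stored_night_config
        if config is None:
            raise ProtocolError("control-visit entry requires a stored night configuration")
    else:
        if incoming_config is None:
            raise ProtocolError(f"entry path {entry_path.value} requires the "
                                "configuration carried over from the previous process")
        config = incoming_config
    state = TdtState(phase=TdtPhase.VENTILATING, config=config, entry_path=entry_path,
                     cycle_count=0, cycle_started_at=now,
                     bga_due_at=now + settings.tdt_bga_minute)
    events = (
        EventDraft(EventKind.STATE_ENTERED, {"phase": state.phase.value,
                                             "entry_path": entry_path.value}),
        EventDraft(EventKind.CONFIG_CHANGED, {"config": config_payload(config),
                                              "reason": f"entry via {entry_path.value}"}),
        EventDraft(EventKind.RECOMMENDATION,
                   {"advice": f"ventilate for {settings.tdt_cycle_minutes:g} minutes; "
                              f"draw a blood gas after {settings.tdt_bga_minute:g} minutes",
                    "cycle_minutes": settings.tdt_cycle_minutes,
                    "bga_minute": settings.tdt_bga_minute}),
    )
    return Transition(state, events)


def tdt_on_clock(state: TdtState, now: float) -> Transition:
    """Clock poke: flag the blood gas as due once minute 15 is reached."""
    if state.phase is TdtPhase.VENTILATING and now >= state.bga_due_at:
        return Transition(replace(state, phase=TdtPhase.AWAITING_BGA),
                          (EventDraft(EventKind.RECOMMENDATION,
                                      {"advice": "perform a blood gas analysis now"}),))
    return Transition(state, ())


def tdt_receive_bga(state: TdtState, sample: BloodGasSample,
                    settings: ProtocolSettings = DEFAULT_SETTINGS,
                    now: float = 0.0) -> Transition:
    """Evaluate a cycle blood gas and gate the process on it."""
    if state.phase not in (TdtPhase.VENTILATING, TdtPhase.AWAITING_BGA):
        raise ProtocolError(f"blood gas not accepted in phase {state.phase.value}")
    if sample.taken_at < state.cycle_started_at:
        raise InputError("sample precedes the current ventilation cycle")

    verdict = evaluate_safety(sample, settings)
    events: list[EventDraft] = [
        EventDraft(EventKind.SAFETY_VERDICT,
                   {"verdict": verdict.verdict.value,
                    "reasons": sorted(r.value for r in verdict.reasons)}),
    ]
    if verdict.verdict is SafetyAction.ABORT_CALL_PHYSICIAN:
        events.append(EventDraft(EventKind.RECOMMENDATION,
                                 {"advice": "abort immediately and call a physician"}))
        events.append(EventDraft(EventKind.TERMINATED, {"outcome": "ABORTED"}))
        return Transition(replace(state, phase=TdtPhase.ABORTED), tuple(events))
    if verdict.verdict is SafetyAction.STOP_AND_PAUSE:
        pause_until = now + settings.pause_minutes
        events.append(EventDraft(
            EventKind.RECOMMENDATION,
            {"advice": f"stop ventilation; pause for {settings.pause_minutes:g} minutes, "
                       "then repeat the blood gas",
             "pause_until": pause_until}))
        return Transition(replace(state, phase=TdtPhase.PAUSED_ALKALOSIS,
                                  pause_until=pause_until), tuple(events))
    events.append(EventDraft(EventKind.QUESTION_ASKED, {"questions": ["Q1"]}))
    return Transition(replace(state, phase=TdtPhase.QUESTIONING), tuple(events))


def tdt_resume_after_pause(state: TdtState, recheck: BloodGasSample,
                           patient_approves: bool,
                           settings: ProtocolSettings = DEFAULT_SETTINGS,
                           now: float = 0.0) -> Transition:
    """Recheck after the alkalosis pause: resume at IPAP - 2 mbar or abort."""
    if state.phase is not TdtPhase.PAUSED_ALKALOSIS:
        raise ProtocolError(f"no alkalosis pause active in phase {state.phase.value}")
    assert state.pause_until is not None
    if now < state.pause_until:
        remaining = state.pause_until - now
        raise ProtocolError(f"pause not yet elapsed: {remaining:g} minutes remain")

    floor = state.config.epap + settings.ipap_floor_gap
    new_ipap = max(state.config.ipap - settings.ipap_step, floor)
    if alkalosis_resolved(recheck, settings) and patient_approves \
            and new_ipap < state.config.ipap:
        new_config = state.config.with_ipap(new_ipap)
        events = (
            EventDraft(EventKind.CONFIG_CHANGED,
                       {"config": config_payload(new_config),
                        "reason": "restart after resolved alkalosis: IPAP lowered"}),
            EventDraft(EventKind.STATE_ENTERED, {"phase": TdtPhase.VENTILATING.value}),
            EventDraft(EventKind.RECOMMENDATION,
                       {"advice": f"ventilate for {settings.tdt_cycle_minutes:g} minutes; "
                                  f"draw a blood gas after {settings.tdt_bga_minute:g} minutes"}),
        )
        return Transition(_fresh_cycle(state, new_config, now, settings), events)

    if not alkalosis_resolved(recheck, settings):
        reason = "alkalosis persisted"
    elif not patient_approves:
        reason = "patient declined to continue"
    else:
        reason = "inspiratory pressure cannot be lowered further"
    events = (
        EventDraft(EventKind.RECOMMENDATION,
                   {"advice": "abort and call a physician", "reason": reason}),
        EventDraft(EventKind.TERMINATED, {"outcome": "ABORTED", "reason": reason}),
    )
    return Transition(replace(state, phase=TdtPhase.ABORTED, pause_until=None), events)


def tdt_apply_q1(state: TdtState, answers: QuestionnaireResponse,
                 patient_approves_another_cycle: bool = True,
                 settings: ProtocolSettings = DEFAULT_SETTINGS,
                 now: float = 0.0) -> Transition:
    """Optimize the inspiratory pressure from the Q1 answer.

    "Enough" ends the process with the pressure considered optimal. Any
    adjustment consumes one of the three cycles; a fourth cycle, a declined
    continuation, or a pressure already at its limit also ends the process.
    """
    if state.phase is not TdtPhase.QUESTIONING:
        raise ProtocolError(f"Q1 answer not accepted in phase {state.phase.value}")

    events: list[EventDraft] = [
        EventDraft(EventKind.ANSWER_RECORDED, {"q1": answers.q1_air_amount.value}),
    ]
    if answers.q1_air_amount is AirAmount.ENOUGH:
        events.append(EventDraft(EventKind.TERMINATED,
                                 {"outcome": "DONE", "reason": "pressure optimal",
                                  "config": config_payload(state.config)}))
        return Transition(replace(state, phase=TdtPhase.DONE), tuple(events))

    step = settings.ipap_step
    floor = state.config.epap + settings.ipap_floor_gap
    if answers.q1_air_amount is AirAmount.TOO_LITTLE:
        new_ipap = min(state.config.ipap + step, settings.tdt_ipap_ceiling)
        limit_note = "CEILING_REACHED"
    else:
        new_ipap = max(state.config.ipap - step, floor)
        limit_note = "FLOOR_REACHED"

    if new_ipap == state.config.ipap:
        events.append(EventDraft(EventKind.RECOMMENDATION, {"note": limit_note}))
        events.append(EventDraft(EventKind.TERMINATED,
                                 {"outcome": "DONE", "reason": "pressure at limit",
                                  "config": config_payload(state.config)}))
        return Transition(replace(state, phase=TdtPhase.DONE), tuple(events))

    new_config = state.config.with_ipap(new_ipap)
    cycle_count = state.cycle_count + 1
    events.append(EventDraft(EventKind.CONFIG_CHANGED,
                             {"config": config_payload(new_config),
                              "cycle": cycle_count}))
    if cycle_count >= settings.tdt_max_cycles or not patient_approves_another_cycle:
        reason = ("adjustment cycles exhausted" if cycle_count >= settings.tdt_max_cycles
                  else "patient declined another cycle")
        events.append(EventDraft(EventKind.TERMINATED,
                                 {"outcome": "DONE", "reason": reason,
                                  "config": config_payload(new_config)}))
        return Transition(replace(state, phase=TdtPhase.DONE, config=new_config,
                                  cycle_count=cycle_count), tuple(events))

    events.append(EventDraft(
        EventKind.RECOMMENDATION,
        {"advice": f"ventilate for {settings.tdt_cycle_minutes:g} minutes; "
                   f"draw a blood gas after {settings.tdt_bga_minute:g} minutes"}))
    next_state = replace(_fresh_cycle(state, new_config, now, settings), cycle_count=cycle_count)
    return Transition(next_state, tuple(events))
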