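"""First initiation of NIV (INI).

A new patient is started on the best-practice configuration (pressure
support, IPAP 16 / EPAP 5 mbar, backup rate 18/min), ventilated for five
minutes, and then asked the comfort questionnaire. The answers drive
adjustments of three parameter families —

* Q1 (air amount)  -> inspiratory pressure, in 2 mbar steps, capped at
  20 mbar during initiation and floored at EPAP + 2 mbar;
* Q2 (air speed)   -> rise-time level, one ordinal step;
* Q3 (trigger effort) -> trigger sensitivity, one ordinal step more
  sensitive;

after any change the patient ventilates again and is additionally asked Q4
(is it now more comfortable?). A "no" reverts the last change and freezes
the families it touched. A family is also frozen after three consecutive
same-direction changes, and the whole loop is bounded by a global pass cap,
so initiation always terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .model import (
    DEFAULT_SETTINGS,
    AirAmount,
    AirSpeed,
    EventDraft,
    EventKind,
    PatientRecord,
    PatientStatus,
    ProtocolError,
    ProtocolSettings,
    QuestionnaireResponse,
    RoutingError,
    Transition,
    VentilatorConfig,
    config_payload,
    default_initial_config,
)

# Parameter families the questionnaire adjusts.
FAMILY_PRESSURE = "PRESSURE"
FAMILY_RISE_TIME = "RISE_TIME"
FAMILY_TRIGGER = "TRIGGER"


class IniPhase(str, Enum):
    VENTILATING = "VENTILATING"
    QUESTIONING = "QUESTIONING"
    DONE = "DONE"


@dataclass(frozen=True)
class IniState:
    """Position of the initiation state machine.

    ``streaks`` tracks, per family, the direction (+1/-1 encoded as "+"/"-")
    and length of the current run of same-direction changes; ``frozen``
    lists families no longer adjusted.
    """

    phase: IniPhase
    config: VentilatorConfig
    prior_config: Optional[VentilatorConfig] = None
    phase_started_at: float = 0.0
    expecting_q4: bool = False
    pass_count: int = 0
    frozen: frozenset[str] = frozenset()
    changed_last_pass: frozenset[str] = frozenset()
    streaks: tuple[tuple[str, str, int], ...] = ()

    def streak(self, family: str) -> tuple[Optional[str], int]:
        for fam, direction, count in self.streaks:
            if fam == family:
                return direction, count
        return None, 0

    def _with_streak(self, family: str, direction: str, count: int) -> "IniState":
        rest = tuple(s for s in self.streaks if s[0] != family)
        return replace(self, streaks=tuple(sorted(rest + ((family, direction, count),))))


def ini_start(record: PatientRecord,
              settings: ProtocolSettings = DEFAULT_SETTINGS,
              now: float = 0.0) -> Transition:
    """Start initiation for a new patient.

    Mask selection is a physician's manual step and is recorded as an
    advisory only. Emits the 5-minute ventilation advisory on the session
    clock; the engine never blocks on it.
    """
    if record.status is not PatientStatus.NEW:
        raise RoutingError("initiation is only performed for new patients; "
                           "recurring patients enter night-time titration")
    config = default_initial_config(settings)
    state = IniState(phase=IniPhase.VENTILATING, config=config, phase_started_at=now)
    events = (
        EventDraft(EventKind.STATE_ENTERED, {"phase": state.phase.value}),
        EventDraft(EventKind.CONFIG_CHANGED, {"config": config_payload(config),
                                              "reason": "initial best-practice configuration"}),
        EventDraft(EventKind.RECOMMENDATION,
                   {"advice": "choose a suitable mask (physician) and ventilate "
                              f"for {settings.ini_ventilation_minutes:g} minutes",
                    "ventilation_minutes": settings.ini_ventilation_minutes}),
    )
    return Transition(state, events)


def _clamp(value: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, value))


def ini_apply_answers(state: IniState, answers: QuestionnaireResponse,
                      settings: ProtocolSettings = DEFAULT_SETTINGS,
                      now: float = 0.0) -> Transition:
    """Apply one questionnaire pass and adjust the configuration.

    Returns the successor state: either VENTILATING again (a change was
    made; Q4 will be expected on the next pass) or DONE (no change was
    needed or possible, or the pass cap was reached).
    """
    if state.phase not in (IniPhase.VENTILATING, IniPhase.QUESTIONING):
        raise ProtocolError(f"questionnaire answers not accepted in phase {state.phase.value}")
    if state.expecting_q4 and answers.q4_more_comfortable is None:
        raise ProtocolError("Q4 must be answered after a configuration change")
    if not state.expecting_q4 and answers.q4_more_comfortable is not None:
        raise ProtocolError("Q4 is only asked after a configuration change")

    events: list[EventDraft] = [
        EventDraft(EventKind.QUESTION_ASKED,
                   {"questions": ["Q1", "Q2", "Q3"] + (["Q4"] if state.expecting_q4 else [])}),
    ]

    config = state.config
    frozen = set(state.frozen)
    st = state

    # Q4 "no": revert the most recent change and stop adjusting the families
    # it touched.
    if state.expecting_q4 and answers.q4_more_comfortable is False:
        assert state.prior_config is not None
        config = state.prior_config
        frozen |= set(state.changed_last_pass)
        for fam in state.changed_last_pass:
            st = st._with_streak(fam, "+", 0)
        events.append(EventDraft(
            EventKind.CONFIG_CHANGED,
            {"config": config_payload(config),
             "reason": "reverted: previous configuration was more comfortable",
             "frozen_families": sorted(state.changed_last_pass)}))

    changed: set[str] = set()
    notes: list[str] = []

    def adjust(family: str, current: int, delta: int, lo: int, hi: int,
               limit_note: str) -> int:
        nonlocal st
        if family in frozen or delta == 0:
            return current
        target = _clamp(current + delta, lo, hi)
        if target == current:
            notes.append(limit_note)
            return current
        direction = "+" if delta > 0 else "-"
        prev_dir, count = st.streak(family)
        count = count + 1 if prev_dir == direction else 1
        st = st._with_streak(family, direction, count)
        if count >= settings.ini_family_streak_limit:
            frozen.add(family)
        changed.add(family)
        return target

    step = settings.ipap_step
    ipap_delta = {AirAmount.TOO_LITTLE: step, AirAmount.TOO_MUCH: -step,
                  AirAmount.ENOUGH: 0}[answers.q1_air_amount]
    new_ipap = adjust(FAMILY_PRESSURE, config.ipap, ipap_delta,
                      config.epap + settings.ipap_floor_gap, settings.ini_ipap_cap,
                      "CAP_REACHED" if ipap_delta > 0 else "FLOOR_REACHED")

    rise_delta = {AirSpeed.TOO_FAST: 1, AirSpeed.TOO_SLOW: -1,
                  AirSpeed.ADEQUATE: 0}[answers.q2_air_speed]
    new_rise = adjust(FAMILY_RISE_TIME, config.rise_time_level, rise_delta,
                      config.level_min, config.level_max, "RISE_TIME_SCALE_LIMIT")

    trig_delta = 1 if answers.q3_trigger_exhausting else 0
    new_trigger = adjust(FAMILY_TRIGGER, config.trigger_level, trig_delta,
                         config.level_min, config.level_max, "TRIGGER_SCALE_LIMIT")

    new_config = replace(config, ipap=new_ipap, rise_time_level=new_rise,
                         trigger_level=new_trigger)
    for note in notes:
        events.append(EventDraft(EventKind.RECOMMENDATION, {"note": note}))

    pass_count = state.pass_count + 1
    if changed and pass_count < settings.ini_max_passes:
        events.append(EventDraft(
            EventKind.CONFIG_CHANGED,
            {"config": config_payload(new_config),
             "changed_families": sorted(changed)}))
        events.append(EventDraft(
            EventKind.RECOMMENDATION,
            {"advice": f"ventilate for {settings.ini_ventilation_minutes:g} minutes "
                       "with the adjusted configuration",
             "ventilation_minutes": settings.ini_ventilation_minutes}))
        next_state = replace(
            st, phase=IniPhase.VENTILATING, config=new_config,
            prior_config=config, phase_started_at=now, expecting_q4=True,
            pass_count=pass_count, frozen=frozenset(frozen),
            changed_last_pass=frozenset(changed))
        return Transition(next_state, tuple(events))

    if changed:  # pass cap reached with a final change applied
        events.append(EventDraft(
            EventKind.CONFIG_CHANGED,
            {"config": config_payload(new_config), "changed_families": sorted(changed)}))
    events.append(EventDraft(EventKind.TERMINATED,
                             {"outcome": "DONE", "config": config_payload(new_config)}))
    next_state = replace(
        st, phase=IniPhase.DONE, config=new_config, prior_config=config,
        phase_started_at=now, expecting_q4=False, pass_count=pass_count,
        frozen=frozenset(frozen), changed_last_pass=frozenset(changed))
    return Transition(next_state, tuple(events))
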