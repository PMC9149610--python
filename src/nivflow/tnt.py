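"""Night-time titration of NIV (TNT).

The patient stays overnight. Ventilation is evaluated by blood gas
analyses: once before the night off NIV (baseline) and twice during the
night on NIV. On-NIV samples pass through the same safety gate as in
day-time titration (abort on hypoxemia/acidosis; stop-pause-retry with a
2 mbar IPAP reduction on alkalosis). In the morning the questionnaire and
the PaCO2 trend rule decide among three outcomes:

* option A — adequate ventilation and a satisfied patient: discharge;
* option B — adjustments that do not touch the inspiratory pressure
  (rise time, trigger, oxygen-flow advisory): repeat the night titration;
* option C — the inspiratory pressure has to change: repeat day-time and
  night-time titration.

Nocturnal transcutaneous CO2 values are accepted through the ordinary
blood-gas sample type (source tag) with no separate calibration model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .model import (
    DEFAULT_SETTINGS,
    AirAmount,
    AirSpeed,
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
    TrendVerdict,
    VentilatorConfig,
    config_payload,
)
from .safety import alkalosis_resolved, classify_paco2, evaluate_safety


class TntPhase(str, Enum):
    BASELINE_BGA = "BASELINE_BGA"
    NIGHT_BGA_1 = "NIGHT_BGA_1"
    NIGHT_BGA_2 = "NIGHT_BGA_2"
    PAUSED_ALKALOSIS = "PAUSED_ALKALOSIS"
    MORNING_EVALUATION = "MORNING_EVALUATION"
    ABORTED = "ABORTED"
    COMPLETE = "COMPLETE"


class TntOption(str, Enum):
    A_DISCHARGE = "A_DISCHARGE"
    B_REPEAT_TNT = "B_REPEAT_TNT"
    C_REPEAT_TDT_AND_TNT = "C_REPEAT_TDT_AND_TNT"


class TntReason(str, Enum):
    SATISFIED_AND_ADEQUATE = "SATISFIED_AND_ADEQUATE"
    PACO2_NEEDS_ADJUSTMENT = "PACO2_NEEDS_ADJUSTMENT"
    PATIENT_DISSATISFIED = "PATIENT_DISSATISFIED"
    PRESSURE_CHANGED = "PRESSURE_CHANGED"
    SAFETY_ABORT = "SAFETY_ABORT"


@dataclass(frozen=True)
class TntOutcome:
    """Routing outcome of one titration night."""

    option: TntOption
    final_config: VentilatorConfig
    rationale: tuple[TntReason, ...]

    def __post_init__(self) -> None:
        if (self.option is TntOption.A_DISCHARGE
                and self.rationale != (TntReason.SATISFIED_AND_ADEQUATE,)):
            raise InputError("discharge requires exactly the satisfied-and-adequate rationale")
        if (self.option is TntOption.C_REPEAT_TDT_AND_TNT
                and TntReason.PRESSURE_CHANGED not in self.rationale):
            raise InputError("option C requires a pressure change in its rationale")


@dataclass(frozen=True)
class TntState:
    phase: TntPhase
    config: VentilatorConfig
    samples: tuple[BloodGasSample, ...] = ()
    pause_until: Optional[float] = None
    paused_slot: Optional[TntPhase] = None
    expecting_q4: bool = False

    @property
    def on_niv_samples(self) -> tuple[BloodGasSample, ...]:
        return tuple(s for s in self.samples if s.on_niv)


def tnt_start(record: PatientRecord, config: VentilatorConfig,
              settings: ProtocolSettings = DEFAULT_SETTINGS,
              now: float = 0.0) -> Transition:
    """Start a titration night with the given configuration.

    The measurement plan is one off-NIV baseline sample plus two on-NIV
    samples during the night.
    """
    state = TntState(phase=TntPhase.BASELINE_BGA, config=config)
    events = (
        EventDraft(EventKind.STATE_ENTERED, {"phase": state.phase.value}),
        EventDraft(EventKind.CONFIG_CHANGED, {"config": config_payload(config),
                                              "reason": "night-time titration start"}),
        EventDraft(EventKind.RECOMMENDATION,
                   {"advice": "measurement plan: one blood gas before the night "
                              "without NIV, two during the night with NIV",
                    "planned_off_niv_samples": 1,
                    "planned_on_niv_samples": 2}),
    )
    return Transition(state, events)


_NIGHT_SLOTS = (TntPhase.NIGHT_BGA_1, TntPhase.NIGHT_BGA_2)


def tnt_receive_sample(state: TntState, sample: BloodGasSample,
                       settings: ProtocolSettings = DEFAULT_SETTINGS,
                       now: float = 0.0) -> Transition:
    """Record the next planned sample, applying the safety gate on NIV."""
    if state.phase is TntPhase.BASELINE_BGA:
        if sample.on_niv:
            raise InputError("the baseline sample must be taken without NIV")
        events = (
            EventDraft(EventKind.STATE_ENTERED, {"phase": TntPhase.NIGHT_BGA_1.value}),
            EventDraft(EventKind.RECOMMENDATION,
                       {"advice": "start night ventilation; two on-NIV blood gases follow"}),
        )
        return Transition(replace(state, phase=TntPhase.NIGHT_BGA_1,
                                  samples=state.samples + (sample,)), events)

    if state.phase not in _NIGHT_SLOTS:
        raise ProtocolError(f"sample not accepted in phase {state.phase.value}")
    if not sample.on_niv:
        raise InputError("night samples must be taken under NIV")

    verdict = evaluate_safety(sample, settings)
    events_l: list[EventDraft] = [
        EventDraft(EventKind.SAFETY_VERDICT,
                   {"verdict": verdict.verdict.value,
                    "reasons": sorted(r.value for r in verdict.reasons)}),
    ]
    if verdict.verdict is SafetyAction.ABORT_CALL_PHYSICIAN:
        events_l.append(EventDraft(EventKind.RECOMMENDATION,
                                   {"advice": "abort immediately and call a physician"}))
        events_l.append(EventDraft(EventKind.TERMINATED, {"outcome": "ABORTED"}))
        return Transition(replace(state, phase=TntPhase.ABORTED), tuple(events_l))
    if verdict.verdict is SafetyAction.STOP_AND_PAUSE:
        pause_until = now + settings.pause_minutes
        events_l.append(EventDraft(
            EventKind.RECOMMENDATION,
            {"advice": f"stop ventilation; pause for {settings.pause_minutes:g} minutes, "
                       "then repeat the blood gas",
             "pause_until": pause_until}))
        return Transition(replace(state, phase=TntPhase.PAUSED_ALKALOSIS,
                                  pause_until=pause_until, paused_slot=state.phase),
                          tuple(events_l))

    samples = state.samples + (sample,)
    if state.phase is TntPhase.NIGHT_BGA_1:
        events_l.append(EventDraft(EventKind.STATE_ENTERED,
                                   {"phase": TntPhase.NIGHT_BGA_2.value}))
        return Transition(replace(state, phase=TntPhase.NIGHT_BGA_2, samples=samples),
                          tuple(events_l))
    questions = ["Q1", "Q2", "Q3"] + (["Q4"] if state.expecting_q4 else [])
    events_l.append(EventDraft(EventKind.STATE_ENTERED,
                               {"phase": TntPhase.MORNING_EVALUATION.value}))
    events_l.append(EventDraft(EventKind.QUESTION_ASKED, {"questions": questions}))
    return Transition(replace(state, phase=TntPhase.MORNING_EVALUATION, samples=samples),
                      tuple(events_l))


def tnt_resume_after_pause(state: TntState, recheck: BloodGasSample,
                           patient_approves: bool,
                           settings: ProtocolSettings = DEFAULT_SETTINGS,
                           now: float = 0.0) -> Transition:
    """Nocturnal alkalosis recheck: resume at IPAP - 2 mbar or abort.

    Identical rule to day-time titration; the resumed night returns to the
    sample slot that was interrupted and a fresh sample is expected there.
    """
    if state.phase is not TntPhase.PAUSED_ALKALOSIS:
        raise ProtocolError(f"no alkalosis pause active in phase {state.phase.value}")
    assert state.pause_until is not None and state.paused_slot is not None
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
            EventDraft(EventKind.STATE_ENTERED, {"phase": state.paused_slot.value}),
        )
        return Transition(replace(state, phase=state.paused_slot, config=new_config,
                                  pause_until=None, paused_slot=None, expecting_q4=True),
                          events)

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
    return Transition(replace(state, phase=TntPhase.ABORTED, pause_until=None,
                              paused_slot=None), events)


@dataclass(frozen=True)
class TntEvaluation:
    """Successor state, routing outcome, and events of the morning evaluation."""

    state: TntState
    outcome: TntOutcome
    events: tuple[EventDraft, ...]


def _comfort_adjusted(config: VentilatorConfig,
                      answers: QuestionnaireResponse) -> VentilatorConfig:
    """Rise-time / trigger adjustments (never touches pressures)."""
    rise = config.rise_time_level
    if answers.q2_air_speed is AirSpeed.TOO_FAST:
        rise = min(rise + 1, config.level_max)
    elif answers.q2_air_speed is AirSpeed.TOO_SLOW:
        rise = max(rise - 1, config.level_min)
    trigger = config.trigger_level
    if answers.q3_trigger_exhausting:
        trigger = min(trigger + 1, config.level_max)
    return replace(config, rise_time_level=rise, trigger_level=trigger)


def tnt_evaluate(state: TntState, record: PatientRecord,
                 answers: QuestionnaireResponse,
                 settings: ProtocolSettings = DEFAULT_SETTINGS,
                 now: float = 0.0) -> TntEvaluation:
    """Morning evaluation: map trend verdict and questionnaire to A/B/C.

    The PaCO2 trend is evaluated for the last on-NIV sample against the
    patient's measurements strictly before it (the record is expected to
    contain the night's samples). Option A requires full satisfaction and
    an adequate/improving PaCO2; any required pressure change routes to
    option C; everything else (comfort or advisory-only adjustments)
    routes to option B.
    """
    if state.phase is not TntPhase.MORNING_EVALUATION:
        raise ProtocolError(f"morning evaluation not available in phase {state.phase.value}")
    missing = []
    if not any(not s.on_niv for s in state.samples):
        missing.append("baseline off-NIV sample")
    if len(state.on_niv_samples) < 2:
        missing.append(f"{2 - len(state.on_niv_samples)} on-NIV night sample(s)")
    if missing:
        raise ProtocolError("missing measurements: " + ", ".join(missing))
    if state.expecting_q4 and answers.q4_more_comfortable is None:
        raise ProtocolError("Q4 must be answered: the configuration changed overnight")

    current_sample = state.on_niv_samples[-1]
    prior = [v for t, v in record.paco2_history if t < current_sample.taken_at]
    lowest = min(prior) if prior else None
    previous = prior[-1] if prior else None
    trend = classify_paco2(lowest, previous, current_sample.paco2, settings)

    events: list[EventDraft] = [
        EventDraft(EventKind.ANSWER_RECORDED,
                   {"q1": answers.q1_air_amount.value,
                    "q2": answers.q2_air_speed.value,
                    "q3": answers.q3_trigger_exhausting,
                    "q4": answers.q4_more_comfortable}),
        EventDraft(EventKind.SAFETY_VERDICT,
                   {"paco2_trend": trend.verdict.value,
                    "current_paco2": current_sample.paco2,
                    "lowest_delta": trend.lowest_delta,
                    "previous_delta": trend.previous_delta}),
    ]

    paco2_ok = trend.verdict in (TrendVerdict.ADEQUATE, TrendVerdict.IMPROVING_TREND)
    if paco2_ok and answers.fully_satisfied:
        outcome = TntOutcome(TntOption.A_DISCHARGE, state.config,
                             (TntReason.SATISFIED_AND_ADEQUATE,))
        events.append(EventDraft(EventKind.RECOMMENDATION,
                                 {"advice": "adequate ventilation and satisfied patient: "
                                            "discharge", "option": "a"}))
    elif (answers.q1_air_amount is not AirAmount.ENOUGH
          or trend.verdict is TrendVerdict.NEEDS_ADJUSTMENT):
        # A pressure change is required. Direction: the patient's perception
        # wins when voiced; a purely PaCO2-driven adjustment raises support.
        step = settings.ipap_step
        if answers.q1_air_amount is AirAmount.TOO_MUCH:
            new_ipap = max(state.config.ipap - step,
                           state.config.epap + settings.ipap_floor_gap)
        else:
            new_ipap = min(state.config.ipap + step, settings.tdt_ipap_ceiling)
        rationale = []
        if answers.q1_air_amount is not AirAmount.ENOUGH:
            rationale.append(TntReason.PATIENT_DISSATISFIED)
        if trend.verdict is TrendVerdict.NEEDS_ADJUSTMENT:
            rationale.append(TntReason.PACO2_NEEDS_ADJUSTMENT)
        if new_ipap != state.config.ipap:
            new_config = _comfort_adjusted(state.config.with_ipap(new_ipap), answers)
            outcome = TntOutcome(TntOption.C_REPEAT_TDT_AND_TNT, new_config,
                                 tuple(rationale) + (TntReason.PRESSURE_CHANGED,))
            events.append(EventDraft(
                EventKind.CONFIG_CHANGED, {"config": config_payload(new_config),
                                           "reason": "inspiratory pressure adjustment"}))
            events.append(EventDraft(EventKind.RECOMMENDATION,
                                     {"advice": "repeat day-time and night-time titration",
                                      "option": "c"}))
        else:
            # Pressure at its cap/floor: no different configuration can be
            # emitted, so the night is repeated with comfort adjustments only.
            new_config = _comfort_adjusted(state.config, answers)
            outcome = TntOutcome(TntOption.B_REPEAT_TNT, new_config, tuple(rationale))
            events.append(EventDraft(EventKind.RECOMMENDATION,
                                     {"advice": "pressure already at its limit; repeat "
                                                "night-time titration", "option": "b",
                                      "note": "PRESSURE_LIMIT"}))
    else:
        new_config = _comfort_adjusted(state.config, answers)
        outcome = TntOutcome(TntOption.B_REPEAT_TNT, new_config,
                             (TntReason.PATIENT_DISSATISFIED,))
        if new_config != state.config:
            events.append(EventDraft(
                EventKind.CONFIG_CHANGED, {"config": config_payload(new_config),
                                           "reason": "comfort adjustment"}))
        events.append(EventDraft(EventKind.RECOMMENDATION,
                                 {"advice": "adjust ventilator comfort settings and/or "
                                            "oxygen flow (advisory); repeat night-time "
                                            "titration", "option": "b"}))

    events.append(EventDraft(EventKind.TERMINATED,
                             {"outcome": "COMPLETE", "option": outcome.option.value}))
    return TntEvaluation(replace(state, phase=TntPhase.COMPLETE), outcome, tuple(events))
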