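"""Virtual hypercapnic COPD patients for closed-loop testing.

The physiological model is deliberately linear-with-noise: its job is to
exercise every branch of the decision logic, not respiratory realism.

* PaCO2 falls linearly with the applied pressure support (IPAP - EPAP) and
  with time spent on the ventilator, scaled so that ``co2_sensitivity`` is
  the reduction in mmHg per mbar of support after a full 8-hour night.
* pH is coupled linearly to the PaCO2 *deviation from the patient's chronic
  set point*: a stable chronic hypercapnic patient is renally compensated,
  so at their baseline PaCO2 the pH sits near 7.40, and an acute CO2
  reduction pushes the pH up (post-hypercapnic alkalosis — the very
  condition the titration protocol's pause rule exists for). Setting
  ``ph_reference`` below the baseline models an acutely decompensated
  (acidotic) patient instead.
* SpO2 rises linearly with pressure support while on the ventilator.

Questionnaire answers follow a configurable comfort policy with a private
pressure target; all randomness comes from a single seeded generator per
patient, so identical parameters and seed give an identical response
stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .model import (
    DEFAULT_SETTINGS,
    AirAmount,
    AirSpeed,
    BloodGasSample,
    Disposition,
    InputError,
    PatientRecord,
    PatientStatus,
    ProtocolSettings,
    QuestionnaireResponse,
    VentilatorConfig,
)


class ComfortPolicy(str, Enum):
    ALWAYS_SATISFIED = "ALWAYS_SATISFIED"
    WANTS_MORE_PRESSURE = "WANTS_MORE_PRESSURE"
    WANTS_LESS_PRESSURE = "WANTS_LESS_PRESSURE"
    RANDOM = "RANDOM"


class ApprovalPolicy(str, Enum):
    ALWAYS = "ALWAYS"
    NEVER = "NEVER"
    RANDOM = "RANDOM"


@dataclass(frozen=True)
class VirtualPatientParams:
    """Parameters of the linear virtual-patient model.

    ``co2_sensitivity`` is in mmHg per mbar of pressure support per 8-hour
    night; ``ph_coupling`` in pH units per mmHg of PaCO2 deviation from
    ``ph_reference`` (non-positive); ``spo2_gain`` in percent per mbar of
    support. ``ph_reference`` defaults to the chronic baseline PaCO2
    (compensated patient); ``ipap_target`` is the private comfort target
    consulted by the pressure-seeking policies.
    """

    patient_id: str = "VP"
    baseline_paco2: float = 55.0
    co2_sensitivity: float = 0.5
    ph_coupling: float = -0.008
    ph_reference: Optional[float] = None
    baseline_spo2: float = 90.0
    spo2_gain: float = 0.3
    noise_sd_paco2: float = 1.0
    noise_sd_ph: float = 0.0
    comfort_policy: ComfortPolicy = ComfortPolicy.ALWAYS_SATISFIED
    approval_policy: ApprovalPolicy = ApprovalPolicy.ALWAYS
    ipap_target: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.co2_sensitivity < 0 or self.spo2_gain < 0:
            raise InputError("gains must be non-negative")
        if self.noise_sd_paco2 < 0 or self.noise_sd_ph < 0:
            raise InputError("noise standard deviations must be non-negative")
        if self.ph_coupling > 0:
            raise InputError("ph_coupling must be non-positive (CO2 retention lowers pH)")

    @property
    def ph_setpoint(self) -> float:
        return self.baseline_paco2 if self.ph_reference is None else self.ph_reference


class VirtualPatient:
    """Stateful wrapper: one seeded random stream per patient."""

    def __init__(self, params: VirtualPatientParams):
        self.params = params
        self.rng = np.random.default_rng(params.rng_seed)

    # -- physiology --------------------------------------------------------

    def simulate_bga(self, config: VentilatorConfig, on_niv: bool,
                     hours_on_niv: float, at: float = 0.0) -> BloodGasSample:
        """Draw one blood-gas sample under the linear model."""
        p = self.params
        support = config.ipap - config.epap
        paco2 = p.baseline_paco2
        if on_niv:
            paco2 -= p.co2_sensitivity * support * (hours_on_niv / 8.0)
        if p.noise_sd_paco2 > 0:
            paco2 += self.rng.normal(0.0, p.noise_sd_paco2)
        paco2 = max(paco2, 15.0)

        ph = 7.40 + p.ph_coupling * (paco2 - p.ph_setpoint)
        if p.noise_sd_ph > 0:
            ph += self.rng.normal(0.0, p.noise_sd_ph)
        ph = min(max(ph, 6.5), 8.0)

        spo2 = p.baseline_spo2 + (p.spo2_gain * support if on_niv else 0.0)
        spo2 = min(max(spo2, 1.0), 100.0)
        return BloodGasSample(ph=round(ph, 4), paco2=round(paco2, 3),
                              spo2=round(spo2, 2), taken_at=at, on_niv=on_niv)

    # -- behaviour ---------------------------------------------------------

    def _q1(self, config: VentilatorConfig) -> AirAmount:
        p = self.params
        if p.comfort_policy is ComfortPolicy.ALWAYS_SATISFIED:
            return AirAmount.ENOUGH
        if p.comfort_policy is ComfortPolicy.WANTS_MORE_PRESSURE:
            return AirAmount.TOO_LITTLE if config.ipap < p.ipap_target else AirAmount.ENOUGH
        if p.comfort_policy is ComfortPolicy.WANTS_LESS_PRESSURE:
            return AirAmount.TOO_MUCH if config.ipap > p.ipap_target else AirAmount.ENOUGH
        return AirAmount(self.rng.choice([a.value for a in AirAmount]))

    def answer_questionnaire(self, config: VentilatorConfig,
                             previous_config: Optional[VentilatorConfig] = None,
                             include_q4: bool = False) -> QuestionnaireResponse:
        """Answer Q1-Q3 (and Q4 when asked) per the comfort policy.

        Q4 is "yes" iff the current IPAP is at least as close to the private
        pressure target as the previous one.
        """
        p = self.params
        q1 = self._q1(config)
        if p.comfort_policy is ComfortPolicy.RANDOM:
            q2 = AirSpeed(self.rng.choice([a.value for a in AirSpeed]))
            q3 = bool(self.rng.random() < 0.25)
        else:
            q2, q3 = AirSpeed.ADEQUATE, False
        q4: Optional[bool] = None
        if include_q4:
            if previous_config is None:
                q4 = True
            else:
                q4 = (abs(config.ipap - p.ipap_target)
                      <= abs(previous_config.ipap - p.ipap_target))
        return QuestionnaireResponse(q1_air_amount=q1, q2_air_speed=q2,
                                     q3_trigger_exhausting=q3, q4_more_comfortable=q4)

    def approves(self) -> bool:
        p = self.params
        if p.approval_policy is ApprovalPolicy.ALWAYS:
            return True
        if p.approval_policy is ApprovalPolicy.NEVER:
            return False
        return bool(self.rng.random() < 0.5)


# ---------------------------------------------------------------------------
# Closed loop
# ---------------------------------------------------------------------------

class LivelockError(RuntimeError):
    """The closed-loop driver detected an unbounded intra-night loop."""


def run_closed_loop(params: VirtualPatientParams,
                    settings: ProtocolSettings = DEFAULT_SETTINGS,
                    record: Optional[PatientRecord] = None,
                    max_nights: int = 20,
                    max_steps_per_night: int = 60):
    """Drive a full session against a virtual patient.

    Returns the final :class:`~nivflow.engine.Session`. The loop stops when
    the session reaches a terminal disposition or ``max_nights`` morning
    evaluations have occurred.
    """
    from .engine import (AnswersInput, BgaInput, ClockAdvance, Session,
                         advance, new_session)
    from .ini import IniPhase, IniState
    from .tdt import TdtPhase, TdtState
    from .tnt import TntPhase, TntState

    patient = VirtualPatient(params)
    if record is None:
        record = PatientRecord(patient_id=params.patient_id, status=PatientStatus.NEW)
    session = new_session(record, settings, session_id=f"vp-{params.patient_id}")

    night_start: Optional[float] = None
    steps_this_night = 0

    while session.disposition is Disposition.IN_PROGRESS:
        if session.nights_completed >= max_nights:
            break
        steps_this_night += 1
        if steps_this_night > max_steps_per_night:
            raise LivelockError(
                f"more than {max_steps_per_night} engine steps within one night")
        st = session.process_state
        nights_before = session.nights_completed

        if isinstance(st, IniState):
            if session.clock < st.phase_started_at + settings.ini_ventilation_minutes:
                inp = ClockAdvance(st.phase_started_at
                                   + settings.ini_ventilation_minutes - session.clock)
            else:
                answers = patient.answer_questionnaire(
                    st.config, st.prior_config, include_q4=st.expecting_q4)
                inp = AnswersInput(answers=answers,
                                   approves_another_cycle=patient.approves())

        elif isinstance(st, TdtState):
            if st.phase is TdtPhase.VENTILATING and session.clock < st.bga_due_at:
                inp = ClockAdvance(st.bga_due_at - session.clock)
            elif st.phase in (TdtPhase.VENTILATING, TdtPhase.AWAITING_BGA):
                minutes_on = session.clock - st.cycle_started_at
                sample = patient.simulate_bga(st.config, on_niv=True,
                                              hours_on_niv=minutes_on / 60.0,
                                              at=session.clock)
                inp = BgaInput(sample=sample)
            elif st.phase is TdtPhase.PAUSED_ALKALOSIS:
                if session.clock < st.pause_until:
                    inp = ClockAdvance(st.pause_until - session.clock)
                else:
                    recheck = patient.simulate_bga(st.config, on_niv=False,
                                                   hours_on_niv=0.0, at=session.clock)
                    inp = BgaInput(sample=recheck, patient_approves=patient.approves())
            else:  # QUESTIONING
                answers = patient.answer_questionnaire(st.config)
                inp = AnswersInput(answers=answers,
                                   approves_another_cycle=patient.approves())

        elif isinstance(st, TntState):
            if st.phase is TntPhase.BASELINE_BGA:
                sample = patient.simulate_bga(st.config, on_niv=False,
                                              hours_on_niv=0.0, at=session.clock)
                inp = BgaInput(sample=sample)
                night_start = session.clock
            elif st.phase in (TntPhase.NIGHT_BGA_1, TntPhase.NIGHT_BGA_2):
                assert night_start is not None
                due = night_start + (240.0 if st.phase is TntPhase.NIGHT_BGA_1 else 480.0)
                if session.clock < due:
                    inp = ClockAdvance(due - session.clock)
                else:
                    hours = (session.clock - night_start) / 60.0
                    sample = patient.simulate_bga(st.config, on_niv=True,
                                                  hours_on_niv=hours, at=session.clock)
                    inp = BgaInput(sample=sample)
            elif st.phase is TntPhase.PAUSED_ALKALOSIS:
                if session.clock < st.pause_until:
                    inp = ClockAdvance(st.pause_until - session.clock)
                else:
                    recheck = patient.simulate_bga(st.config, on_niv=False,
                                                   hours_on_niv=0.0, at=session.clock)
                    inp = BgaInput(sample=recheck, patient_approves=patient.approves())
            else:  # MORNING_EVALUATION
                answers = patient.answer_questionnaire(st.config,
                                                       include_q4=st.expecting_q4)
                inp = AnswersInput(answers=answers)
        else:
            raise LivelockError("no active process while in progress")

        session = advance(session, inp)
        if session.nights_completed > nights_before:
            steps_this_night = 0

    return session


# ---------------------------------------------------------------------------
# Cohort files
# ---------------------------------------------------------------------------

def load_cohort(path: Union[str, Path]) -> list[VirtualPatientParams]:
    """Read a cohort specification (JSON list of parameter objects)."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise InputError("cohort file must contain a JSON list")
    cohort = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict):
            raise InputError(f"cohort entry {i} is not an object")
        if "comfort_policy" in entry:
            entry = {**entry, "comfort_policy": ComfortPolicy(entry["comfort_policy"])}
        if "approval_policy" in entry:
            entry = {**entry, "approval_policy": ApprovalPolicy(entry["approval_policy"])}
        cohort.append(VirtualPatientParams(**entry))
    return cohort
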