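"""Core domain types for the NIV titration workflow engine.

Everything here is an immutable value object: the state machines in
:mod:`nivflow.ini`, :mod:`nivflow.tdt` and :mod:`nivflow.tnt` are pure step
functions over these types, which is what makes deterministic replay of a
session from its event log possible.

Units follow common respiratory-medicine convention: pressures in mbar,
PaCO2 in mmHg, SpO2 in percent, pH unitless. The session clock is an
abstract monotone counter in minutes since session start; binding it to
wall-clock time is the caller's (or the CLI's) job.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Mapping, Optional


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class NivFlowError(Exception):
    """Base class for all errors raised by the engine."""


class InputError(NivFlowError):
    """A supplied value is outside its physiologic/structural validity range."""


class ProtocolError(NivFlowError):
    """An operation was attempted in a phase or at a time where it is not allowed."""


class RoutingError(NivFlowError):
    """A patient was routed into a process their status does not admit."""


class SessionFormatError(NivFlowError):
    """A persisted session document could not be parsed."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Mode(str, Enum):
    """Ventilation mode. Only pressure-support ventilation is modelled."""

    PRESSURE_SUPPORT = "PRESSURE_SUPPORT"


class AirAmount(str, Enum):
    """Answer alphabet of Q1 (perceived inspiratory pressure)."""

    ENOUGH = "ENOUGH"
    TOO_MUCH = "TOO_MUCH"
    TOO_LITTLE = "TOO_LITTLE"


class AirSpeed(str, Enum):
    """Answer alphabet of Q2 (perceived rise time)."""

    ADEQUATE = "ADEQUATE"
    TOO_FAST = "TOO_FAST"
    TOO_SLOW = "TOO_SLOW"


class PatientStatus(str, Enum):
    NEW = "NEW"
    RECURRING = "RECURRING"


class ProcessName(str, Enum):
    INI = "INI"
    TDT = "TDT"
    TNT = "TNT"
    ENGINE = "ENGINE"


class EventKind(str, Enum):
    STATE_ENTERED = "STATE_ENTERED"
    CONFIG_CHANGED = "CONFIG_CHANGED"
    MEASUREMENT_RECORDED = "MEASUREMENT_RECORDED"
    QUESTION_ASKED = "QUESTION_ASKED"
    ANSWER_RECORDED = "ANSWER_RECORDED"
    SAFETY_VERDICT = "SAFETY_VERDICT"
    RECOMMENDATION = "RECOMMENDATION"
    TERMINATED = "TERMINATED"
    CLOCK_ADVANCED = "CLOCK_ADVANCED"


class SafetyReason(str, Enum):
    HYPOXEMIA = "HYPOXEMIA"
    ACIDOSIS = "ACIDOSIS"
    ALKALOSIS = "ALKALOSIS"


class SafetyAction(str, Enum):
    CONTINUE = "CONTINUE"
    ABORT_CALL_PHYSICIAN = "ABORT_CALL_PHYSICIAN"
    STOP_AND_PAUSE = "STOP_AND_PAUSE"


class TrendVerdict(str, Enum):
    ADEQUATE = "ADEQUATE"
    IMPROVING_TREND = "IMPROVING_TREND"
    NEEDS_ADJUSTMENT = "NEEDS_ADJUSTMENT"


class Disposition(str, Enum):
    IN_PROGRESS = "IN_PROGRESS"
    DISCHARGED = "DISCHARGED"
    ABORTED_PHYSICIAN = "ABORTED_PHYSICIAN"


# Verbatim questionnaire items driving the comfort-based adjustments.
QUESTION_TEXT: Mapping[str, str] = {
    "Q1": "How much air do you get during ventilation? [enough/too much/too little]",
    "Q2": "How fast does the ventilator deliver the air? [adequately/too fast/too slow]",
    "Q3": "Is it exhausting to initiate a new breath? [yes/no]",
    "Q4": "Is the ventilation now more comfortable than in the previous configuration? [yes/no]",
}


# ---------------------------------------------------------------------------
# Protocol settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolSettings:
    """Tunable protocol constants.

    The thresholds default to the published protocol values; overriding them
    produces a nonconforming engine and the CLI warns prominently when asked
    to do so. Step sizes and caps that the protocol leaves open are explicit
    here so that every rule in the processes is parameter-free.

    Attributes
    ----------
    ipap_step:
        Pressure increment/decrement for all questionnaire-driven IPAP
        adjustments (mbar).
    ini_ipap_cap:
        Hard ceiling on IPAP during first initiation (mbar).
    tdt_ipap_ceiling:
        Ceiling on IPAP during day/night titration (mbar). The published
        20 mbar cap is stated for initiation only.
    ipap_floor_gap:
        Minimum IPAP-EPAP difference maintained when lowering IPAP (mbar).
    level_min, level_max:
        Bounds of the ordinal rise-time / trigger-sensitivity scales.
    ini_ventilation_minutes:
        Advisory ventilation period after each initiation configuration.
    ini_max_passes:
        Global cap on questionnaire passes during initiation (termination
        guarantee for unsatisfiable answer streams).
    ini_family_streak_limit:
        Consecutive same-direction adjustments of one parameter family
        before that family is frozen.
    tdt_cycle_minutes, tdt_bga_minute:
        Day-time titration cycle length and the offset of the blood gas
        within it.
    tdt_max_cycles:
        Maximum number of ventilation-and-parameter-change cycles.
    pause_minutes:
        Length of the stop-ventilation pause after alkalosis.
    spo2_floor, ph_acidosis, ph_alkalosis:
        Safety thresholds (abort below/above, strict inequalities).
    paco2_adequate, paco2_upper:
        PaCO2 interval bounds for the night-time trend evaluation (mmHg);
        values at or below ``paco2_adequate`` count as adequate, values
        above ``paco2_upper`` always need adjustment.
    min_improvement:
        Improvement over the patient's lowest prior PaCO2 that the trend
        criterion requires (strictly more than this many mmHg).
    """

    ipap_step: int = 2
    ini_ipap_cap: int = 20
    tdt_ipap_ceiling: int = 30
    ipap_floor_gap: int = 2
    level_min: int = 1
    level_max: int = 5
    ini_ventilation_minutes: float = 5.0
    ini_max_passes: int = 10
    ini_family_streak_limit: int = 3
    tdt_cycle_minutes: float = 20.0
    tdt_bga_minute: float = 15.0
    tdt_max_cycles: int = 3
    pause_minutes: float = 30.0
    spo2_floor: float = 85.0
    ph_acidosis: float = 7.35
    ph_alkalosis: float = 7.55
    paco2_adequate: float = 45.0
    paco2_upper: float = 50.0
    min_improvement: float = 5.0

    def nonconformances(self) -> list[str]:
        """Names of threshold fields that differ from the published protocol."""
        reference = ProtocolSettings()
        guarded = (
            "spo2_floor", "ph_acidosis", "ph_alkalosis",
            "paco2_adequate", "paco2_upper", "min_improvement",
            "ini_ipap_cap", "ipap_step", "tdt_max_cycles",
            "pause_minutes", "tdt_cycle_minutes", "tdt_bga_minute",
        )
        return [f for f in guarded if getattr(self, f) != getattr(reference, f)]


DEFAULT_SETTINGS = ProtocolSettings()


# ---------------------------------------------------------------------------
# Value types
# ---------------------------------------------------------------------------

def _require_int(name: str, value: Any) -> None:
    if isinstance(value, bool) or not isinstance(value, int):
        raise InputError(f"{name} must be an integer (got {value!r})")


@dataclass(frozen=True)
class VentilatorConfig:
    """The respirator setting vector the engine titrates.

    ``rise_time_level`` and ``trigger_level`` are ordinal comfort levels on a
    configurable 1..5 scale (the protocol gives no physical units for them);
    a higher trigger level means a more sensitive trigger.
    """

    mode: Mode = Mode.PRESSURE_SUPPORT
    ipap: int = 16
    epap: int = 5
    backup_rate: int = 18
    rise_time_level: int = 3
    trigger_level: int = 3
    level_min: int = 1
    level_max: int = 5

    def __post_init__(self) -> None:
        for name in ("ipap", "epap", "backup_rate", "rise_time_level",
                     "trigger_level", "level_min", "level_max"):
            _require_int(name, getattr(self, name))
        if self.ipap <= 0 or self.epap <= 0 or self.backup_rate <= 0:
            raise InputError("ipap, epap and backup_rate must be strictly positive")
        if self.ipap <= self.epap:
            raise InputError(
                f"ipap ({self.ipap}) must be strictly greater than epap ({self.epap})")
        for name in ("rise_time_level", "trigger_level"):
            v = getattr(self, name)
            if not (self.level_min <= v <= self.level_max):
                raise InputError(
                    f"{name}={v} outside ordinal scale [{self.level_min}, {self.level_max}]")

    def with_ipap(self, ipap: int) -> "VentilatorConfig":
        return replace(self, ipap=ipap)


def default_initial_config(settings: ProtocolSettings = DEFAULT_SETTINGS) -> VentilatorConfig:
    """Best-practice starting configuration feasible for most patients.

    Pressure-support mode, IPAP 16 mbar, EPAP 5 mbar, backup rate
    18 breaths/min; rise-time and trigger levels start mid-scale.
    """
    mid = (settings.level_min + settings.level_max) // 2
    return VentilatorConfig(
        mode=Mode.PRESSURE_SUPPORT, ipap=16, epap=5, backup_rate=18,
        rise_time_level=mid, trigger_level=mid,
        level_min=settings.level_min, level_max=settings.level_max,
    )


@dataclass(frozen=True)
class BloodGasSample:
    """A pH / PaCO2 / SpO2 measurement on the session clock.

    ``on_niv`` records whether the sample was drawn under ventilation;
    transcutaneous CO2 values used nocturnally are accepted through the same
    type (``source`` tag), with no separate calibration model.
    """

    ph: float
    paco2: float
    spo2: float
    taken_at: float = 0.0
    on_niv: bool = True
    source: str = "arterial"

    def __post_init__(self) -> None:
        if not (6.5 <= self.ph <= 8.0):
            raise InputError(f"pH {self.ph} outside plausibility gate [6.5, 8.0]")
        if not (0.0 < self.spo2 <= 100.0):
            raise InputError(f"SpO2 {self.spo2} outside (0, 100]")
        if self.paco2 <= 0.0:
            raise InputError(f"PaCO2 {self.paco2} must be positive")
        if self.taken_at < 0.0:
            raise InputError("taken_at must be non-negative session minutes")


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Answers to the 4-item comfort questionnaire.

    Q4 compares the current configuration with the previous one and is only
    meaningful (and only accepted by the processes) after a configuration
    change.
    """

    q1_air_amount: AirAmount
    q2_air_speed: AirSpeed = AirSpeed.ADEQUATE
    q3_trigger_exhausting: bool = False
    q4_more_comfortable: Optional[bool] = None

    @property
    def fully_satisfied(self) -> bool:
        return (self.q1_air_amount is AirAmount.ENOUGH
                and self.q2_air_speed is AirSpeed.ADEQUATE
                and not self.q3_trigger_exhausting)


@dataclass(frozen=True)
class PatientRecord:
    """Identity, routing status and PaCO2 measurement history of a patient."""

    patient_id: str
    status: PatientStatus = PatientStatus.NEW
    paco2_history: tuple[tuple[float, float], ...] = ()
    stored_night_config: Optional[VentilatorConfig] = None

    def __post_init__(self) -> None:
        if self.status is PatientStatus.RECURRING and self.stored_night_config is None:
            raise InputError("a recurring patient must carry a stored night configuration")
        times = [t for t, _ in self.paco2_history]
        if any(b < a for a, b in zip(times, times[1:])):
            raise InputError("paco2_history timestamps must be non-decreasing")

    @property
    def lowest_paco2(self) -> Optional[float]:
        """Minimum PaCO2 over the whole history, or None if empty."""
        if not self.paco2_history:
            return None
        return min(v for _, v in self.paco2_history)

    @property
    def latest_paco2(self) -> Optional[float]:
        if not self.paco2_history:
            return None
        return self.paco2_history[-1][1]

    @property
    def previous_paco2(self) -> Optional[float]:
        """Second-most-recent PaCO2 entry, or None."""
        if len(self.paco2_history) < 2:
            return None
        return self.paco2_history[-2][1]


def update_paco2_history(record: PatientRecord, sample: BloodGasSample) -> PatientRecord:
    """Return a new record with ``sample`` appended to the PaCO2 history.

    The original record is not modified. Samples older than the newest
    history entry are rejected (session-clock monotonicity).
    """
    if record.paco2_history and sample.taken_at < record.paco2_history[-1][0]:
        raise InputError(
            f"sample at t={sample.taken_at} precedes newest history entry "
            f"at t={record.paco2_history[-1][0]}")
    return replace(record,
                   paco2_history=record.paco2_history + ((sample.taken_at, sample.paco2),))


@dataclass(frozen=True)
class SafetyVerdict:
    """Outcome of the blood-gas safety gate."""

    verdict: SafetyAction
    reasons: frozenset[SafetyReason] = frozenset()

    def __post_init__(self) -> None:
        abort = bool(self.reasons & {SafetyReason.HYPOXEMIA, SafetyReason.ACIDOSIS})
        if abort != (self.verdict is SafetyAction.ABORT_CALL_PHYSICIAN):
            raise InputError("abort verdict must coincide with hypoxemia/acidosis reasons")
        if (self.verdict is SafetyAction.STOP_AND_PAUSE
                and self.reasons != frozenset({SafetyReason.ALKALOSIS})):
            raise InputError("stop-and-pause requires exactly the alkalosis reason")
        if self.verdict is SafetyAction.CONTINUE and self.reasons:
            raise InputError("continue verdict must carry no reasons")


@dataclass(frozen=True)
class ProcessEvent:
    """One entry of the append-only audit trail."""

    seq: int
    at: float
    process: ProcessName
    kind: EventKind
    payload: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class EventDraft:
    """An event emitted by a process step before the engine stamps seq/at."""

    kind: EventKind
    payload: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class Transition:
    """Result of a process step: the successor state plus emitted events."""

    state: Any
    events: tuple[EventDraft, ...] = ()


def config_payload(config: VentilatorConfig) -> dict[str, Any]:
    """JSON-native snapshot of a configuration for event payloads."""
    return {
        "mode": config.mode.value,
        "ipap": config.ipap,
        "epap": config.epap,
        "backup_rate": config.backup_rate,
        "rise_time_level": config.rise_time_level,
        "trigger_level": config.trigger_level,
    }
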