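"""Blood-gas safety gates and the PaCO2 adequacy/trend criterion.

These are the pure rules shared by the day-time and night-time titration
processes:

* abort and call a physician on hypoxemia (SpO2 < 85 %) or acidosis
  (pH < 7.35);
* stop ventilation and pause on alkalosis (pH > 7.55), resuming once
  pH <= 7.55 again;
* judge night-time ventilation adequacy from the current PaCO2: at or below
  45 mmHg it is adequate, above 50 mmHg it needs adjustment, and inside
  (45, 50] it counts as an improving trend only if it is more than 5 mmHg
  below the patient's lowest prior value *and* below the previous
  measurement.

All inequalities are strict exactly as printed in the protocol; the
boundary values themselves therefore do not trigger the rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    DEFAULT_SETTINGS,
    BloodGasSample,
    PatientRecord,
    ProtocolError,
    ProtocolSettings,
    SafetyAction,
    SafetyReason,
    SafetyVerdict,
    TrendVerdict,
)


def evaluate_safety(sample: BloodGasSample,
                    settings: ProtocolSettings = DEFAULT_SETTINGS) -> SafetyVerdict:
    """Apply the blood-gas safety gate to one sample.

    Hypoxemia or acidosis yields an immediate abort with advice to call a
    physician; alkalosis alone yields stop-and-pause. An abort reason
    dominates a co-occurring alkalosis flag, but all fired reasons are
    reported.
    """
    reasons: set[SafetyReason] = set()
    if sample.spo2 < settings.spo2_floor:
        reasons.add(SafetyReason.HYPOXEMIA)
    if sample.ph < settings.ph_acidosis:
        reasons.add(SafetyReason.ACIDOSIS)
    if sample.ph > settings.ph_alkalosis:
        reasons.add(SafetyReason.ALKALOSIS)

    if reasons & {SafetyReason.HYPOXEMIA, SafetyReason.ACIDOSIS}:
        verdict = SafetyAction.ABORT_CALL_PHYSICIAN
    elif reasons:
        verdict = SafetyAction.STOP_AND_PAUSE
    else:
        verdict = SafetyAction.CONTINUE
    return SafetyVerdict(verdict=verdict, reasons=frozenset(reasons))


def alkalosis_resolved(recheck: BloodGasSample,
                       settings: ProtocolSettings = DEFAULT_SETTINGS) -> bool:
    """True iff the alkalosis has disappeared on the recheck (pH <= 7.55).

    The bound is inclusive: a recheck pH of exactly 7.55 counts as resolved.
    """
    return recheck.ph <= settings.ph_alkalosis


@dataclass(frozen=True)
class Paco2Verdict:
    """Outcome of the PaCO2 adequacy/trend evaluation.

    ``lowest_delta`` and ``previous_delta`` are signed differences
    (current minus reference, mmHg); negative values mean improvement.
    They are None when no reference was needed or available.
    """

    verdict: TrendVerdict
    lowest_delta: Optional[float] = None
    previous_delta: Optional[float] = None


def classify_paco2(lowest: Optional[float], previous: Optional[float],
                   current: float,
                   settings: ProtocolSettings = DEFAULT_SETTINGS) -> Paco2Verdict:
    """Classify a current PaCO2 against explicit reference values.

    ``lowest`` is the patient's lowest prior PaCO2 and ``previous`` the most
    recent prior measurement. Outside the evaluation interval the references
    are not consulted: at or below 45 mmHg the result is ADEQUATE, above
    50 mmHg it is NEEDS_ADJUSTMENT. Inside (45, 50] the improving-trend
    criterion requires improvement of strictly more than 5 mmHg versus
    ``lowest`` and any strict improvement versus ``previous``.
    """
    def deltas() -> tuple[Optional[float], Optional[float]]:
        ld = None if lowest is None else current - lowest
        pd = None if previous is None else current - previous
        return ld, pd

    if current <= settings.paco2_adequate:
        ld, pd = deltas()
        return Paco2Verdict(TrendVerdict.ADEQUATE, ld, pd)
    if current > settings.paco2_upper:
        ld, pd = deltas()
        return Paco2Verdict(TrendVerdict.NEEDS_ADJUSTMENT, ld, pd)

    if lowest is None or previous is None:
        raise ProtocolError(
            "PaCO2 trend evaluation inside the interval requires at least one "
            "prior measurement; record a baseline first")
    improving = (lowest - current) > settings.min_improvement and current < previous
    verdict = TrendVerdict.IMPROVING_TREND if improving else TrendVerdict.NEEDS_ADJUSTMENT
    return Paco2Verdict(verdict, current - lowest, current - previous)


def evaluate_paco2_trend(record: PatientRecord, current: float,
                         settings: ProtocolSettings = DEFAULT_SETTINGS) -> Paco2Verdict:
    """Classify ``current`` against a record of *prior* measurements.

    The record's history must not yet contain the current value: the lowest
    reference is the minimum over the history and the previous reference its
    last entry.
    """
    previous = record.latest_paco2
    return classify_paco2(record.lowest_paco2, previous, current, settings)


def evaluate_latest_paco2(record: PatientRecord,
                          settings: ProtocolSettings = DEFAULT_SETTINGS) -> Paco2Verdict:
    """Classify the record's newest entry against everything before it."""
    if not record.paco2_history:
        raise ProtocolError("record has no PaCO2 measurements")
    current = record.paco2_history[-1][1]
    prior = [v for _, v in record.paco2_history[:-1]]
    lowest = min(prior) if prior else None
    previous = prior[-1] if prior else None
    return classify_paco2(lowest, previous, current, settings)
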