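# nivflow

An executable, auditable decision- and workflow-support engine for
initiating and controlling long-term **non-invasive ventilation (NIV)** in
stable hypercapnic COPD patients. It is aimed at clinical-informatics
researchers and engineers who need the titration protocol as a testable
state machine rather than a flowchart: every rule is a pure function, every
session is an append-only event log, and a virtual-patient simulator closes
the loop so the whole workflow can be exercised with no clinical data.

## The protocol

Three interlocking processes are routed by patient status — every new
patient passes through all three, a recurring patient enters the night
titration directly:

```
new patient:        INI ─→ TDT ─→ TNT ──(a)─→ discharge
                                   │ └──(b)──→ TNT again
recurring patient:  ───────────→ TNT ───(c)──→ TDT ─→ TNT
```

* **INI — first initiation.** Start at the best-practice configuration
  (pressure-support mode, IPAP 16 mbar, EPAP 5 mbar, backup rate 18/min),
  ventilate 5 min, then optimise inspiratory pressure, rise time and
  trigger sensitivity from a 4-item comfort questionnaire, with IPAP capped
  at 20 mbar during initiation.
* **TDT — day-time titration.** 20-minute ventilation cycles with a blood
  gas at minute 15. Safety gates: abort and call a physician on hypoxemia
  (SpO₂ < 85 %) or acidosis (pH < 7.35); on alkalosis (pH > 7.55) stop for
  30 min and restart with IPAP − 2 mbar if the recheck shows pH ≤ 7.55 and
  the patient approves. The Q1 answer moves IPAP ± 2 mbar, at most three
  adjustment cycles.
* **TNT — night-time titration.** One blood gas off NIV before the night,
  two on NIV during it (same safety gates). In the morning, the PaCO₂
  trend rule decides adequacy: PaCO₂ ≤ 45 mmHg is adequate, > 50 mmHg needs
  adjustment, and a value in (45, 50] counts as an improving trend only if
  it is **more than 5 mmHg below the patient's lowest prior value** and
  below the previous measurement. Adequate + satisfied → discharge (a);
  comfort-only adjustments → repeat the night (b); any inspiratory-pressure
  change → repeat day and night titration (c).

## Worked example

`examples/full_stay.py` drives a complete stay for a virtual patient whose
PaCO₂ falls 1 mmHg per mbar of pressure support over a full night:

```
disposition      : DISCHARGED
titration nights : 1
night config     : IPAP 16 / EPAP 5 mbar
events logged    : 42

blood gases recorded (pH / PaCO2 mmHg / SpO2 %, on or off NIV):
  t=    20 min  on NIV   pH 7.403  PaCO2  54.7  SpO2 93.3
  t=    20 min  off NIV  pH 7.400  PaCO2  55.0  SpO2 90.0
  t=   260 min  on NIV   pH 7.444  PaCO2  49.5  SpO2 93.3
  t=   500 min  on NIV   pH 7.488  PaCO2  44.0  SpO2 93.3
```

The day-time blood gas at minute 20 of the session (minute 15 of the
cycle) passes the safety gate, the patient reports enough air, and the
night at 11 mbar of support drives the PaCO₂ from the 55 mmHg baseline to
44 mmHg — at or below the 45 mmHg adequacy bound — so the engine discharges
the patient after a single titration night with the tested configuration
stored for follow-up. The other scripts in `examples/` demonstrate the
safety and trend rules on hand-picked samples, the initiation pressure
loop, and a small mixed cohort.

A thin CLI wraps the same library (`nivflow start / resume / batch /
replay / validate-session`); sessions persist as diff-able JSON documents
and `nivflow replay` verifies that a session's recorded inputs reproduce
its event log byte for byte.

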