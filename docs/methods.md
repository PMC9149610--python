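# Methods

## Model of the workflow

The engine treats the titration protocol as three communicating finite
state machines (initiation INI, day-time titration TDT, night-time
titration TNT) under a router. All state is immutable; each process step is
a pure function `(state, input, now) -> (state, events)` and the engine
`advance(session, input)` is a pure step function over the whole session.
This is what makes the two global contracts testable:

* **Replay determinism.** Every external input (clock advance, blood gas,
  questionnaire answers with approvals) is recorded in the append-only
  event log; re-applying the extracted inputs to a fresh session
  reproduces the final state and event sequence byte-for-byte under the
  JSON serialization.
* **Routing conservation.** The sequence of processes started in any
  trajectory lies in the prefix-closure of
  `INI·TDT·TNT·(TNT | TDT·TNT)*` for new patients and
  `TNT·(TNT | TDT·TNT)*` for recurring ones.

Time is an abstract monotone session clock in minutes. Ventilation-phase
durations (5 min after an initiation change, the 20-minute day-time cycle
with its minute-15 blood gas) are advisory events; only the 30-minute
alkalosis pause is enforced — no transition out of the paused state is
possible before it elapses. Binding the clock to wall time is the CLI's
job, which keeps every timed rule testable without sleeping.

## Protocol constants and thresholds

All constants live in one frozen `ProtocolSettings` object. Thresholds
default to the published protocol values and overriding them via the CLI
prints a prominent nonconformance warning.

| parameter | default | meaning |
|---|---|---|
| `spo2_floor` | 85 % | hypoxemia abort, strict `<` |
| `ph_acidosis` | 7.35 | acidosis abort, strict `<` |
| `ph_alkalosis` | 7.55 | alkalosis pause, strict `>`; resolution is inclusive `≤` |
| `paco2_adequate` | 45 mmHg | at or below: adequate night ventilation |
| `paco2_upper` | 50 mmHg | above: always needs adjustment |
| `min_improvement` | 5 mmHg | trend requires strictly more improvement vs the lowest prior value |
| `ipap_step` | 2 mbar | every questionnaire- or alkalosis-driven IPAP change |
| `ini_ipap_cap` | 20 mbar | initiation-only ceiling |
| `tdt_ipap_ceiling` | 30 mbar | titration ceiling (the 20 mbar cap is stated for initiation only) |
| `ipap_floor_gap` | 2 mbar | minimum IPAP−EPAP kept when lowering |
| `tdt_cycle_minutes` / `tdt_bga_minute` | 20 / 15 | day-time cycle and blood-gas offset |
| `tdt_max_cycles` | 3 | ventilation-and-parameter-change cycles |
| `pause_minutes` | 30 | alkalosis stop-ventilation pause |

Rise time and trigger sensitivity are ordinal comfort levels 1–5 (the
protocol names no physical units for the target ventilators); a higher
trigger level means a more sensitive trigger, and each questionnaire hit
moves a level by one. Pressures are integers in mbar — every protocol
value and delta is integral — and PaCO₂ is fixed to mmHg.

## Design choices where the protocol is open

* **Trend-interval endpoints.** The evaluation interval "(45–50) mmHg" is
  read as half-open `(45, 50]`: exactly 45 counts as adequate (the most
  permissive reading at the favourable boundary), exactly 50 still enters
  the trend check. "Improved more than 5 mmHg" is strict, and "improved
  compared to the previous value" means strictly lower PaCO₂.
* **Lowest prior value.** The trend rule compares the current PaCO₂ with
  the lowest *prior* measurement (and the most recent prior one). If the
  current value itself were included in the minimum, a new personal best
  would always show zero improvement against "the lowest value" and the
  rule could never fire; the core `classify_paco2(lowest, previous,
  current)` therefore takes the references explicitly, with record-based
  wrappers that derive them from the history before the current sample.
* **Q4 semantics.** Q4 ("is the ventilation now more comfortable?") is
  asked only after a configuration change; a "no" reverts the most recent
  change and freezes the parameter families it touched.
* **Initiation termination.** Each family is frozen after three
  consecutive same-direction changes; because an adversarial alternating
  answer stream would defeat that rule alone, a global cap of ten
  questionnaire passes bounds the loop. Both limits are configurable; the
  cap is unreachable for any consistent patient (the pressure cap or
  satisfaction ends the loop first).
* **Alkalosis restart at the floor.** The restart rule lowers IPAP by
  2 mbar; when IPAP already sits at `EPAP + 2` no strictly lower pressure
  exists, and recurring alkalosis would cycle forever through
  pause-and-restart at an unchanged configuration. The engine aborts with
  physician referral in that case, which also guarantees termination:
  every restart strictly lowers IPAP.
* **Option B vs C.** A morning evaluation that demands a pressure change
  (any Q1 complaint, or a PaCO₂ verdict of needs-adjustment) routes to
  option C with IPAP moved one step in the indicated direction (the
  patient's perception wins when voiced; a purely PaCO₂-driven adjustment
  raises support). If the pressure is already at its cap/floor so no
  different configuration can be emitted, the outcome degrades to option B
  with a pressure-at-limit advisory, preserving the invariant that option
  C is emitted exactly when the recommended IPAP differs. Oxygen-flow
  changes are advisory free text only — no numeric titration rule exists.
* **Recurring patients** route directly to the night titration; the
  day-time control-visit entry (stored night configuration) remains
  reachable by explicitly starting TDT with that entry path.

## Virtual patients

The simulator exists to exercise every branch of the decision logic, not
to model respiratory mechanics. It is linear with Gaussian noise, one
seeded generator per patient:

* `PaCO2 = baseline − co2_sensitivity · (IPAP − EPAP) · hours/8 + ε`,
  floored at 15 mmHg; `co2_sensitivity` (default 0.5 mmHg per mbar per
  8-hour night) is the response to pressure support, `baseline` defaults
  to 55 mmHg, noise SD 1 mmHg.
* `pH = 7.40 + ph_coupling · (PaCO2 − ph_reference)` with coupling
  −0.008/mmHg. `ph_reference` defaults to the baseline PaCO₂: a *stable*
  chronic hypercapnic patient is renally compensated, so pH sits near 7.40
  at their habitual PaCO₂ and an acute CO₂ reduction pushes pH up —
  exactly the post-hypercapnic alkalosis the pause rule guards against.
  Setting `ph_reference` below baseline models an acutely decompensated
  patient who trips the acidosis gate instead.
* `SpO2 = baseline + spo2_gain · (IPAP − EPAP)` on NIV (gain 0.3 %/mbar,
  baseline 90 %), clamped to (0, 100].

Comfort policies answer the questionnaire (always satisfied; wants
more/less pressure toward a private IPAP target, with Q4 comparing
closeness to that target; fully random), and approval policies answer the
continue-titrating questions. The model is memoryless across nights (the
off-NIV baseline always returns to the chronic value) and has no sleep
staging, no mask-fit effects and no carry-over adaptation — so passing
closed-loop tests demonstrate the correctness and safety of the *decision
logic* under plausible physiology, not clinical effectiveness.

## Numerical and testing choices

* Safety thresholds are exact strict inequalities on floats; the
  continue/abort and continue/pause boundaries are recovered to 1e-6 by
  bisection in the test suite, which pins both the values and their
  strictness.
* The trend rule is verified against an independently coded brute-force
  oracle on a dense grid (> 100 000 triples) that straddles the interval
  edges and the 5 mmHg boundary.
* Termination of initiation is proven by a memoized exhaustive walk over
  the full 36-letter answer alphabet (×3 Q4 variants where admissible);
  day-time titration by an exhaustive branch over every input category at
  every decision point. Closed-loop behaviour is fuzzed over 1 000 seeded
  virtual patients for up to 20 simulated nights each — bounded work per
  night (livelock guard), physician referral whenever an on-NIV sample is
  acidotic or hypoxemic, and routing-language conformance.
* Problem sizes (grid spacing 0.1–0.5 mmHg, 1 000 fuzzed patients,
  20-night horizon, 25 replayed sessions) keep the whole suite around a
  minute on one core while covering every rule boundary; the acceptance
  script's trend sweep uses 0.001 mmHg steps over the 5 mmHg-wide
  interval.

## Known limitations

* The engine models one patient per session; ward scheduling, EHR and
  device connectivity are out of scope.
* Transcutaneous CO₂ values are accepted as ordinary samples with a source
  tag; no sensor calibration model.
* Nocturnal oxygenation beyond the SpO₂ ≥ 85 % safety floor has no
  stricter discharge target; only the stated rules are applied.
* kPa inputs are not converted; PaCO₂ is mmHg throughout.
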