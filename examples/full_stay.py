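"""A complete closed-loop hospital stay: initiation, day-time titration,
one or more titration nights, and a routing outcome.

The virtual patient responds well to pressure support (PaCO2 falls
1 mmHg per mbar of support over a full night) and is satisfied, so a
single night at the default pressures reaches an adequate PaCO2 and the
engine discharges them (night-time option a).

Run:  python examples/full_stay.py
"""

from nivflow import Disposition, EventKind
from nivflow.patient import VirtualPatientParams, run_closed_loop

params = VirtualPatientParams(patient_id="EX2", co2_sensitivity=1.0,
                              noise_sd_paco2=0.0, rng_seed=1)
session = run_closed_loop(params)

print(f"disposition      : {session.disposition.value}")
print(f"titration nights : {session.nights_completed}")
cfg = session.record.stored_night_config
print(f"night config     : IPAP {cfg.ipap} / EPAP {cfg.epap} mbar")
print(f"events logged    : {len(session.events)}")
print()
print("blood gases recorded (pH / PaCO2 mmHg / SpO2 %, on or off NIV):")
for e in session.events:
    if e.kind is EventKind.MEASUREMENT_RECORDED:
        p = e.payload
        where = "on NIV " if p["on_niv"] else "off NIV"
        print(f"  t={e.at:6.0f} min  {where}  pH {p['ph']:.3f}"
              f"  PaCO2 {p['paco2']:5.1f}  SpO2 {p['spo2']:.1f}")
print()
print("the final on-NIV PaCO2 is at or below 45 mmHg, the patient is")
print("satisfied, and all safety gates passed: discharge after one night.")
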