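"""Blood-gas safety gate and night-time PaCO2 trend rule on hand-picked samples.

Run:  python examples/safety_and_trend_rules.py
"""

from nivflow import BloodGasSample, classify_paco2, evaluate_safety

print("Safety gate (abort on SpO2 < 85 % or pH < 7.35; pause on pH > 7.55):")
for ph, spo2 in [(7.42, 95.0), (7.30, 95.0), (7.40, 84.0), (7.60, 95.0), (7.35, 85.0)]:
    verdict = evaluate_safety(BloodGasSample(ph=ph, paco2=50.0, spo2=spo2))
    reasons = ", ".join(sorted(r.value for r in verdict.reasons)) or "-"
    print(f"  pH {ph:.2f}  SpO2 {spo2:4.0f} %  ->  {verdict.verdict.value:22s} [{reasons}]")

print()
print("PaCO2 trend rule for values inside (45, 50] mmHg")
print("(improving only if > 5 mmHg below the lowest prior value AND below the")
print("previous measurement; <= 45 is adequate, > 50 always needs adjustment):")
for lowest, previous, current in [(55, 49, 48), (51, 49, 48), (54, 50, 49),
                                  (60, 60, 44), (60, 60, 52)]:
    v = classify_paco2(lowest, previous, current)
    print(f"  lowest {lowest}  previous {previous}  current {current}"
          f"  ->  {v.verdict.value}")
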