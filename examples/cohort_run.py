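"""Closed-loop run over a small mixed cohort of virtual patients.

One patient responds well, one keeps asking for more pressure, and one is
acutely decompensated (acidotic on every blood gas) and is referred to a
physician at the first day-time safety check.

Run:  python examples/cohort_run.py
"""

from nivflow.patient import ComfortPolicy, VirtualPatientParams, run_closed_loop

cohort = [
    VirtualPatientParams(patient_id="responder", co2_sensitivity=1.0,
                         noise_sd_paco2=0.5, rng_seed=11),
    VirtualPatientParams(patient_id="wants-pressure", co2_sensitivity=0.8,
                         comfort_policy=ComfortPolicy.WANTS_MORE_PRESSURE,
                         ipap_target=22, noise_sd_paco2=0.5, rng_seed=12),
    VirtualPatientParams(patient_id="decompensated", ph_reference=40.0,
                         noise_sd_paco2=0.5, rng_seed=13),
]

print("patient_id\tnights\tfinal_ipap\tdisposition")
for params in cohort:
    session = run_closed_loop(params)
    cfg = session.record.stored_night_config
    final_ipap = cfg.ipap if cfg is not None else session.process_state.config.ipap
    print(f"{params.patient_id}\t{session.nights_completed}\t"
          f"{final_ipap}\t{session.disposition.value}")
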