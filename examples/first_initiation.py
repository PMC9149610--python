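"""First initiation of NIV driven by a pressure-hungry virtual patient.

The patient keeps answering "too little air" (Q1), so the engine raises
IPAP in 2 mbar steps from the best-practice start (16 mbar) until the
20 mbar initiation cap; the cap then ends the comfort loop.

Run:  python examples/first_initiation.py
"""

from nivflow import PatientRecord
from nivflow.ini import IniPhase, ini_apply_answers, ini_start
from nivflow.patient import ComfortPolicy, VirtualPatient, VirtualPatientParams

patient = VirtualPatient(VirtualPatientParams(
    comfort_policy=ComfortPolicy.WANTS_MORE_PRESSURE, ipap_target=99,
    noise_sd_paco2=0.0))

state = ini_start(PatientRecord(patient_id="EX1")).state
cfg = state.config
print(f"start: IPAP {cfg.ipap} / EPAP {cfg.epap} mbar, backup {cfg.backup_rate}/min")

while state.phase is not IniPhase.DONE:
    answers = patient.answer_questionnaire(state.config, state.prior_config,
                                           include_q4=state.expecting_q4)
    state = ini_apply_answers(state, answers).state
    print(f"pass {state.pass_count}: Q1={answers.q1_air_amount.value:10s}"
          f" -> IPAP {state.config.ipap} mbar  (phase {state.phase.value})")

print(f"final configuration after initiation: IPAP {state.config.ipap} mbar"
      " (never exceeds the 20 mbar initiation cap)")
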