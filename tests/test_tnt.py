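"""Night-time titration: measurement plan, safety, morning routing to a/b/c."""

import itertools

import pytest

from nivflow import (
    AirAmount,
    AirSpeed,
    EventKind,
    InputError,
    PatientRecord,
    ProtocolError,
    QuestionnaireResponse,
    TrendVerdict,
)
from nivflow.tnt import (
    TntOption,
    TntPhase,
    TntReason,
    tnt_evaluate,
    tnt_receive_sample,
    tnt_resume_after_pause,
    tnt_start,
)
from conftest import bga


def answers(q1=AirAmount.ENOUGH, q2=AirSpeed.ADEQUATE, q3=False, q4=None):
    return QuestionnaireResponse(q1_air_amount=q1, q2_air_speed=q2,
                                 q3_trigger_exhausting=q3, q4_more_comfortable=q4)


def run_night(record, config, baseline=58.0, night1=50.0, night2=48.0):
    """Drive one uneventful night; returns (state, record-with-history)."""
    from nivflow import update_paco2_history
    state = tnt_start(record, config).state
    for paco2, on_niv, t in ((baseline, False, 0.0), (night1, True, 240.0),
                             (night2, True, 480.0)):
        sample = bga(paco2=paco2, taken_at=t, on_niv=on_niv)
        state = tnt_receive_sample(state, sample, now=t).state
        record = update_paco2_history(record, sample)
    return state, record


class TestStartAndSamples:
    def test_measurement_plan_one_off_two_on(self, new_record, config):
        tr = tnt_start(new_record, config)
        plan = [e for e in tr.events if e.kind is EventKind.RECOMMENDATION][0]
        assert plan.payload["planned_off_niv_samples"] == 1
        assert plan.payload["planned_on_niv_samples"] == 2
        assert tr.state.config == config  # config passes through unchanged

    def test_baseline_must_be_off_niv(self, new_record, config):
        state = tnt_start(new_record, config).state
        with pytest.raises(InputError, match="without NIV"):
            tnt_receive_sample(state, bga(on_niv=True))

    def test_night_samples_must_be_on_niv(self, new_record, config):
        state = tnt_start(new_record, config).state
        state = tnt_receive_sample(state, bga(on_niv=False)).state
        with pytest.raises(InputError, match="under NIV"):
            tnt_receive_sample(state, bga(on_niv=False, taken_at=240.0))

    def test_unsafe_night_sample_aborts(self, new_record, config):
        state = tnt_start(new_record, config).state
        state = tnt_receive_sample(state, bga(on_niv=False)).state
        out = tnt_receive_sample(state, bga(ph=7.33, taken_at=240.0), now=240.0)
        assert out.state.phase is TntPhase.ABORTED

    def test_two_safe_samples_reach_morning_evaluation(self, new_record, config):
        state, _ = run_night(new_record, config)
        assert state.phase is TntPhase.MORNING_EVALUATION
        assert len(state.on_niv_samples) == 2


class TestNocturnalAlkalosis:
    def _paused(self, record, config):
        state = tnt_start(record, config).state
        state = tnt_receive_sample(state, bga(on_niv=False)).state
        return tnt_receive_sample(state, bga(ph=7.60, taken_at=240.0),
                                  now=240.0).state

    def test_pause_thirty_minutes_then_resume_lowers_ipap(self, new_record, config):
        paused = self._paused(new_record, config)
        assert paused.phase is TntPhase.PAUSED_ALKALOSIS
        assert paused.pause_until == 270.0
        tr = tnt_resume_after_pause(paused, bga(ph=7.50, taken_at=270.0,
                                                on_niv=False),
                                    patient_approves=True, now=270.0)
        assert tr.state.phase is TntPhase.NIGHT_BGA_1  # back to the same slot
        assert tr.state.config.ipap == config.ipap - 2
        assert tr.state.expecting_q4  # configuration changed overnight

    def test_premature_resume_rejected(self, new_record, config):
        paused = self._paused(new_record, config)
        with pytest.raises(ProtocolError, match="remain"):
            tnt_resume_after_pause(paused, bga(ph=7.50, taken_at=250.0),
                                   patient_approves=True, now=250.0)

    def test_decline_aborts(self, new_record, config):
        paused = self._paused(new_record, config)
        tr = tnt_resume_after_pause(paused, bga(ph=7.50, taken_at=270.0),
                                    patient_approves=False, now=270.0)
        assert tr.state.phase is TntPhase.ABORTED


class TestMorningEvaluation:
    def test_satisfied_and_adequate_discharges(self, new_record, config):
        state, record = run_night(new_record, config, night2=44.0)
        ev = tnt_evaluate(state, record, answers())
        assert ev.outcome.option is TntOption.A_DISCHARGE
        assert ev.outcome.rationale == (TntReason.SATISFIED_AND_ADEQUATE,)

    def test_improving_trend_discharges(self, new_record, config):
        # prior lowest 55, previous 55, current 48: inside (45, 50] but more
        # than 5 mmHg below the lowest and below the previous value
        state, record = run_night(new_record, config, baseline=58.0,
                                  night1=55.0, night2=48.0)
        ev = tnt_evaluate(state, record, answers())
        assert ev.outcome.option is TntOption.A_DISCHARGE

    def test_comfort_dissatisfaction_repeats_night_only(self, new_record, config):
        state, record = run_night(new_record, config, night2=44.0)
        ev = tnt_evaluate(state, record, answers(q2=AirSpeed.TOO_FAST))
        assert ev.outcome.option is TntOption.B_REPEAT_TNT
        assert ev.outcome.final_config.ipap == config.ipap  # pressure untouched
        assert ev.outcome.final_config.rise_time_level == config.rise_time_level + 1

    def test_pressure_complaint_repeats_day_and_night(self, new_record, config):
        state, record = run_night(new_record, config, night2=44.0)
        ev = tnt_evaluate(state, record, answers(q1=AirAmount.TOO_LITTLE))
        assert ev.outcome.option is TntOption.C_REPEAT_TDT_AND_TNT
        assert ev.outcome.final_config.ipap == config.ipap + 2
        assert TntReason.PRESSURE_CHANGED in ev.outcome.rationale

    def test_high_paco2_drives_pressure_up(self, new_record, config):
        state, record = run_night(new_record, config, night1=54.0, night2=53.0)
        ev = tnt_evaluate(state, record, answers())
        assert ev.outcome.option is TntOption.C_REPEAT_TDT_AND_TNT
        assert ev.outcome.final_config.ipap == config.ipap + 2
        assert TntReason.PACO2_NEEDS_ADJUSTMENT in ev.outcome.rationale

    def test_missing_samples_listed(self, new_record, config):
        state = tnt_start(new_record, config).state
        state = tnt_receive_sample(state, bga(on_niv=False)).state
        state = tnt_receive_sample(state, bga(taken_at=240.0), now=240.0).state
        # force the phase forward without the second sample
        from dataclasses import replace
        broken = replace(state, phase=TntPhase.MORNING_EVALUATION)
        with pytest.raises(ProtocolError, match="on-NIV night sample"):
            tnt_evaluate(broken, new_record, answers())

    def test_q4_required_after_overnight_change(self, new_record, config):
        from dataclasses import replace
        state, record = run_night(new_record, config, night2=44.0)
        changed = replace(state, expecting_q4=True)
        with pytest.raises(ProtocolError, match="Q4"):
            tnt_evaluate(changed, record, answers())


QUESTIONNAIRE_ALPHABET = [
    answers(q1=q1, q2=q2, q3=q3)
    for q1, q2, q3 in itertools.product(AirAmount, AirSpeed, [False, True])
]


class TestRoutingTotality:
    def _night_for_verdict(self, record, config, verdict):
        """Construct a completed night whose trend verdict is ``verdict``."""
        if verdict is TrendVerdict.ADEQUATE:
            return run_night(record, config, night2=44.0)
        if verdict is TrendVerdict.IMPROVING_TREND:
            return run_night(record, config, baseline=58.0, night1=55.0,
                             night2=48.0)   # prior lowest 55, previous 55
        return run_night(record, config, night1=54.0, night2=53.0)

    def test_every_cell_maps_to_exactly_one_option(self, new_record, config):
        """Exhaustive cross-product of trend verdict x questionnaire alphabet:
        the evaluation is total, and option A fires exactly on
        {adequate or improving} x {fully satisfied}."""
        for verdict in TrendVerdict:
            state, record = self._night_for_verdict(new_record, config, verdict)
            for a in QUESTIONNAIRE_ALPHABET:
                ev = tnt_evaluate(state, record, a)
                expect_a = (verdict in (TrendVerdict.ADEQUATE,
                                        TrendVerdict.IMPROVING_TREND)
                            and a.fully_satisfied)
                assert (ev.outcome.option is TntOption.A_DISCHARGE) == expect_a
                if a.q1_air_amount is not AirAmount.ENOUGH \
                        or verdict is TrendVerdict.NEEDS_ADJUSTMENT:
                    assert ev.outcome.option is not TntOption.A_DISCHARGE

    def test_option_c_iff_ipap_differs(self, new_record, config):
        """Option C is emitted exactly when the recommended configuration
        differs from the incoming one in IPAP."""
        for verdict in TrendVerdict:
            state, record = self._night_for_verdict(new_record, config, verdict)
            for a in QUESTIONNAIRE_ALPHABET:
                ev = tnt_evaluate(state, record, a)
                differs = ev.outcome.final_config.ipap != state.config.ipap
                assert differs == (ev.outcome.option is
                                   TntOption.C_REPEAT_TDT_AND_TNT)
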