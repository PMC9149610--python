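"""JSON persistence for sessions.

The session document is a stable, diff-able JSON rendering of the full
engine state including the append-only event log. Serialization is
lossless: ``load_session(save_session(s)) == s`` for every valid session,
and key order is fixed so equal sessions serialize to identical bytes.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional, Union

from .engine import Session
from .ini import IniPhase, IniState
from .model import (
    BloodGasSample,
    Disposition,
    EventKind,
    Mode,
    PatientRecord,
    PatientStatus,
    ProcessEvent,
    ProcessName,
    ProtocolSettings,
    SessionFormatError,
    VentilatorConfig,
)
from .tdt import TdtEntryPath, TdtPhase, TdtState
from .tnt import TntPhase, TntState

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# To dict
# ---------------------------------------------------------------------------

def _config_dict(config: Optional[VentilatorConfig]) -> Optional[dict]:
    if config is None:
        return None
    return {"mode": config.mode.value, "ipap": config.ipap, "epap": config.epap,
            "backup_rate": config.backup_rate,
            "rise_time_level": config.rise_time_level,
            "trigger_level": config.trigger_level,
            "level_min": config.level_min, "level_max": config.level_max}


def _record_dict(record: PatientRecord) -> dict:
    return {"patient_id": record.patient_id, "status": record.status.value,
            "paco2_history": [list(e) for e in record.paco2_history],
            "stored_night_config": _config_dict(record.stored_night_config)}


def _sample_dict(sample: BloodGasSample) -> dict:
    return {"ph": sample.ph, "paco2": sample.paco2, "spo2": sample.spo2,
            "taken_at": sample.taken_at, "on_niv": sample.on_niv,
            "source": sample.source}


def _state_dict(state) -> Optional[dict]:
    if state is None:
        return None
    if isinstance(state, IniState):
        return {"type": "INI", "phase": state.phase.value,
                "config": _config_dict(state.config),
                "prior_config": _config_dict(state.prior_config),
                "phase_started_at": state.phase_started_at,
                "expecting_q4": state.expecting_q4,
                "pass_count": state.pass_count,
                "frozen": sorted(state.frozen),
                "changed_last_pass": sorted(state.changed_last_pass),
                "streaks": [list(s) for s in state.streaks]}
    if isinstance(state, TdtState):
        return {"type": "TDT", "phase": state.phase.value,
                "config": _config_dict(state.config),
                "entry_path": state.entry_path.value,
                "cycle_count": state.cycle_count,
                "cycle_started_at": state.cycle_started_at,
                "bga_due_at": state.bga_due_at,
                "pause_until": state.pause_until}
    if isinstance(state, TntState):
        return {"type": "TNT", "phase": state.phase.value,
                "config": _config_dict(state.config),
                "samples": [_sample_dict(s) for s in state.samples],
                "pause_until": state.pause_until,
                "paused_slot": None if state.paused_slot is None else state.paused_slot.value,
                "expecting_q4": state.expecting_q4}
    raise SessionFormatError(f"unknown process state type {type(state).__name__}")


def session_to_dict(session: Session) -> dict:
    return {
        "session_id": session.session_id,
        "settings": asdict(session.settings),
        "initial_record": _record_dict(session.initial_record),
        "record": _record_dict(session.record),
        "clock": session.clock,
        "active_process": None if session.active_process is None
        else session.active_process.value,
        "process_state": _state_dict(session.process_state),
        "events": [{"seq": e.seq, "at": e.at, "process": e.process.value,
                    "kind": e.kind.value, "payload": dict(e.payload)}
                   for e in session.events],
        "disposition": session.disposition.value,
        "nights_completed": session.nights_completed,
    }


def session_to_json(session: Session) -> str:
    doc = {"schema_version": SCHEMA_VERSION, "session": session_to_dict(session)}
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


# ---------------------------------------------------------------------------
# From dict
# ---------------------------------------------------------------------------

def _config_from(d: Optional[dict]) -> Optional[VentilatorConfig]:
    if d is None:
        return None
    return VentilatorConfig(mode=Mode(d["mode"]), ipap=d["ipap"], epap=d["epap"],
                            backup_rate=d["backup_rate"],
                            rise_time_level=d["rise_time_level"],
                            trigger_level=d["trigger_level"],
                            level_min=d.get("level_min", 1),
                            level_max=d.get("level_max", 5))


def _record_from(d: dict) -> PatientRecord:
    return PatientRecord(patient_id=d["patient_id"], status=PatientStatus(d["status"]),
                         paco2_history=tuple((float(t), float(v))
                                             for t, v in d["paco2_history"]),
                         stored_night_config=_config_from(d["stored_night_config"]))


def _sample_from(d: dict) -> BloodGasSample:
    return BloodGasSample(ph=d["ph"], paco2=d["paco2"], spo2=d["spo2"],
                          taken_at=d["taken_at"], on_niv=d["on_niv"],
                          source=d.get("source", "arterial"))


def _state_from(d: Optional[dict]):
    if d is None:
        return None
    if d["type"] == "INI":
        return IniState(phase=IniPhase(d["phase"]), config=_config_from(d["config"]),
                        prior_config=_config_from(d["prior_config"]),
                        phase_started_at=d["phase_started_at"],
                        expecting_q4=d["expecting_q4"], pass_count=d["pass_count"],
                        frozen=frozenset(d["frozen"]),
                        changed_last_pass=frozenset(d["changed_last_pass"]),
                        streaks=tuple((f, dr, c) for f, dr, c in d["streaks"]))
    if d["type"] == "TDT":
        return TdtState(phase=TdtPhase(d["phase"]), config=_config_from(d["config"]),
                        entry_path=TdtEntryPath(d["entry_path"]),
                        cycle_count=d["cycle_count"],
                        cycle_started_at=d["cycle_started_at"],
                        bga_due_at=d["bga_due_at"], pause_until=d["pause_until"])
    if d["type"] == "TNT":
        return TntState(phase=TntPhase(d["phase"]), config=_config_from(d["config"]),
                        samples=tuple(_sample_from(s) for s in d["samples"]),
                        pause_until=d["pause_until"],
                        paused_slot=None if d["paused_slot"] is None
                        else TntPhase(d["paused_slot"]),
                        expecting_q4=d["expecting_q4"])
    raise SessionFormatError(f"unknown process state type {d['type']!r}")


def session_from_dict(d: dict) -> Session:
    try:
        return Session(
            session_id=d["session_id"],
            settings=ProtocolSettings(**d["settings"]),
            initial_record=_record_from(d["initial_record"]),
            record=_record_from(d["record"]),
            clock=d["clock"],
            active_process=None if d["active_process"] is None
            else ProcessName(d["active_process"]),
            process_state=_state_from(d["process_state"]),
            events=tuple(ProcessEvent(seq=e["seq"], at=e["at"],
                                      process=ProcessName(e["process"]),
                                      kind=EventKind(e["kind"]),
                                      payload=e["payload"])
                         for e in d["events"]),
            disposition=Disposition(d["disposition"]),
            nights_completed=d["nights_completed"],
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise SessionFormatError(f"malformed session document: {exc}") from exc


def session_from_json(text: str) -> Session:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SessionFormatError(
            f"not valid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise SessionFormatError("missing schema_version")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise SessionFormatError(
            f"unknown schema_version {doc['schema_version']!r}; this build reads "
            f"version {SCHEMA_VERSION!r} — migrate the document first")
    return session_from_dict(doc["session"])


# ---------------------------------------------------------------------------
# Files
# ---------------------------------------------------------------------------

def save_session(session: Session, path: Union[str, Path]) -> None:
    """Atomically write the session document (no partial files on error)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(session_to_json(session))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_session(path: Union[str, Path]) -> Session:
    return session_from_json(Path(path).read_text())
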