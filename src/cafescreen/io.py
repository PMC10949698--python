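"""Readers and writers: JSONL session logs, cohort CSVs, analysis reports.

Session logs are JSON Lines: a header object (seed, protocol hash,
package version) followed by one event per line with fields ``t``,
``phase``, ``level``, ``payload``.  Tabular exports are CSV with a
``#``-prefixed provenance header embedding the same metadata, so every
output can be traced to the seed and configuration that produced it.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import FixtureFormatError, SchemaError
from .session import (
    Phase,
    ResponseSet,
    SessionEvent,
    SessionLog,
    SessionOutcome,
    RESPONSE_PHASES,
)

__all__ = [
    "write_session_log",
    "read_session_log",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_scores_csv",
]

_LOG_FORMAT = "cafescreen-session-log"


def _package_version() -> str:
    from . import __version__

    return __version__


def _jsonable_payload(payload):
    if isinstance(payload, dict):
        return {k: list(v) if isinstance(v, tuple) else v for k, v in payload.items()}
    if isinstance(payload, tuple):
        return list(payload)
    return payload


def write_session_log(log: SessionLog, path: str | Path, no_timestamp: bool = False) -> None:
    """Write a session log as JSONL (header line, then one event per line)."""
    header = {
        "format": _LOG_FORMAT,
        "version": _package_version(),
        "seed": log.script_seed,
        "protocol_hash": log.protocol_hash,
        "outcome": log.outcome.status,
        "discontinued_at": log.outcome.discontinued_at,
    }
    if not no_timestamp:
        header["created"] = datetime.now(timezone.utc).isoformat()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(header) + "\n")
        for ev in log.events:
            rec = {
                "t": ev.timestamp,
                "phase": ev.phase.value,
                "level": ev.level,
                "payload": _jsonable_payload(ev.payload),
            }
            fh.write(json.dumps(rec) + "\n")


def _payload_from_json(phase: Phase, payload):
    """Restore the in-memory payload shapes JSON cannot represent."""
    if phase in (Phase.IMMEDIATE_RECALL, Phase.DELAYED_RECALL, Phase.COUNTER_SELECTION):
        return tuple(payload or ())
    if phase is Phase.SERVICE:
        return {k: (int(v[0]), int(v[1])) for k, v in dict(payload or {}).items()}
    if phase is Phase.LEVEL_END and isinstance(payload, dict) and "accuracies" in payload:
        return {**payload, "accuracies": tuple(payload["accuracies"])}
    if isinstance(payload, list):
        return tuple(payload)
    return payload


def _responses_from_events(events: Iterable[SessionEvent]) -> dict[int, ResponseSet]:
    stored: dict[int, dict[Phase, object]] = {}
    for ev in events:
        if ev.phase in RESPONSE_PHASES:
            stored.setdefault(ev.level, {})[ev.phase] = ev.payload
    out: dict[int, ResponseSet] = {}
    for level, phases in stored.items():
        service = {
            k: (int(v[0]), int(v[1]))
            for k, v in dict(phases.get(Phase.SERVICE, {})).items()
        }
        out[level] = ResponseSet(
            level=level,
            immediate_recall=tuple(phases.get(Phase.IMMEDIATE_RECALL, ())),
            delayed_recall=tuple(phases.get(Phase.DELAYED_RECALL, ())),
            counter_selection=tuple(phases.get(Phase.COUNTER_SELECTION, ())),
            service=service,
        )
    return out


def read_session_log(path: str | Path) -> SessionLog:
    """Parse a JSONL session log back into a :class:`SessionLog`.

    Malformed lines raise :class:`FixtureFormatError` naming the line
    number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise FixtureFormatError(f"{path}: empty session log")

    def parse(i: int, line: str) -> dict:
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise FixtureFormatError(f"{path}: line {i + 1} is not valid JSON: {exc}") from exc
        if not isinstance(obj, dict):
            raise FixtureFormatError(f"{path}: line {i + 1} is not a JSON object")
        return obj

    header = parse(0, lines[0])
    if header.get("format") != _LOG_FORMAT:
        raise FixtureFormatError(f"{path}: line 1 missing session-log header")
    events = []
    for i, line in enumerate(lines[1:], start=1):
        rec = parse(i, line)
        for f in ("t", "phase", "level"):
            if f not in rec:
                raise FixtureFormatError(f"{path}: line {i + 1} missing field {f!r}")
        try:
            phase = Phase(rec["phase"])
        except ValueError as exc:
            raise FixtureFormatError(
                f"{path}: line {i + 1} has unknown phase {rec['phase']!r}"
            ) from exc
        events.append(
            SessionEvent(
                timestamp=float(rec["t"]),
                phase=phase,
                level=int(rec["level"]),
                payload=_payload_from_json(phase, rec.get("payload")),
            )
        )
    if not events:
        raise FixtureFormatError(f"{path}: session log holds no events")
    outcome = SessionOutcome(
        status=header.get("outcome", "completed"),
        discontinued_at=header.get("discontinued_at"),
    )
    return SessionLog(
        script_seed=int(header["seed"]),
        protocol_hash=str(header["protocol_hash"]),
        events=tuple(events),
        responses=_responses_from_events(events),
        outcome=outcome,
    )


def _provenance_header(seed: int, config_hash: str, no_timestamp: bool) -> str:
    parts = [f"# cafescreen version={_package_version()} seed={seed} config_hash={config_hash}"]
    if not no_timestamp:
        parts.append(f"# created={datetime.now(timezone.utc).isoformat()}")
    return "\n".join(parts) + "\n"


def write_cohort_csv(
    table: pd.DataFrame,
    path: str | Path,
    seed: int,
    config_hash: str,
    no_timestamp: bool = False,
) -> None:
    """Write a cohort table as CSV with a provenance comment header."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_header(seed, config_hash, no_timestamp))
        table.to_csv(fh, index=False)


#: columns the analysis pipeline requires of an imported cohort table
REQUIRED_COHORT_COLUMNS = ("group", "grand_total", "screener_score", "impaired_flag")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV (ignoring ``#`` provenance lines) and check its schema."""
    try:
        table = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: no tabular data found") from exc
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: cohort table missing column(s) {missing}")
    return table


def write_scores_csv(
    rows: pd.DataFrame,
    path: str | Path,
    seed: int,
    config_hash: str,
    no_timestamp: bool = False,
) -> None:
    """Write per-session score rows as CSV with a provenance header."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_header(seed, config_hash, no_timestamp))
        rows.to_csv(fh, index=False)
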