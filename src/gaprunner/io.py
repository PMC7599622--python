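"""Readers and writers for session logs and cohorts.

Formats are deliberately plain: comma-separated UTF-8 CSV with a mandatory
header and "." decimals, or JSON-lines with one record per line.  Floats
are written with ``repr`` so write-then-read is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

from .cohort_sim import Cohort, ParticipantProfile, SwanScore
from .errors import DataFormatError
from .schedule import ISClass
from .task_engine import JumpRecord, SessionLog

__all__ = [
    "write_session_log",
    "read_session_log",
    "write_cohort",
    "read_cohort",
]

_LOG_HEADER = "participant_id,block_id,gap_index,is_nominal,voluntary,omission,distance,outcome"
_LOG_FIELDS = _LOG_HEADER.split(",")


def _record_to_row(r: JumpRecord) -> dict:
    return {
        "participant_id": r.participant_id,
        "block_id": r.block_id,
        "gap_index": r.gap_index,
        "is_nominal": r.is_nominal.value,
        "voluntary": r.voluntary,
        "omission": r.omission,
        "distance": r.distance,
        "outcome": r.outcome,
    }


def _row_to_record(row: dict, line: int | None = None) -> JumpRecord:
    try:
        return JumpRecord(
            participant_id=str(row["participant_id"]),
            block_id=str(row["block_id"]),
            gap_index=int(row["gap_index"]),
            is_nominal=ISClass(str(row["is_nominal"])),
            voluntary=_parse_bool(row["voluntary"]),
            omission=_parse_bool(row["omission"]),
            distance=float(row["distance"]),
            outcome=str(row["outcome"]),
        )
    except (KeyError, ValueError) as exc:
        raise DataFormatError(f"bad record: {exc}", line=line) from exc


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def write_session_log(log: SessionLog, path: str | Path) -> None:
    """Write a log as CSV or JSON-lines depending on the file suffix."""
    path = Path(path)
    if path.suffix == ".jsonl":
        with path.open("w", encoding="utf-8") as fh:
            fh.write(json.dumps({"participant_id": log.participant_id,
                                 "schedule_hash": log.schedule_hash,
                                 "n_clamped": log.n_clamped}) + "\n")
            for r in log.records:
                fh.write(json.dumps(_record_to_row(r)) + "\n")
        return
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schedule_hash={log.schedule_hash} n_clamped={log.n_clamped}\n")
        fh.write(_LOG_HEADER + "\n")
        for r in log.records:
            fh.write(
                f"{r.participant_id},{r.block_id},{r.gap_index},{r.is_nominal.value},"
                f"{r.voluntary},{r.omission},{r.distance!r},{r.outcome}\n"
            )


def read_session_log(path: str | Path) -> SessionLog:
    """Read a CSV or JSON-lines session log; errors carry the line number."""
    path = Path(path)
    if path.suffix == ".jsonl":
        return _read_jsonl(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta = {"schedule_hash": "", "n_clamped": 0}
    idx = 0
    if lines and lines[0].startswith("#"):
        for tok in lines[0][1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                if k in meta:
                    meta[k] = int(v) if k == "n_clamped" else v
        idx = 1
    if idx >= len(lines) or lines[idx].strip() != _LOG_HEADER:
        raise DataFormatError(f"expected header '{_LOG_HEADER}'", line=idx + 1)
    records = []
    pid = ""
    for lineno, ln in enumerate(lines[idx + 1:], start=idx + 2):
        if not ln.strip():
            continue
        parts = ln.split(",")
        if len(parts) != len(_LOG_FIELDS):
            raise DataFormatError(
                f"expected {len(_LOG_FIELDS)} fields, got {len(parts)}", line=lineno
            )
        rec = _row_to_record(dict(zip(_LOG_FIELDS, parts)), line=lineno)
        records.append(rec)
        pid = rec.participant_id
    return SessionLog(
        participant_id=pid,
        schedule_hash=str(meta["schedule_hash"]),
        records=records,
        n_clamped=int(meta["n_clamped"]),
    )


def _read_jsonl(path: Path) -> SessionLog:
    records = []
    header: dict = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            try:
                obj = json.loads(ln)
            except json.JSONDecodeError as exc:
                raise DataFormatError(f"invalid JSON: {exc}", line=lineno) from exc
            if lineno == 1 and "block_id" not in obj:
                header = obj
                continue
            records.append(_row_to_record(obj, line=lineno))
    return SessionLog(
        participant_id=str(header.get("participant_id",
                                      records[0].participant_id if records else "")),
        schedule_hash=str(header.get("schedule_hash", "")),
        records=records,
        n_clamped=int(header.get("n_clamped", 0)),
    )


# -- cohorts ------------------------------------------------------------

_PROFILE_EXTRA = ("d0", "sigma_d", "lapse_rate", "swan_sigma",
                  "attention_gain", "is_threshold", "is_ref")
_COHORT_HEADER = (
    "participant_id,lambda,swan_total,"
    + ",".join(f"swan_item_{i}" for i in range(1, 10))
    + "," + ",".join(_PROFILE_EXTRA)
)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write ``participants.csv`` plus one session-log CSV per participant."""
    outdir = Path(outdir)
    (outdir / "logs").mkdir(parents=True, exist_ok=True)
    with (outdir / "participants.csv").open("w", encoding="utf-8", newline="") as fh:
        fh.write(_COHORT_HEADER + "\n")
        for p, s in zip(cohort.profiles, cohort.swan):
            extras = ",".join(repr(float(getattr(p, name))) for name in _PROFILE_EXTRA)
            items = ",".join(str(i) for i in s.items)
            fh.write(f"{p.participant_id},{p.lam!r},{s.total},{items},{extras}\n")
    for p, log in zip(cohort.profiles, cohort.logs):
        write_session_log(log, outdir / "logs" / f"{p.participant_id}.csv")


def read_cohort(indir: str | Path) -> Cohort:
    """Inverse of :func:`write_cohort`; round-trips all fields exactly."""
    indir = Path(indir)
    text = (indir / "participants.csv").read_text(encoding="utf-8").splitlines()
    if not text or text[0].strip() != _COHORT_HEADER:
        raise DataFormatError("unexpected participants.csv header", line=1)
    profiles, swans, logs = [], [], []
    for lineno, ln in enumerate(text[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split(",")
        if len(parts) != 12 + len(_PROFILE_EXTRA):
            raise DataFormatError(
                f"expected {12 + len(_PROFILE_EXTRA)} fields, got {len(parts)}",
                line=lineno,
            )
        try:
            pid = parts[0]
            lam = float(parts[1])
            total = int(parts[2])
            items = tuple(int(v) for v in parts[3:12])
            extras = {name: float(v) for name, v in zip(_PROFILE_EXTRA, parts[12:])}
        except ValueError as exc:
            raise DataFormatError(str(exc), line=lineno) from exc
        profiles.append(ParticipantProfile(participant_id=pid, lam=lam, **extras))
        swans.append(SwanScore(items=items, total=total))
        logs.append(read_session_log(indir / "logs" / f"{pid}.csv"))
    return Cohort(profiles=profiles, swan=swans, logs=logs)
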