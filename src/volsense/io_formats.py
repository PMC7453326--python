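"""CSV/JSON readers and writers for the pipeline's tabular types.

All files are UTF-8, comma-separated, header required. Invariants of the
data model (ranges, ordering, duplication) are enforced at this boundary:
nothing invalid is admitted past a reader, and writers refuse rows that
violate the model rather than emitting them.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError
from .types import (
    FEATURES,
    SCALES,
    CorrelationCell,
    CorrelationReport,
    FeatureRow,
    RecordingLog,
    SubjectScales,
)

logger = logging.getLogger(__name__)

RECORDING_COLUMNS = ["subject_id", "timestamp", "volume", "speech_detected"]
SCALES_COLUMNS = ["subject_id", "timepoint", "lsas", "gad7", "phq8", "sds", "age", "sex"]
FEATURE_COLUMNS = ["subject_id", *FEATURES, "n_recordings", "included"]
REPORT_COLUMNS = ["feature", "scale", "r", "p", "n"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    return df


def read_recording_log(path: str | Path) -> dict[str, RecordingLog]:
    """Read a recordings CSV into per-subject :class:`RecordingLog` objects.

    Rows may arrive out of order; they are sorted by timestamp per subject.
    Duplicate timestamps within a subject keep the first occurrence and log
    a warning. Unparseable timestamps or volumes raise :class:`FormatError`
    with the 1-based file line number (header is line 1).
    """
    df = _read_csv(path, RECORDING_COLUMNS)
    lines = df.index.to_numpy() + 2  # +1 header, +1 zero-based

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise FormatError(
            f"unparseable timestamp {df['timestamp'].iloc[bad[0]]!r}",
            line=int(lines[bad[0]]),
        )
    try:
        # python-float conversion: exact round-trip of repr-formatted values
        vol = df["volume"].to_numpy(dtype=float)
    except ValueError:
        for i, x in enumerate(df["volume"]):
            try:
                float(x)
            except ValueError:
                raise FormatError(
                    f"unparseable volume {x!r}", line=int(lines[i])
                ) from None
        raise
    bad = np.flatnonzero(~np.isfinite(vol))
    if bad.size:
        raise FormatError(
            f"non-finite volume {df['volume'].iloc[bad[0]]!r}",
            line=int(lines[bad[0]]),
        )
    flag = df["speech_detected"].to_numpy()
    ok = np.isin(flag, ("0", "1"))
    if not ok.all():
        i = int(np.flatnonzero(~ok)[0])
        raise FormatError(
            f"speech_detected must be 0 or 1, got {flag[i]!r}", line=int(lines[i])
        )

    out: dict[str, RecordingLog] = {}
    tsec = ts.astype("int64").to_numpy() // 10**9
    speech = flag == "1"
    for sid, idx in df.groupby("subject_id", sort=True).indices.items():
        order = idx[np.argsort(tsec[idx], kind="stable")]
        t = tsec[order]
        keep = np.ones(len(order), dtype=bool)
        keep[1:] = np.diff(t) > 0
        if not keep.all():
            logger.warning(
                "subject %s: dropped %d duplicate-timestamp row(s), kept first",
                sid,
                int((~keep).sum()),
            )
            order = order[keep]
            t = t[keep]
        out[str(sid)] = RecordingLog(
            subject_id=str(sid),
            timestamps=t.astype("datetime64[s]"),
            volumes=vol[order],
            speech=speech[order],
        )
    return out


def write_recording_log(logs: dict[str, RecordingLog], path: str | Path) -> None:
    """Write per-subject logs to a recordings CSV (inverse of the reader)."""
    frames = []
    for sid in sorted(logs):
        log = logs[sid]
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": log.subject_id,
                    "timestamp": np.datetime_as_string(log.timestamps, unit="s"),
                    "volume": [repr(float(v)) for v in log.volumes],
                    "speech_detected": log.speech.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_scales(path: str | Path) -> list[SubjectScales]:
    """Read and validate a self-report scales CSV.

    Raises a located :class:`FormatError` for out-of-range scores,
    unknown sex/timepoint values, or duplicate (subject, timepoint) rows.
    """
    df = _read_csv(path, SCALES_COLUMNS)
    rows: list[SubjectScales] = []
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2
        sid = str(rec["subject_id"])
        key = (sid, str(rec["timepoint"]))
        if key in seen:
            raise FormatError(
                f"duplicate (subject, timepoint) row {key}", line=line
            )
        seen.add(key)
        try:
            scores = {s: int(rec[s]) for s in SCALES}
            age = float(rec["age"])
        except ValueError as e:
            raise FormatError(f"unparseable numeric field: {e}", line=line) from None
        try:
            rows.append(
                SubjectScales(
                    subject_id=sid,
                    timepoint=str(rec["timepoint"]),
                    age=age,
                    sex=str(rec["sex"]),
                    **scores,
                )
            )
        except RangeError as e:
            raise FormatError(str(e), line=line) from None
    return rows


def write_scales(rows: list[SubjectScales], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "timepoint": r.timepoint,
                "lsas": r.lsas,
                "gad7": r.gad7,
                "phq8": r.phq8,
                "sds": r.sds,
                "age": repr(r.age),
                "sex": r.sex,
            }
            for r in rows
        ],
        columns=SCALES_COLUMNS,
    ).to_csv(path, index=False)


def _fmt(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def write_feature_table(rows: list[FeatureRow], path: str | Path) -> None:
    """Write feature rows to CSV at full float precision.

    Rows are validated by construction (:class:`FeatureRow` refuses
    out-of-range values); an empty list yields a header-only file.
    Undefined feature cells are emitted as empty fields.
    """
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                **{f: _fmt(r.get(f)) for f in FEATURES},
                "n_recordings": r.n_recordings,
                "included": int(r.included),
            }
            for r in rows
        ],
        columns=FEATURE_COLUMNS,
    ).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[FeatureRow]:
    df = _read_csv(path, FEATURE_COLUMNS)
    rows = []
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2
        try:
            cells = {
                f: (None if rec[f] == "" else float(rec[f])) for f in FEATURES
            }
            rows.append(
                FeatureRow(
                    subject_id=str(rec["subject_id"]),
                    n_recordings=int(rec["n_recordings"]),
                    included=bool(int(rec["included"])),
                    **cells,
                )
            )
        except (ValueError, RangeError) as e:
            raise FormatError(str(e), line=line) from None
    return rows


def write_correlation_report(
    report: CorrelationReport, path: str | Path, format: str = "csv"
) -> None:
    """Write the feature × scale grid as CSV or JSON.

    Both formats carry identical numbers; unavailable cells (n < 3 or
    constant input) have r and p empty (CSV) / null (JSON).
    """
    records = [
        {
            "feature": feat,
            "scale": scale,
            "r": report[(feat, scale)].r,
            "p": report[(feat, scale)].p,
            "n": report[(feat, scale)].n,
        }
        for feat, scale in report
    ]
    if format == "csv":
        df = pd.DataFrame(
            {
                "feature": [r["feature"] for r in records],
                "scale": [r["scale"] for r in records],
                "r": [_fmt(r["r"]) for r in records],
                "p": [_fmt(r["p"]) for r in records],
                "n": [r["n"] for r in records],
            },
            columns=REPORT_COLUMNS,
        )
        df.to_csv(path, index=False)
    elif format == "json":
        Path(path).write_text(json.dumps(records, indent=2, sort_keys=True) + "\n")
    else:
        raise FormatError(f"unknown report format {format!r}")


def read_correlation_report(path: str | Path, format: str = "csv") -> CorrelationReport:
    report = CorrelationReport()
    if format == "csv":
        df = _read_csv(path, REPORT_COLUMNS)
        records = df.to_dict("records")
        for rec in records:
            rec["r"] = None if rec["r"] == "" else float(rec["r"])
            rec["p"] = None if rec["p"] == "" else float(rec["p"])
    elif format == "json":
        records = json.loads(Path(path).read_text())
    else:
        raise FormatError(f"unknown report format {format!r}")
    for rec in records:
        report[(str(rec["feature"]), str(rec["scale"]))] = CorrelationCell(
            r=rec["r"], p=rec["p"], n=int(rec["n"])
        )
    return report
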