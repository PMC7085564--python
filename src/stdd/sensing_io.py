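"""Canonical data model and CSV I/O for passive-sensing streams.

A study dataset is a directory with one sub-directory per participant::

    <root>/<participant_id>/
        accel_phone.csv   timestamp,x,y,z           50 Hz triaxial accelerometer
        accel_watch.csv   timestamp,x,y,z
        hrm.csv           timestamp,bpm             heart-rate samples
        light.csv         timestamp,lux             ambient light
        events.csv        timestamp,kind            step / significant_motion /
                                                    screen_on / screen_off
        calls.csv         start,direction,duration_s
        apps.csv          start,app_id,is_social,duration_s
        ema.csv           checkin_time,answered,physical,mood,sleep,social,food
        manifest.csv      participant_id,phq9,interview_outcome,timezone

All timestamps are integer epoch milliseconds (UTC).  Clock-time rules
(EMA slots, the nocturnal sleep window) are evaluated in the participant's
IANA timezone from the manifest; the default is UTC.

Two API levels are provided.  ``read_stream``/``write_stream`` operate on
lists of typed records and are convenient for small streams and tests;
``read_frame``/``write_frame`` exchange :class:`pandas.DataFrame` objects and
are what the pipeline uses for the high-rate accelerometer streams.
Malformed rows are never silently dropped: they are counted, logged and
reported back to the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stdd.sensing_io")

# ---------------------------------------------------------------------------
# Enumerations and constants

DEVICES = ("phone", "watch")
EVENT_KINDS = ("step", "significant_motion", "screen_on", "screen_off")
CALL_DIRECTIONS = ("incoming", "outgoing")
INTERVIEW_OUTCOMES = (
    "none",
    "remission_or_partial",
    "other_depressive_disorder",
    "mdd_confirmed",
)

#: Local clock hours of the six daily EMA check-in slots.
EMA_SLOT_HOURS = (7, 10, 13, 16, 19, 22)

MS_PER_MIN = 60_000
MS_PER_HOUR = 3_600_000
MS_PER_DAY = 86_400_000


# ---------------------------------------------------------------------------
# Typed records

@dataclass(slots=True)
class AccelSample:
    """One triaxial accelerometer sample, m/s^2 including gravity."""

    timestamp: int
    x: float
    y: float
    z: float
    device: str = "phone"


@dataclass(slots=True)
class HrmSample:
    timestamp: int
    bpm: float


@dataclass(slots=True)
class LightSample:
    timestamp: int
    lux: float


@dataclass(slots=True)
class DiscreteEvent:
    timestamp: int
    kind: str


@dataclass(slots=True)
class CallRecord:
    start: int
    direction: str
    duration_s: float


@dataclass(slots=True)
class AppSession:
    start: int
    app_id: str
    is_social: bool
    duration_s: float


@dataclass(slots=True)
class EmaResponse:
    """One scheduled EMA check-in: five 1-10 ordinal answers or a skip."""

    checkin_time: int
    answered: bool
    physical: int | None = None
    mood: int | None = None
    sleep: int | None = None
    social: int | None = None
    food: int | None = None

    def __post_init__(self) -> None:
        if self.answered:
            for name in ("physical", "mood", "sleep", "social", "food"):
                v = getattr(self, name)
                if v is None or not (1 <= int(v) <= 10):
                    raise ValueError(
                        f"answered EMA requires {name} in 1..10, got {v!r}"
                    )

    def answers(self) -> dict[str, int]:
        if not self.answered:
            raise ValueError("EMA was skipped; no answers available")
        return {
            name: int(getattr(self, name))
            for name in ("physical", "mood", "sleep", "social", "food")
        }


@dataclass(slots=True)
class ParticipantManifest:
    participant_id: str
    phq9: int
    interview_outcome: str
    timezone: str = "UTC"

    def __post_init__(self) -> None:
        if not 0 <= int(self.phq9) <= 27:
            raise ValueError(f"phq9 must lie in [0, 27], got {self.phq9}")
        if self.interview_outcome not in INTERVIEW_OUTCOMES:
            raise ValueError(
                f"unknown interview outcome {self.interview_outcome!r}"
            )


# ---------------------------------------------------------------------------
# Stream schemas

@dataclass(frozen=True)
class _StreamSpec:
    columns: tuple[str, ...]
    time_col: str
    float_cols: tuple[str, ...] = ()
    int_cols: tuple[str, ...] = ()
    enum_cols: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    str_cols: tuple[str, ...] = ()


STREAM_SPECS: dict[str, _StreamSpec] = {
    "accel": _StreamSpec(("timestamp", "x", "y", "z"), "timestamp",
                         float_cols=("x", "y", "z")),
    "hrm": _StreamSpec(("timestamp", "bpm"), "timestamp", float_cols=("bpm",)),
    "light": _StreamSpec(("timestamp", "lux"), "timestamp", float_cols=("lux",)),
    "events": _StreamSpec(("timestamp", "kind"), "timestamp",
                          enum_cols={"kind": EVENT_KINDS}),
    "calls": _StreamSpec(("start", "direction", "duration_s"), "start",
                         float_cols=("duration_s",),
                         enum_cols={"direction": CALL_DIRECTIONS}),
    "apps": _StreamSpec(("start", "app_id", "is_social", "duration_s"),
                        "start", float_cols=("duration_s",),
                        int_cols=("is_social",), str_cols=("app_id",)),
    "ema": _StreamSpec(
        ("checkin_time", "answered", "physical", "mood", "sleep", "social",
         "food"),
        "checkin_time", int_cols=("answered",),
        float_cols=("physical", "mood", "sleep", "social", "food")),
}

_RECORD_TYPES = {
    "accel": AccelSample,
    "hrm": HrmSample,
    "light": LightSample,
    "events": DiscreteEvent,
    "calls": CallRecord,
    "apps": AppSession,
    "ema": EmaResponse,
}

#: dataset file name -> (stream kind, device or None)
DATASET_LAYOUT = {
    "accel_phone.csv": ("accel", "phone"),
    "accel_watch.csv": ("accel", "watch"),
    "hrm.csv": ("hrm", None),
    "light.csv": ("light", None),
    "events.csv": ("events", None),
    "calls.csv": ("calls", None),
    "apps.csv": ("apps", None),
    "ema.csv": ("ema", None),
}


class SchemaError(ValueError):
    """CSV header does not match the expected stream schema."""


def empty_frame(kind: str) -> pd.DataFrame:
    spec = STREAM_SPECS[kind]
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in spec.columns})
    df[spec.time_col] = df[spec.time_col].astype(np.int64)
    for c in spec.enum_cols:
        df[c] = df[c].astype(object)
    for c in spec.str_cols:
        df[c] = df[c].astype(object)
    return df


# ---------------------------------------------------------------------------
# Frame-level I/O (pipeline fast path)

def read_frame(path: str | Path, kind: str) -> tuple[pd.DataFrame, int]:
    """Read one sensor CSV into a validated, time-sorted DataFrame.

    Returns ``(frame, malformed_count)``.  Rows with non-numeric values
    where numbers are required, out-of-range values or unknown enum labels
    are counted as malformed and excluded.  Non-monotone timestamps are
    stably sorted with a logged warning.
    """
    if kind not in STREAM_SPECS:
        raise KeyError(f"unknown stream kind {kind!r}")
    spec = STREAM_SPECS[kind]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={c: object for c in spec.str_cols},
                     float_precision="round_trip")
    if tuple(df.columns) != spec.columns:
        raise SchemaError(
            f"{path}: header {tuple(df.columns)} does not match the "
            f"{kind!r} schema {spec.columns}"
        )
    n_raw = len(df)
    if n_raw == 0:
        return empty_frame(kind), 0

    valid = np.ones(n_raw, dtype=bool)
    t = pd.to_numeric(df[spec.time_col], errors="coerce")
    valid &= t.notna().to_numpy()
    for c in spec.float_cols + spec.int_cols:
        v = pd.to_numeric(df[c], errors="coerce")
        df[c] = v
        if kind == "ema" and c != "answered":
            continue  # answer columns may legitimately be blank (skips)
        valid &= v.notna().to_numpy()
    for c, allowed in spec.enum_cols.items():
        valid &= df[c].isin(allowed).to_numpy()

    # domain bounds
    if kind == "hrm":
        valid &= ((df["bpm"] > 25) & (df["bpm"] < 250)).fillna(False).to_numpy()
    elif kind == "light":
        valid &= (df["lux"] >= 0).fillna(False).to_numpy()
    elif kind == "calls":
        valid &= (df["duration_s"] >= 0).fillna(False).to_numpy()
    elif kind == "apps":
        valid &= (df["duration_s"] > 0).fillna(False).to_numpy()
    elif kind == "ema":
        answered = df["answered"].fillna(-1).to_numpy()
        valid &= np.isin(answered, (0, 1))
        ans_cols = df[["physical", "mood", "sleep", "social", "food"]]
        ok_range = ((ans_cols >= 1) & (ans_cols <= 10)).all(axis=1).to_numpy()
        has_all = ans_cols.notna().all(axis=1).to_numpy()
        valid &= np.where(answered == 1, has_all & ok_range, True)

    malformed = int(n_raw - valid.sum())
    if malformed:
        logger.warning("%s: %d malformed row(s) skipped", path, malformed)
    df = df.loc[valid].copy()
    df[spec.time_col] = t[valid].astype(np.int64)

    tv = df[spec.time_col].to_numpy()
    if len(tv) > 1 and np.any(np.diff(tv) < 0):
        logger.warning("%s: timestamps not monotone; applying stable sort",
                       path)
        df = df.sort_values(spec.time_col, kind="stable")
    df = df.reset_index(drop=True)
    if kind == "apps":
        df["is_social"] = df["is_social"].astype(np.int64)
    if kind == "ema":
        df["answered"] = df["answered"].astype(np.int64)
    return df, malformed


def write_frame(df: pd.DataFrame, kind: str, path: str | Path) -> Path:
    """Write a stream DataFrame as CSV (sorted by time, round-trip safe)."""
    spec = STREAM_SPECS[kind]
    path = Path(path)
    out = df.loc[:, list(spec.columns)].copy()
    if len(out):
        tv = out[spec.time_col].to_numpy()
        if np.any(np.diff(tv) < 0):
            logger.warning("write_frame(%s): records out of order; sorting",
                           kind)
            out = out.sort_values(spec.time_col, kind="stable")
        out[spec.time_col] = out[spec.time_col].astype(np.int64)
        # shortest round-trip decimal rendering for reals (repr), blanks
        # for missing values
        for c in spec.float_cols:
            out[c] = [("" if v != v else repr(v))
                      for v in out[c].astype(float).to_numpy().tolist()]
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Record-level I/O

@dataclass(slots=True)
class ReadResult:
    records: list
    malformed: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def frame_to_records(df: pd.DataFrame, kind: str,
                     device: str | None = None) -> list:
    rows = df.to_dict("records")
    if kind == "accel":
        dev = device or "phone"
        return [AccelSample(int(r["timestamp"]), float(r["x"]),
                            float(r["y"]), float(r["z"]), dev) for r in rows]
    if kind == "hrm":
        return [HrmSample(int(r["timestamp"]), float(r["bpm"])) for r in rows]
    if kind == "light":
        return [LightSample(int(r["timestamp"]), float(r["lux"]))
                for r in rows]
    if kind == "events":
        return [DiscreteEvent(int(r["timestamp"]), str(r["kind"]))
                for r in rows]
    if kind == "calls":
        return [CallRecord(int(r["start"]), str(r["direction"]),
                           float(r["duration_s"])) for r in rows]
    if kind == "apps":
        return [AppSession(int(r["start"]), str(r["app_id"]),
                           bool(r["is_social"]), float(r["duration_s"]))
                for r in rows]
    if kind == "ema":
        out = []
        for r in rows:
            answered = bool(r["answered"])
            def _a(v):
                return int(v) if answered and pd.notna(v) else None
            out.append(EmaResponse(int(r["checkin_time"]), answered,
                                   _a(r["physical"]), _a(r["mood"]),
                                   _a(r["sleep"]), _a(r["social"]),
                                   _a(r["food"])))
        return out
    raise KeyError(kind)


def records_to_frame(records: Sequence, kind: str) -> pd.DataFrame:
    spec = STREAM_SPECS[kind]
    if not records:
        return empty_frame(kind)
    cols: dict[str, list] = {c: [] for c in spec.columns}
    for rec in records:
        if kind == "ema":
            cols["checkin_time"].append(rec.checkin_time)
            cols["answered"].append(int(rec.answered))
            for c in ("physical", "mood", "sleep", "social", "food"):
                v = getattr(rec, c)
                cols[c].append(np.nan if v is None else int(v))
        else:
            for c in spec.columns:
                v = getattr(rec, c)
                cols[c].append(int(v) if isinstance(v, bool) else v)
    return pd.DataFrame(cols)


def _kind_of(record) -> str:
    for kind, typ in _RECORD_TYPES.items():
        if isinstance(record, typ):
            return kind
    raise TypeError(f"unrecognised record type {type(record).__name__}")


def read_stream(path: str | Path, kind: str,
                device: str | None = None) -> ReadResult:
    """Read a sensor CSV as a list of typed records plus a malformed count."""
    df, malformed = read_frame(path, kind)
    return ReadResult(frame_to_records(df, kind, device=device), malformed)


def write_stream(records: Sequence, path: str | Path,
                 kind: str | None = None) -> Path:
    """Write homogeneous records to CSV; ``kind`` is required for []."""
    if kind is None:
        if not records:
            raise ValueError("kind is required when writing an empty stream")
        kind = _kind_of(records[0])
    if records and any(_kind_of(r) != kind for r in records):
        raise TypeError("write_stream requires a homogeneous record list")
    return write_frame(records_to_frame(records, kind), kind, path)


# ---------------------------------------------------------------------------
# Manifest and participant datasets

def read_manifest(path: str | Path) -> ParticipantManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing participant manifest: {path}")
    df = pd.read_csv(path, dtype={"participant_id": object,
                                  "interview_outcome": object,
                                  "timezone": object})
    expected = ("participant_id", "phq9", "interview_outcome", "timezone")
    if tuple(df.columns) != expected or len(df) != 1:
        raise SchemaError(f"{path}: expected a single-row manifest with "
                          f"columns {expected}")
    r = df.iloc[0]
    return ParticipantManifest(str(r["participant_id"]), int(r["phq9"]),
                               str(r["interview_outcome"]),
                               str(r["timezone"]))


def write_manifest(manifest: ParticipantManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "participant_id": manifest.participant_id,
        "phq9": manifest.phq9,
        "interview_outcome": manifest.interview_outcome,
        "timezone": manifest.timezone,
    }]).to_csv(path, index=False)
    return path


@dataclass
class ParticipantDataset:
    """All of one participant's streams, EMA log and manifest (as frames)."""

    participant_id: str
    manifest: ParticipantManifest
    accel_phone: pd.DataFrame
    accel_watch: pd.DataFrame
    hrm: pd.DataFrame
    light: pd.DataFrame
    events: pd.DataFrame
    calls: pd.DataFrame
    apps: pd.DataFrame
    ema: pd.DataFrame
    malformed: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def timezone(self) -> str:
        return self.manifest.timezone

    def ema_records(self) -> list[EmaResponse]:
        return frame_to_records(self.ema, "ema")


def load_participant(root: str | Path,
                     participant_id: str) -> ParticipantDataset:
    """Load one participant directory into a :class:`ParticipantDataset`.

    The manifest is mandatory; absent optional streams yield empty frames
    with a recorded warning.
    """
    pdir = Path(root) / participant_id
    if not pdir.is_dir():
        raise FileNotFoundError(
            f"participant {participant_id!r} not found under {root}")
    manifest = read_manifest(pdir / "manifest.csv")

    frames: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    warnings: list[str] = []
    for fname, (kind, device) in DATASET_LAYOUT.items():
        key = fname[:-4]
        fpath = pdir / fname
        if fpath.exists():
            frames[key], malformed[key] = read_frame(fpath, kind)
        else:
            msg = f"{participant_id}: missing optional stream {fname}"
            logger.warning(msg)
            warnings.append(msg)
            frames[key], malformed[key] = empty_frame(kind), 0
    return ParticipantDataset(
        participant_id=participant_id, manifest=manifest,
        accel_phone=frames["accel_phone"], accel_watch=frames["accel_watch"],
        hrm=frames["hrm"], light=frames["light"], events=frames["events"],
        calls=frames["calls"], apps=frames["apps"], ema=frames["ema"],
        malformed=malformed, warnings=warnings)


def list_participants(root: str | Path) -> list[str]:
    root = Path(root)
    return sorted(p.name for p in root.iterdir()
                  if p.is_dir() and (p / "manifest.csv").exists())


# ---------------------------------------------------------------------------
# Clock-time helpers

def to_local(ts_ms, tz: str = "UTC") -> pd.DatetimeIndex:
    """Convert epoch-ms values to timezone-aware local datetimes."""
    idx = pd.to_datetime(np.asarray(ts_ms, dtype=np.int64), unit="ms",
                         utc=True)
    return pd.DatetimeIndex(idx).tz_convert(tz)


def local_to_ms(when: pd.Timestamp | str, tz: str = "UTC") -> int:
    """Epoch ms of a naive local clock time in timezone ``tz``."""
    ts = pd.Timestamp(when)
    if ts.tzinfo is None:
        ts = ts.tz_localize(tz)
    return int(ts.tz_convert("UTC").value // 1_000_000)


def slot_hour_of(ts_ms, tz: str = "UTC") -> np.ndarray:
    """Local clock hour of each timestamp (EMA slot identification)."""
    return to_local(ts_ms, tz).hour.to_numpy()


def local_date_of(ts_ms, tz: str = "UTC") -> np.ndarray:
    return to_local(ts_ms, tz).date
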